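"""Pooled allele frequencies, day-0-normalized trajectories and summaries.

Frequencies are read-count ratios: ``ref_af = ref_count / (ref_count +
alt_count)`` and ``alt_af`` its complement.  "Normalization to day 0" is
the difference ``alt_af(day) - alt_af(day 0)``, so trajectories share a
common origin and stay inside [-1, 1].  Because every analyzed marker has
opposite-homozygote parents with the maternal allele as reference, the
maternal-haplotype frequency is the frequency of the female's allele and
the paternal frequency its complement.  Per-marker heterozygosity is
``ref_af * alt_af`` (maximal 0.25 at 0.5/0.5), and "sequence divergence"
at an endpoint counts markers whose alternative frequency rose or fell
relative to day 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LarvascanError, ValidationError

__all__ = [
    "compute_allele_freq",
    "normalize_to_day0",
    "mean_trajectory",
    "haplotype_frequencies",
    "heterozygosity",
    "sample_mean_heterozygosity",
    "divergence_direction",
    "DivergenceCounts",
]

logger = logging.getLogger(__name__)


def compute_allele_freq(counts: pd.DataFrame) -> pd.DataFrame:
    """Append ``ref_af``/``alt_af`` columns; missing cells propagate NaN."""
    total = counts["ref_count"] + counts["alt_count"]
    nonmissing = counts["ref_count"].notna()
    if (nonmissing & (total == 0)).any():
        raise LarvascanError(
            "zero total depth on a nonmissing cell; apply depth filters first"
        )
    out = counts.copy()
    out["ref_af"] = (counts["ref_count"] / total).astype(float)
    out["alt_af"] = (counts["alt_count"] / total).astype(float)
    return out


def _day0_lookup(freqs: pd.DataFrame, female: int, male: int) -> pd.Series:
    d0 = freqs[(freqs["female"] == female) & (freqs["male"] == male) & (freqs["day"] == 0)]
    return d0.set_index("marker_id")["alt_af"]


def normalize_to_day0(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-marker trajectory deltas ``alt_af(day) - alt_af(day 0)``.

    Returns a long frame over the non-day-0 samples with a ``delta_af``
    column; markers whose day-0 frequency is missing are excluded and
    logged.  Adding a constant to every ``alt_af`` leaves deltas unchanged.
    """
    out_frames = []
    for (f, m), fam in freqs.groupby(["female", "male"], sort=False):
        base = _day0_lookup(freqs, f, m).dropna()
        later = fam[fam["day"] != 0].copy()
        known = later["marker_id"].isin(base.index)
        n_dropped = later.loc[~known, "marker_id"].nunique()
        if n_dropped:
            logger.info(
                "F%d.M%d: %d markers lack a day-0 frequency and were excluded", f, m, n_dropped
            )
        later = later[known]
        later["delta_af"] = later["alt_af"].to_numpy() - base.reindex(later["marker_id"]).to_numpy()
        out_frames.append(later)
    if not out_frames:
        return freqs.iloc[0:0].assign(delta_af=pd.Series(dtype=float))
    return pd.concat(out_frames, ignore_index=True)


def mean_trajectory(
    freqs: pd.DataFrame,
    female: int,
    male: int,
    replicate: int,
    markers: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-day mean alternative allele frequency over (a set of) markers.

    Day-23 size groups are reported separately.  The day-0 row of the
    family (shared across replicates) is included.
    """
    fam = freqs[(freqs["female"] == female) & (freqs["male"] == male)]
    sel = fam[(fam["replicate"] == replicate) | fam["replicate"].isna()]
    if markers is not None:
        sel = sel[sel["marker_id"].isin(set(markers))]
    grouped = (
        sel.groupby(["day", "size_group"], dropna=False, observed=True)["alt_af"]
        .mean()
        .reset_index()
        .rename(columns={"alt_af": "mean_alt_af"})
        .sort_values(["day", "size_group"], na_position="first")
        .reset_index(drop=True)
    )
    return grouped


def haplotype_frequencies(freqs: pd.DataFrame, pg: pd.DataFrame) -> pd.DataFrame:
    """Maternal/paternal haplotype frequencies per (marker, sample).

    The maternal frequency is the pooled frequency of the allele the
    female parent is homozygous for; paternal is its complement.  Raises
    on non-informative markers.
    """
    orient = pg.set_index(["marker_id", "female", "male"])[["female_gt", "male_gt"]]
    merged = freqs.join(
        orient, on=["marker_id", "female", "male"], how="left", validate="m:1"
    )
    informative = (
        (merged["female_gt"] == "hom_ref") & (merged["male_gt"] == "hom_alt")
    ) | ((merged["female_gt"] == "hom_alt") & (merged["male_gt"] == "hom_ref"))
    if not informative.all():
        bad = merged.loc[~informative, "marker_id"].unique()[:5]
        raise ValidationError(f"non-informative markers in haplotype analysis: {list(bad)}")
    out = freqs.copy()
    female_is_ref = (merged["female_gt"] == "hom_ref").to_numpy()
    out["maternal_af"] = np.where(female_is_ref, merged["ref_af"], merged["alt_af"])
    out["paternal_af"] = 1.0 - out["maternal_af"]
    return out


def heterozygosity(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per (marker, sample) pooled heterozygosity ``ref_af * alt_af``."""
    out = freqs.copy()
    out["heterozygosity"] = out["ref_af"] * out["alt_af"]
    return out


def sample_mean_heterozygosity(
    freqs: pd.DataFrame, markers: Iterable[str]
) -> pd.DataFrame:
    """Mean heterozygosity per sample over a supplied marker set."""
    marker_set = set(markers)
    sub = heterozygosity(freqs[freqs["marker_id"].isin(marker_set)])
    return (
        sub.groupby(["female", "male", "replicate", "day", "size_group"], dropna=False, observed=True)[
            "heterozygosity"
        ]
        .mean()
        .reset_index()
        .rename(columns={"heterozygosity": "mean_heterozygosity"})
    )


@dataclass(frozen=True)
class DivergenceCounts:
    increase: int
    decrease: int
    ties: int


def divergence_direction(
    freqs: pd.DataFrame,
    markers: Sequence[str],
    female: int,
    male: int,
    replicate: int,
    day: int = 23,
    size_group: str | None = "Big",
) -> DivergenceCounts:
    """Count markers whose alt frequency rose/fell at an endpoint vs day 0.

    Ties (exact equality) are reported separately rather than forced into
    either class.
    """
    marker_set = set(markers)
    fam = freqs[(freqs["female"] == female) & (freqs["male"] == male)]
    base = _day0_lookup(fam, female, male)
    end = fam[(fam["replicate"] == replicate) & (fam["day"] == day)]
    if size_group is None:
        end = end[end["size_group"].isna()]
    else:
        end = end[end["size_group"] == size_group]
    end = end.set_index("marker_id")["alt_af"]
    common = [m for m in marker_set if m in base.index and m in end.index]
    delta = end.reindex(common) - base.reindex(common)
    delta = delta.dropna()
    return DivergenceCounts(
        increase=int((delta > 0).sum()),
        decrease=int((delta < 0).sum()),
        ties=int((delta == 0).sum()),
    )
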