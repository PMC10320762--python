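"""Monotonic-trend marker selection and the Monte-Carlo chance-of-drift null.

A marker inside a significant contig is a trend (viability) marker when
its pooled alternative allele frequency moves strictly in one direction
through the whole experiment: the chained comparisons D0→D11, D11→D16,
D16→D23Big and D16→D23Small (the Small branch dropped when that pool was
not recovered) must all share one sign; ties break monotonicity.

The chance-of-drift null asks how often pure sampling noise produces such
a direction-consistent trajectory: the true frequency is held at the
day-0 value p0 and, for each comparison, start and end allele counts are
drawn as independent binomials at the comparison's sequencing depths, so
the comparison signs are exchangeable coin flips.  In the deep-coverage
limit the probability of k strictly same-sign comparisons is exactly
2·(1/2)^k — 12.5% for the four-comparison design — and finite depth can
only lower it (ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .selection_scan import _replicate_wide, _col

__all__ = [
    "TrendResult",
    "DriftEstimate",
    "monotonic_trend_markers",
    "chance_of_drift",
    "drift_for_markers",
    "joint_drift_probability",
]

logger = logging.getLogger(__name__)


def monotonic_trend_markers(
    freqs: pd.DataFrame,
    markers: Iterable[str],
    female: int,
    male: int,
    replicate: int,
) -> pd.DataFrame:
    """Classify each marker's trajectory as monotone increasing/decreasing.

    ``markers`` should be the members of the significant contigs.  Returns
    one row per marker with the day-0-normalized deltas, the step signs
    and ``monotone``/``direction`` columns.  Markers lacking a day-0 or
    any later frequency are excluded (logged).  Missing intermediate
    samples are skipped, chaining the remaining days in order.
    """
    fam = freqs[(freqs["female"] == female) & (freqs["male"] == male)]
    sel = fam[(fam["replicate"] == replicate) | fam["replicate"].isna()]
    sel = sel[sel["marker_id"].isin(set(markers))]
    sg = sel["size_group"].fillna("-")
    wide = sel.assign(size_group=sg).pivot_table(
        index="marker_id", columns=["day", "size_group"], values="alt_af",
        aggfunc="first", dropna=False, observed=True,
    )

    def series_col(day, group="-"):
        key = (day, group)
        return wide[key] if key in wide.columns else pd.Series(np.nan, index=wide.index)

    af = {d: series_col(d) for d in (0, 11, 16)}
    af_big = series_col(23, "Big")
    af_small = series_col(23, "Small")

    rows = []
    n_excluded = 0
    for marker in wide.index:
        base = af[0].loc[marker]
        if not np.isfinite(base):
            n_excluded += 1
            continue
        pre = [(d, af[d].loc[marker]) for d in (0, 11, 16) if np.isfinite(af[d].loc[marker])]
        steps = [b - a for (_, a), (_, b) in zip(pre, pre[1:])]
        branch_base = pre[-1][1]
        deltas = {
            "delta_d11": af[11].loc[marker] - base,
            "delta_d16": af[16].loc[marker] - base,
            "delta_d23big": af_big.loc[marker] - base,
            "delta_d23small": af_small.loc[marker] - base,
        }
        for branch in (af_big.loc[marker], af_small.loc[marker]):
            if np.isfinite(branch):
                steps.append(branch - branch_base)
        if not steps:
            n_excluded += 1
            continue
        steps = np.asarray(steps)
        monotone = bool((steps > 0).all() or (steps < 0).all())
        if monotone:
            direction = "increasing" if steps[0] > 0 else "decreasing"
        else:
            direction = "none"
        rows.append({"marker_id": marker, **deltas, "n_comparisons": len(steps),
                     "monotone": monotone, "direction": direction})
    if n_excluded:
        logger.info("monotonic trend: %d markers excluded (missing day 0 or all later days)",
                    n_excluded)
    return pd.DataFrame(
        rows,
        columns=["marker_id", "delta_d11", "delta_d16", "delta_d23big", "delta_d23small",
                 "n_comparisons", "monotone", "direction"],
    )


@dataclass
class DriftEstimate:
    """Monte-Carlo probability of a direction-consistent trajectory by chance."""

    marker_id: str | None
    p0: float
    depths: np.ndarray  # (n_comparisons, 2) start/end depths
    n_sims: int
    chance_of_drift: float
    seed: int | None


def _comparison_depths(depths, n_comparisons: int) -> np.ndarray:
    """Normalize a depth spec into (n_comparisons, 2) start/end pairs.

    Accepts a scalar (uniform depth), a length-5 sequence of time-point
    depths (D0, D11, D16, D23Big, D23Small) mapped onto the chained
    comparisons, or an explicit (n_comparisons, 2) array.
    """
    arr = np.asarray(depths, dtype=float)
    if arr.ndim == 0:
        out = np.full((n_comparisons, 2), float(arr))
    elif arr.ndim == 1 and arr.size == n_comparisons + 1:
        if n_comparisons == 4:
            d0, d11, d16, dbig, dsmall = arr
            out = np.array([[d0, d11], [d11, d16], [d16, dbig], [d16, dsmall]])
        else:
            out = np.stack([arr[:-1], arr[1:]], axis=1)
    elif arr.ndim == 2 and arr.shape == (n_comparisons, 2):
        out = arr
    else:
        raise ParameterError(f"cannot map depths of shape {arr.shape} onto "
                             f"{n_comparisons} comparisons")
    if (out <= 0).any():
        raise ParameterError("depths must be positive")
    return out


def chance_of_drift(
    p0: float,
    depths,
    n_comparisons: int = 4,
    n_sims: int = 100_000,
    seed: int | np.random.Generator | None = None,
    marker_id: str | None = None,
) -> DriftEstimate:
    """Probability that sampling noise alone yields a monotone trajectory.

    Start and end alt counts of each comparison are independent
    ``Binomial(depth, p0)`` draws; the estimate is the fraction of
    simulations whose comparisons all strictly share one sign.
    Deterministic under a fixed seed; the standard error scales as
    ``1/sqrt(n_sims)``.
    """
    if not 0 <= p0 <= 1:
        raise ParameterError("p0 must lie in [0, 1]")
    if n_sims < 1000:
        raise ParameterError("n_sims must be >= 1000 for a usable estimate")
    dep = _comparison_depths(depths, n_comparisons)
    if p0 in (0.0, 1.0):
        warnings.warn("p0 is fixed (0 or 1): chance-of-drift is 0", stacklevel=2)
        return DriftEstimate(marker_id, p0, dep, n_sims, 0.0, _seed_int(seed))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = rng.binomial(dep[:, 0].astype(int), p0, size=(n_sims, n_comparisons))
    end = rng.binomial(dep[:, 1].astype(int), p0, size=(n_sims, n_comparisons))
    diff = end / dep[:, 1] - start / dep[:, 0]
    monotone = np.all(diff > 0, axis=1) | np.all(diff < 0, axis=1)
    return DriftEstimate(
        marker_id, p0, dep, n_sims, float(monotone.mean()), _seed_int(seed)
    )


def _seed_int(seed):
    return seed if isinstance(seed, (int, np.integer)) or seed is None else None


def drift_for_markers(
    table: pd.DataFrame,
    freqs: pd.DataFrame,
    markers: Sequence[str],
    female: int,
    male: int,
    replicate: int,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-marker chance-of-drift for a replicate, plus the set average.

    p0 is the marker's observed day-0 alt frequency and the comparison
    depths its observed total read counts at each sampled time point.
    Returns a frame with one row per marker; the reported summary of the
    study design is the mean of ``chance_of_drift`` over the set.
    """
    wide = _replicate_wide(table, markers, female, male, replicate)
    fwide = freqs[
        (freqs["female"] == female) & (freqs["male"] == male) & (freqs["day"] == 0)
    ].set_index("marker_id")["alt_af"]
    rng = np.random.default_rng(seed)
    rows = []
    for marker in wide.index:
        p0 = fwide.get(marker, np.nan)
        if not np.isfinite(p0):
            continue
        dep = []
        spec_points = [(0, None), (11, None), (16, None), (23, "Big"), (23, "Small")]
        totals = {}
        for day, g in spec_points:
            ref = _col(wide, "ref_count", day, g)
            alt = _col(wide, "alt_count", day, g)
            if ref is None:
                totals[(day, g)] = np.nan
            else:
                i = wide.index.get_loc(marker)
                totals[(day, g)] = ref[i] + alt[i]
        pairs = [((0, None), (11, None)), ((11, None), (16, None)),
                 ((16, None), (23, "Big")), ((16, None), (23, "Small"))]
        dep = [
            (totals[a], totals[b])
            for a, b in pairs
            if np.isfinite(totals[a]) and np.isfinite(totals[b])
        ]
        if not dep:
            continue
        est = chance_of_drift(
            float(p0), np.asarray(dep), n_comparisons=len(dep),
            n_sims=n_sims, seed=rng, marker_id=marker,
        )
        rows.append({"marker_id": marker, "p0": est.p0,
                     "n_comparisons": len(dep), "n_sims": n_sims,
                     "chance_of_drift": est.chance_of_drift})
    return pd.DataFrame(rows)


def joint_drift_probability(per_replicate_probs: Sequence[float]) -> float:
    """Probability that drift explains every replicate (independence)."""
    probs = np.asarray(per_replicate_probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ParameterError("probabilities must lie in [0, 1]")
    return float(np.prod(probs))
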