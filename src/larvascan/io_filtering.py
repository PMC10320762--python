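"""Count-table and parental-genotype I/O plus the depth/missing-data filters.

The central object is the pool count table: one row per (marker, sample)
with reference/alternative read counts, where a sample is identified by
family (female x male), replicate tank, sampling day and optional day-23
size group (the ``Fx.Mx.Rx.DxBig`` naming scheme).  Day-0 pools are taken
from the fertilized population before the replicate split and therefore
carry no replicate id.

Filtering follows the study protocol: a 40x minimum parental depth, a
"zero recovery" rule converting biologically impossible 0 -> >0 count
rebounds to missing data, and a 20x both-allele depth requirement defining
the per-replicate heterozygous marker set (nHet) that every downstream
significance threshold consumes.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "SampleKey",
    "FilterReport",
    "parse_sample_key",
    "format_sample_key",
    "read_pool_counts",
    "write_pool_counts",
    "validate_pool_counts",
    "read_parental_vcf",
    "informative_markers",
    "filter_parental_depth",
    "apply_zero_recovery_rule",
    "select_heterozygous_markers",
]

logger = logging.getLogger(__name__)

VALID_DAYS = (0, 11, 16, 23)
SIZE_GROUPS = ("Big", "Small")

COUNT_COLUMNS = [
    "marker_id", "contig", "position", "female", "male",
    "replicate", "day", "size_group", "ref_count", "alt_count",
]

_SAMPLE_RE = re.compile(r"^F(\d+)\.M(\d+)(?:\.R(\d+))?\.D(\d+)(Big|Small)?$")


@dataclass(frozen=True)
class SampleKey:
    """Identity of one sequencing pool: family, replicate, day, size group."""

    female: int
    male: int
    replicate: int | None
    day: int
    size_group: str | None = None

    def __post_init__(self):
        if self.day not in VALID_DAYS:
            raise ValidationError(f"day must be one of {VALID_DAYS}, got {self.day}")
        if self.size_group is not None and self.day != 23:
            raise ValidationError("size_group is only defined on day 23")
        if self.size_group is not None and self.size_group not in SIZE_GROUPS:
            raise ValidationError(f"size_group must be Big or Small, got {self.size_group!r}")
        if self.replicate is None and self.day != 0:
            raise ValidationError("only day-0 pools may lack a replicate id")


def parse_sample_key(label: str) -> SampleKey:
    """Parse an ``Fx.Mx.Rx.Dx[Big|Small]`` sample label."""
    m = _SAMPLE_RE.match(label.strip())
    if m is None:
        raise ParseError(f"cannot parse sample label {label!r}")
    f, male, rep, day, size = m.groups()
    return SampleKey(
        female=int(f),
        male=int(male),
        replicate=int(rep) if rep is not None else None,
        day=int(day),
        size_group=size,
    )


def format_sample_key(key: SampleKey) -> str:
    parts = [f"F{key.female}", f"M{key.male}"]
    if key.replicate is not None:
        parts.append(f"R{key.replicate}")
    parts.append(f"D{key.day}{key.size_group or ''}")
    return ".".join(parts)


# ---------------------------------------------------------------------------
# pool count tables


def validate_pool_counts(table: pd.DataFrame) -> None:
    """Check schema invariants; raises :class:`ValidationError`."""
    missing_cols = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    bad_day = ~table["day"].isin(VALID_DAYS)
    if bad_day.any():
        raise ValidationError(f"invalid day values: {sorted(table.loc[bad_day, 'day'].unique())}")
    sg = table["size_group"]
    has_group = sg.notna()
    if (has_group & (table["day"] != 23)).any():
        raise ValidationError("size_group set on a sample with day != 23")
    if has_group.any() and not sg[has_group].isin(SIZE_GROUPS).all():
        raise ValidationError("size_group must be Big or Small")
    if (table["replicate"].isna() & (table["day"] != 0)).any():
        raise ValidationError("replicate missing on a sample with day != 0")
    for col in ("ref_count", "alt_count"):
        vals = table[col]
        if (vals.dropna() < 0).any():
            row = int(table.index[vals < 0][0])
            raise ValidationError(f"negative {col} at row {row}")
    # missing cells carry no counts: either both counts present or both absent
    if (table["ref_count"].isna() != table["alt_count"].isna()).any():
        raise ValidationError("ref_count/alt_count must be missing together")
    keys = table[["marker_id", "female", "male", "replicate", "day", "size_group"]]
    if keys.duplicated().any():
        raise ValidationError("duplicate (marker, sample) rows")


def read_pool_counts(path) -> pd.DataFrame:
    """Read a pool count TSV.

    Accepts either the expanded key columns or a single ``sample`` column
    holding ``Fx.Mx.Rx.Dx[Big|Small]`` labels.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "contig": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if "sample" in raw.columns and "day" not in raw.columns:
        keys = [parse_sample_key(s) for s in raw["sample"]]
        raw = raw.drop(columns=["sample"]).assign(
            female=[k.female for k in keys],
            male=[k.male for k in keys],
            replicate=[k.replicate for k in keys],
            day=[k.day for k in keys],
            size_group=[k.size_group for k in keys],
        )
    for col in ("ref_count", "alt_count", "replicate"):
        if col in raw.columns:
            try:
                raw[col] = raw[col].astype("Int64")
            except TypeError as exc:
                bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise ParseError(f"non-integer {col} near line {line} of {path}") from exc
    if "size_group" in raw.columns:
        raw["size_group"] = raw["size_group"].astype("string")
    validate_pool_counts(raw)
    return raw[COUNT_COLUMNS]


def write_pool_counts(table: pd.DataFrame, path) -> None:
    validate_pool_counts(table)
    table[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parental genotypes

PARENTAL_COLUMNS = [
    "marker_id", "contig", "position", "female", "male",
    "female_gt", "male_gt", "female_depth", "male_depth",
]

_GT_CODE = {(0, 0): "hom_ref", (1, 1): "hom_alt", (0, 1): "het", (1, 0): "het"}


def read_parental_vcf(path, female_sample: str, male_sample: str,
                      family: tuple[int, int] = (1, 1)) -> pd.DataFrame:
    """Ingest parental genotype calls from a VCF.

    Biallelic SNPs only; multiallelic or indel records are skipped (the
    skip count is logged).  A missing per-sample DP leaves the depth
    unknown, which fails the parental depth filter downstream.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    skipped = 0
    rows = []
    f_id, m_id = family
    for rec in vf.fetch() if vf.index is not None else vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        out = {}
        for role, sample in (("female", female_sample), ("male", male_sample)):
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or None in gt:
                out[f"{role}_gt"] = "unknown"
            else:
                out[f"{role}_gt"] = _GT_CODE.get(tuple(sorted(gt)), "unknown")
            dp = call.get("DP")
            out[f"{role}_depth"] = dp if dp is not None else pd.NA
        rows.append(
            (f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, f_id, m_id,
             out["female_gt"], out["male_gt"], out["female_depth"], out["male_depth"])
        )
    if skipped:
        logger.info("read_parental_vcf: skipped %d non-biallelic-SNP records", skipped)
    pg = pd.DataFrame(rows, columns=PARENTAL_COLUMNS)
    pg["female_depth"] = pg["female_depth"].astype("Int64")
    pg["male_depth"] = pg["male_depth"].astype("Int64")
    pg.attrs["skipped_records"] = skipped
    return pg


def informative_markers(pg: pd.DataFrame) -> pd.DataFrame:
    """Markers whose parents are homozygous for opposite alleles."""
    opp = ((pg["female_gt"] == "hom_ref") & (pg["male_gt"] == "hom_alt")) | (
        (pg["female_gt"] == "hom_alt") & (pg["male_gt"] == "hom_ref")
    )
    return pg[opp]


def filter_parental_depth(pg: pd.DataFrame, min_depth: int = 40) -> pd.DataFrame:
    """Drop markers where either parent is below ``min_depth`` (inclusive keep).

    Unknown depths fail the filter.  Families left with no markers are
    dropped entirely (logged), mirroring the discard of whole replicates
    whose parents were under-sequenced.
    """
    fdep = pg["female_depth"].fillna(-1)
    mdep = pg["male_depth"].fillna(-1)
    keep = (fdep >= min_depth) & (mdep >= min_depth)
    out = pg[keep].copy()
    if out.empty:
        warnings.warn("filter_parental_depth removed every marker", stacklevel=2)
    dropped_families = set(map(tuple, pg[["female", "male"]].drop_duplicates().values)) - set(
        map(tuple, out[["female", "male"]].drop_duplicates().values)
    )
    for fam in sorted(dropped_families):
        logger.info("family F%d.M%d dropped entirely by parental depth filter", *fam)
    return out


# ---------------------------------------------------------------------------
# zero-recovery rule


def _series_order(day: int, size_group) -> int:
    # D23 Big/Small are parallel terminal samples; both sort after D16
    return day


def apply_zero_recovery_rule(table: pd.DataFrame) -> pd.DataFrame:
    """Mask counts that rebound from zero (a biological impossibility).

    Within each marker's per-replicate time series (the shared day-0 pool
    included), an allele count of 0 at one day followed by a positive count
    of the same allele at any later day marks that (marker, sample) cell
    missing — both alleles, since a vanished-and-returned marker cannot be
    trusted at that time point.  Terminal zeros are untouched.  Idempotent.
    """
    validate_pool_counts(table)
    out = table.copy()
    mask = np.zeros(len(out), dtype=bool)
    pos = pd.Series(np.arange(len(out)), index=out.index)
    for (f, m), fam in out.groupby(["female", "male"], sort=False):
        d0 = fam[fam["day"] == 0]
        reps = fam.loc[fam["replicate"].notna(), "replicate"].unique()
        for r in reps:
            series = pd.concat([d0, fam[fam["replicate"] == r]])
            series = series.sort_values("day", kind="stable")
            for allele in ("ref_count", "alt_count"):
                wide = series.pivot_table(
                    index="marker_id", columns=["day", "size_group"],
                    values=allele, aggfunc="first", dropna=False, observed=True,
                )
                wide = wide[sorted(wide.columns, key=lambda c: c[0])]
                vals = wide.to_numpy(dtype=float)  # NaN = missing
                later_max = np.full_like(vals, -np.inf)
                days = np.array([c[0] for c in wide.columns])
                for j in range(vals.shape[1]):
                    later = vals[:, days > days[j]]
                    if later.size:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", RuntimeWarning)
                            later_max[:, j] = np.nanmax(later, axis=1, initial=-np.inf)
                bad = (vals == 0) & (later_max > 0)
                if not bad.any():
                    continue
                for i, j in zip(*np.nonzero(bad)):
                    marker = wide.index[i]
                    day, sg = wide.columns[j]
                    sel = (
                        (out["marker_id"] == marker)
                        & (out["female"] == f)
                        & (out["male"] == m)
                        & (out["day"] == day)
                        & ((out["replicate"] == r) | out["replicate"].isna())
                    )
                    if pd.isna(sg):
                        sel &= out["size_group"].isna()
                    else:
                        sel &= out["size_group"] == sg
                    mask |= sel.to_numpy()
    out.loc[mask, ["ref_count", "alt_count"]] = pd.NA
    return out


# ---------------------------------------------------------------------------
# heterozygous marker selection


@dataclass
class FilterReport:
    markers_in: int
    markers_out: int
    reason_counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def select_heterozygous_markers(
    table: pd.DataFrame,
    pg: pd.DataFrame,
    min_allele_depth: int = 20,
) -> tuple[dict[tuple[int, int, int], list[str]], FilterReport]:
    """Per-replicate heterozygous marker sets (nHet) after the 20x rule.

    A marker is retained for a replicate iff its parents are opposite
    homozygotes and, at every nonmissing sample of that replicate's series
    (shared day-0 pool included), both the reference and the alternative
    read count are at least ``min_allele_depth``.  Cells masked by the
    zero-recovery rule are exempt; markers with no nonmissing sample are
    dropped.  Returns ``({(female, male, replicate): [marker_id, ...]},
    report)`` — ``len`` of each list is that replicate's nHet.
    """
    validate_pool_counts(table)
    inf = informative_markers(pg)
    inf_by_family = {
        fam: set(sub["marker_id"]) for fam, sub in inf.groupby(["female", "male"], sort=False)
    }
    result: dict[tuple[int, int, int], list[str]] = {}
    reasons = {"not_informative": 0, "below_allele_depth": 0, "all_missing": 0}
    markers_in = 0
    for (f, m), fam in table.groupby(["female", "male"], sort=False):
        fam_inf = inf_by_family.get((f, m), set())
        d0 = fam[fam["day"] == 0]
        for r in sorted(fam.loc[fam["replicate"].notna(), "replicate"].unique()):
            series = pd.concat([d0, fam[fam["replicate"] == r]])
            all_markers = pd.unique(series["marker_id"])
            markers_in += all_markers.size
            present = series.dropna(subset=["ref_count"])
            deep = (present["ref_count"] >= min_allele_depth) & (
                present["alt_count"] >= min_allele_depth
            )
            ok = deep.groupby(present["marker_id"]).all()
            informative = pd.Index(all_markers).isin(fam_inf)
            reasons["not_informative"] += int((~informative).sum())
            with_data = pd.Index(all_markers).isin(ok.index)
            reasons["all_missing"] += int((informative & ~with_data).sum())
            passed = set(ok.index[ok])
            kept = sorted(
                mk for mk, isinf, has in zip(all_markers, informative, with_data)
                if isinf and has and mk in passed
            )
            reasons["below_allele_depth"] += int((informative & with_data).sum()) - len(kept)
            result[(f, m, int(r))] = kept
    absent = set(table["marker_id"]) - set(pg["marker_id"])
    if absent:
        logger.info("%d markers absent from the parental table were excluded", len(absent))
    report = FilterReport(
        markers_in=markers_in,
        markers_out=sum(len(v) for v in result.values()),
        reason_counts=reasons,
    )
    return result, report
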