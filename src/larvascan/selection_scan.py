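"""Chi-square selection scans on pooled read counts.

Four procedures share one engine, a Pearson 2x2 test of independence on
read counts:

* **viability scan** — per heterozygous marker, (ref, alt) x (day 0,
  day 23) with the day-23 Big and Small pools tested separately; a marker
  is viability-associated when every available test beats the
  replicate-specific threshold ``alpha = alpha_base / nHet``.
* **haplotype scan** — the same tables re-anchored to maternal/paternal
  allele counts, with Storey/BH q-values per comparison family and a
  q < 0.05 rule.
* **contig scan** — maternal/paternal counts summed over a contig's
  markers, tested day 0 vs day 23 (Big and Small) and day 16 vs day 23
  (Big only); the reported set is the intersection of the two comparisons'
  significant contigs.
* **size scan** — (ref, alt) x (Big, Small) on day 23 at the
  ``alpha_base / nHet`` threshold.

The per-replicate Bonferroni-style ``0.05 / nHet`` rule and the q-value
conversion mirror the study protocol; families of q-values are scoped per
replicate x comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ScanError, UndefinedTestError

__all__ = [
    "ScanConfig",
    "ScanOutcome",
    "ContigScanOutcome",
    "OverlapReport",
    "chisq_2x2",
    "qvalues",
    "storey_pi0",
    "viability_scan",
    "haplotype_scan",
    "contig_scan",
    "size_scan",
    "overlap_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Thresholds shared by the scan procedures."""

    alpha_base: float = 0.05
    q_threshold: float = 0.05
    #: Yates continuity correction (off: the study names Pearson's test)
    yates: bool = False
    fdr_method: str = "storey"  # or "bh"
    #: below this family size Storey's smoother is unstable; fall back to BH
    storey_min_tests: int = 100

    def adjusted_alpha(self, n_het: int) -> float:
        if n_het < 1:
            raise ScanError("nHet must be >= 1")
        return self.alpha_base / n_het


# ---------------------------------------------------------------------------
# the 2x2 engine


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]], df=1.

    Raises :class:`UndefinedTestError` when a row or column sum is zero.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ScanError("negative cell counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedTestError("zero marginal: chi-square test undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def _chisq_vec(a, b, c, d, yates: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized closed-form Pearson 2x2; NaN where a marginal is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.abs(a * d - b * c)
        if yates:
            det = np.maximum(det - n / 2.0, 0.0)
        stat = n * det**2 / (r1 * r2 * c1 * c2)
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    stat = np.where(valid, stat, np.nan)
    p = stats.chi2.sf(stat, 1)
    n_undef = int((~valid & np.isfinite(n)).sum())
    if n_undef:
        logger.info("%d tests skipped (zero marginal)", n_undef)
    low_expected = valid & (
        np.minimum.reduce([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / np.where(n > 0, n, 1) < 5
    )
    if low_expected.any():
        logger.info("%d tables have an expected cell < 5", int(low_expected.sum()))
    return stat, p


# ---------------------------------------------------------------------------
# q-values


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 estimate with the cubic lambda-smoother."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(np.clip(pi0, 1.0 / p.size if p.size else 1e-8, 1.0))


def qvalues(p_values: Sequence[float], method: str = "storey",
            storey_min_tests: int = 100) -> np.ndarray:
    """FDR q-values; ``method`` is ``"bh"`` or ``"storey"``.

    BH is the step-up ``q_i = min_{p_j >= p_i} p_j * m / rank_j`` clipped
    to 1; Storey multiplies by the estimated null fraction pi0.  NaN
    entries are ignored and returned as NaN.  Small families always use BH
    (pi0 = 1), where the smoother has nothing to smooth.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    if np.any((pf < 0) | (pf > 1)):
        raise ScanError("p-values must lie in [0, 1]")
    if method == "storey" and m >= storey_min_tests:
        pi0 = storey_pi0(pf)
    elif method in ("storey", "bh"):
        pi0 = 1.0
    else:
        raise ScanError(f"unknown FDR method {method!r}")
    from statsmodels.stats.multitest import multipletests

    q_bh = multipletests(pf, method="fdr_bh")[1]
    q[finite] = np.minimum(pi0 * q_bh, 1.0)
    return q


# ---------------------------------------------------------------------------
# sample extraction helpers


def _replicate_wide(table: pd.DataFrame, markers: Iterable[str],
                    female: int, male: int, replicate: int) -> pd.DataFrame:
    """Wide counts for one replicate's series (day-0 family pool included).

    Index: marker_id; columns: MultiIndex (field, day, size_group) with
    field in {ref, alt}; missing cells are NaN.
    """
    marker_set = set(markers)
    fam = table[
        (table["female"] == female)
        & (table["male"] == male)
        & table["marker_id"].isin(marker_set)
    ]
    sel = fam[(fam["replicate"] == replicate) | fam["replicate"].isna()]
    if sel.empty:
        raise ScanError(f"no samples for F{female}.M{male}.R{replicate}")
    sg = sel["size_group"].fillna("-")
    wide = sel.assign(size_group=sg).pivot_table(
        index="marker_id",
        columns=["day", "size_group"],
        values=["ref_count", "alt_count"],
        aggfunc="first",
        dropna=False,
        observed=True,
    )
    return wide


def _col(wide: pd.DataFrame, field: str, day: int, size_group: str | None) -> np.ndarray | None:
    key = (field, day, size_group if size_group is not None else "-")
    if key not in wide.columns:
        return None
    return wide[key].to_numpy(dtype=float)


def _direction(delta: np.ndarray) -> np.ndarray:
    out = np.where(delta > 0, "increase", np.where(delta < 0, "decrease", "tie"))
    return np.where(np.isfinite(delta), out, "tie")


# ---------------------------------------------------------------------------
# scan outcomes


@dataclass
class ScanOutcome:
    """Per-unit test results and the flagged set for one replicate."""

    results: pd.DataFrame
    flagged: list[str]
    alpha: float | None
    n_het: int | None
    comparisons: list[str]


@dataclass
class ContigScanOutcome:
    results: pd.DataFrame
    significant: dict[str, list[str]]  # per comparison
    intersection: list[str]


def _per_marker_tests(
    wide: pd.DataFrame,
    comparisons: list[tuple[str, tuple, tuple]],
    yates: bool,
) -> pd.DataFrame:
    """Run 2x2 tests marker-wise for each (label, start_key, end_key)."""
    frames = []
    for label, (d1, g1), (d2, g2) in comparisons:
        a = _col(wide, "ref_count", d1, g1)
        b = _col(wide, "alt_count", d1, g1)
        c = _col(wide, "ref_count", d2, g2)
        d = _col(wide, "alt_count", d2, g2)
        stat, p = _chisq_vec(a, b, c, d, yates=yates)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = c / (c + d) - a / (a + b)  # change in alt-AF? see below
        # delta above is in ref-AF terms; flip to alt-AF change
        delta = -delta
        frames.append(
            pd.DataFrame(
                {
                    "unit": wide.index,
                    "comparison": label,
                    "statistic": stat,
                    "p_value": p,
                    "direction": _direction(delta),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _available_d23_groups(wide: pd.DataFrame) -> list[str]:
    return [g for g in ("Big", "Small") if ("ref_count", 23, g) in wide.columns]


def viability_scan(
    table: pd.DataFrame,
    markers: Iterable[str],
    female: int,
    male: int,
    replicate: int,
    n_het: int,
    config: ScanConfig | None = None,
) -> ScanOutcome:
    """Day-0 vs day-23 allele-count tests; flag markers beating 0.05/nHet.

    Big and Small pools are tested separately; a marker is flagged only
    when **all** its available tests are below the adjusted threshold
    (single-test rule when only one size group was recovered).
    """
    config = config or ScanConfig()
    alpha = config.adjusted_alpha(n_het)
    wide = _replicate_wide(table, markers, female, male, replicate)
    groups = _available_d23_groups(wide)
    if not groups:
        raise ScanError(f"F{female}.M{male}.R{replicate} has no day-23 sample")
    comparisons = [(f"D0-vs-D23{g}", (0, None), (23, g)) for g in groups]
    res = _per_marker_tests(wide, comparisons, config.yates)
    res["q_value"] = np.nan
    res["significant"] = res["p_value"] < alpha
    per_unit = res.groupby("unit", observed=True).agg(
        n_avail=("p_value", lambda s: int(np.isfinite(s).sum())),
        n_sig=("significant", "sum"),
        n_tests=("p_value", "size"),
    )
    flagged = sorted(
        per_unit.index[(per_unit["n_avail"] > 0) & (per_unit["n_sig"] == per_unit["n_avail"])]
    )
    return ScanOutcome(
        results=res, flagged=flagged, alpha=alpha, n_het=n_het,
        comparisons=[c[0] for c in comparisons],
    )


def _orient_parental(wide: pd.DataFrame, pg: pd.DataFrame,
                     female: int, male: int) -> tuple[np.ndarray, pd.DataFrame]:
    fam_pg = pg[(pg["female"] == female) & (pg["male"] == male)].set_index("marker_id")
    fam_pg = fam_pg.reindex(wide.index)
    unknown = fam_pg["female_gt"].isna()
    if unknown.any():
        raise ScanError(
            f"{int(unknown.sum())} markers absent from the parental table"
        )
    informative = (
        (fam_pg["female_gt"] == "hom_ref") & (fam_pg["male_gt"] == "hom_alt")
    ) | ((fam_pg["female_gt"] == "hom_alt") & (fam_pg["male_gt"] == "hom_ref"))
    if not informative.all():
        raise ScanError("haplotype/contig scans require informative markers only")
    female_is_ref = (fam_pg["female_gt"] == "hom_ref").to_numpy()
    return female_is_ref, fam_pg


def _maternal_paternal(wide, female_is_ref, day, size_group):
    ref = _col(wide, "ref_count", day, size_group)
    alt = _col(wide, "alt_count", day, size_group)
    if ref is None:
        return None, None
    maternal = np.where(female_is_ref, ref, alt)
    paternal = np.where(female_is_ref, alt, ref)
    return maternal, paternal


def haplotype_scan(
    table: pd.DataFrame,
    pg: pd.DataFrame,
    markers: Iterable[str],
    female: int,
    male: int,
    replicate: int,
    config: ScanConfig | None = None,
) -> ScanOutcome:
    """Maternal vs paternal read-count tests, day 0 vs day 23, with q-values.

    Each comparison (Big, Small) forms its own q-value family; a marker is
    flagged when q < ``q_threshold`` in every available comparison.  The
    test statistic is invariant to the parental orientation flip.
    """
    config = config or ScanConfig()
    wide = _replicate_wide(table, markers, female, male, replicate)
    groups = _available_d23_groups(wide)
    if not groups:
        raise ScanError(f"F{female}.M{male}.R{replicate} has no day-23 sample")
    female_is_ref, _ = _orient_parental(wide, pg, female, male)
    mat0, pat0 = _maternal_paternal(wide, female_is_ref, 0, None)
    frames = []
    for g in groups:
        mat1, pat1 = _maternal_paternal(wide, female_is_ref, 23, g)
        stat, p = _chisq_vec(mat0, pat0, mat1, pat1, yates=config.yates)
        q = qvalues(p, config.fdr_method, config.storey_min_tests)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = pat1 / (mat1 + pat1) - pat0 / (mat0 + pat0)
        frames.append(
            pd.DataFrame(
                {
                    "unit": wide.index,
                    "comparison": f"D0-vs-D23{g}",
                    "statistic": stat,
                    "p_value": p,
                    "q_value": q,
                    "significant": q < config.q_threshold,
                    "direction": _direction(delta),
                }
            )
        )
    res = pd.concat(frames, ignore_index=True)
    per_unit = res.groupby("unit", observed=True).agg(
        n_avail=("p_value", lambda s: int(np.isfinite(s).sum())),
        n_sig=("significant", "sum"),
    )
    flagged = sorted(
        per_unit.index[(per_unit["n_avail"] > 0) & (per_unit["n_sig"] == per_unit["n_avail"])]
    )
    return ScanOutcome(
        results=res, flagged=flagged, alpha=None, n_het=None,
        comparisons=[f"D0-vs-D23{g}" for g in groups],
    )


def contig_scan(
    table: pd.DataFrame,
    pg: pd.DataFrame,
    markers: Iterable[str],
    female: int,
    male: int,
    replicate: int,
    config: ScanConfig | None = None,
) -> ContigScanOutcome:
    """Haplotype-count tests on contig-summed reads.

    Per contig, maternal/paternal read totals are the sums over member
    markers (nonmissing cells).  ``D0-vs-D23`` requires the Big — and,
    when recovered, the Small — test at q < 0.05; ``D16-vs-D23`` uses the
    Big pool.  The reported set is the intersection of the two
    comparisons' significant contigs.
    """
    config = config or ScanConfig()
    wide = _replicate_wide(table, markers, female, male, replicate)
    groups = _available_d23_groups(wide)
    if not groups:
        raise ScanError(f"F{female}.M{male}.R{replicate} has no day-23 sample")
    female_is_ref, _ = _orient_parental(wide, pg, female, male)

    contig_of = (
        table[table["marker_id"].isin(set(markers))][["marker_id", "contig"]]
        .drop_duplicates()
        .set_index("marker_id")["contig"]
        .reindex(wide.index)
    )

    def contig_sums(day, size_group):
        mat, pat = _maternal_paternal(wide, female_is_ref, day, size_group)
        if mat is None:
            return None
        df = pd.DataFrame({"contig": contig_of.to_numpy(), "mat": mat, "pat": pat})
        return df.groupby("contig", observed=True)[["mat", "pat"]].sum(min_count=1)

    sums = {("d0", None): contig_sums(0, None), ("d16", None): contig_sums(16, None)}
    for g in groups:
        sums[("d23", g)] = contig_sums(23, g)

    frames = []
    sig: dict[str, set[str]] = {}

    def run(label, start, end, family_label):
        s, e = sums[start], sums[end]
        if s is None or e is None:
            return
        idx = s.index
        stat, p = _chisq_vec(
            s["mat"].to_numpy(), s["pat"].to_numpy(),
            e["mat"].reindex(idx).to_numpy(), e["pat"].reindex(idx).to_numpy(),
            yates=config.yates,
        )
        q = qvalues(p, config.fdr_method, config.storey_min_tests)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = (
                e["pat"].reindex(idx) / (e["mat"].reindex(idx) + e["pat"].reindex(idx))
                - s["pat"] / (s["mat"] + s["pat"])
            ).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "unit": idx,
                    "comparison": label,
                    "statistic": stat,
                    "p_value": p,
                    "q_value": q,
                    "significant": q < config.q_threshold,
                    "direction": _direction(delta),
                }
            )
        )
        flagged = set(idx[q < config.q_threshold])
        sig.setdefault(family_label, set())
        # within a comparison family, require every constituent test
        if family_label in done_families:
            sig[family_label] &= flagged
        else:
            sig[family_label] |= flagged
            done_families.add(family_label)

    done_families: set[str] = set()
    for g in groups:
        run(f"D0-vs-D23{g}", ("d0", None), ("d23", g), "D0-vs-D23")
    run("D16-vs-D23Big", ("d16", None), ("d23", "Big"), "D16-vs-D23")

    res = pd.concat(frames, ignore_index=True)
    inter: set[str] | None = None
    for fam_label, flag in sig.items():
        inter = flag if inter is None else inter & flag
    return ContigScanOutcome(
        results=res,
        significant={k: sorted(v) for k, v in sig.items()},
        intersection=sorted(inter or set()),
    )


def size_scan(
    table: pd.DataFrame,
    markers: Iterable[str],
    female: int,
    male: int,
    replicate: int,
    n_het: int,
    config: ScanConfig | None = None,
) -> ScanOutcome:
    """Day-23 Big vs Small allele-count test at the 0.05/nHet threshold."""
    config = config or ScanConfig()
    alpha = config.adjusted_alpha(n_het)
    wide = _replicate_wide(table, markers, female, male, replicate)
    groups = _available_d23_groups(wide)
    if set(groups) != {"Big", "Small"}:
        raise ScanError(
            f"F{female}.M{male}.R{replicate} lacks a day-23 size group: {groups}"
        )
    res = _per_marker_tests(wide, [("D23Big-vs-D23Small", (23, "Big"), (23, "Small"))],
                            config.yates)
    res["q_value"] = np.nan
    res["significant"] = res["p_value"] < alpha
    flagged = sorted(res.loc[res["significant"], "unit"])
    return ScanOutcome(
        results=res, flagged=flagged, alpha=alpha, n_het=n_het,
        comparisons=["D23Big-vs-D23Small"],
    )


# ---------------------------------------------------------------------------
# overlap logic


@dataclass
class OverlapReport:
    intersection: list[str]
    set_sizes: list[int]
    pairwise: dict[tuple[int, int], int] = field(default_factory=dict)


def overlap_sets(*sets: Iterable[str]) -> OverlapReport:
    """Exact intersection of >= 2 marker/contig id sets, with size report."""
    if len(sets) < 2:
        raise ScanError("overlap_sets needs at least 2 sets")
    as_sets = [set(s) for s in sets]
    inter = set.intersection(*as_sets)
    pairwise = {
        (i, j): len(as_sets[i] & as_sets[j])
        for i in range(len(as_sets))
        for j in range(i + 1, len(as_sets))
    }
    return OverlapReport(
        intersection=sorted(inter),
        set_sizes=[len(s) for s in as_sets],
        pairwise=pairwise,
    )
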