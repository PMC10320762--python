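"""Replicate-level summary tables, phenotype correlations and the pipeline.

Summary rows follow the study's table conventions: per replicate the
heterozygous marker count (nHet), significant-marker counts per
comparison, the viability-associated SNP count and its percentage of
nHet, monotone-trend counts, size-associated SNP counts, per-day mean
heterozygosity of the flagged set and day-23 divergence direction counts.
Percentages are ``100 * numerator / denominator`` rounded half-up to the
printed precision, and every percentage cell is recomputable from its own
numerator/denominator columns (a self-consistency audit enforces this).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .errors import LarvascanError, ParameterError, ScanError
from . import io_filtering as iof
from . import allele_dynamics as dyn
from . import selection_scan as scan
from . import trend_drift as td
from .synthetic_data import SimConfig, simulate_experiment

__all__ = [
    "percent",
    "build_summary",
    "audit_summary",
    "heterozygosity_summary",
    "survival_size_correlation",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ParameterError("zero denominator in percentage")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# summary assembly


def _count_sig(outcome: scan.ScanOutcome, comparison: str):
    sub = outcome.results[outcome.results["comparison"] == comparison]
    if sub.empty:
        return pd.NA
    return int(sub["significant"].sum())


def build_summary(replicate_blocks: Sequence[dict]) -> pd.DataFrame:
    """Assemble one summary row per replicate.

    Each block is a dict with keys ``female, male, replicate, n_het,
    viability`` (:class:`~larvascan.selection_scan.ScanOutcome`) and
    optionally ``size`` (ScanOutcome), ``trend`` (monotone-trend frame),
    ``overlap`` (int), ``size_overlap_chisq``/``size_overlap_trend``
    (ints).  Missing stages become NA cells, not failures.
    """
    rows = []
    for blk in replicate_blocks:
        n_het = blk["n_het"]
        via: scan.ScanOutcome | None = blk.get("viability")
        size: scan.ScanOutcome | None = blk.get("size")
        trend: pd.DataFrame | None = blk.get("trend")
        row = {
            "female": blk["female"],
            "male": blk["male"],
            "replicate": blk["replicate"],
            "n_het": n_het,
            "n_sig_big": _count_sig(via, "D0-vs-D23Big") if via is not None else pd.NA,
            "n_sig_small": _count_sig(via, "D0-vs-D23Small") if via is not None else pd.NA,
            "n_viability": len(via.flagged) if via is not None else pd.NA,
            "overlap": blk.get("overlap", pd.NA),
            "pct_viability": percent(len(via.flagged), n_het, 3) if via is not None else pd.NA,
        }
        if trend is not None and not trend.empty:
            inc = int((trend["monotone"] & (trend["direction"] == "increasing")).sum())
            dec = int((trend["monotone"] & (trend["direction"] == "decreasing")).sum())
        elif trend is not None:
            inc = dec = 0
        else:
            inc = dec = None
        row["n_trend_increasing"] = inc if inc is not None else pd.NA
        row["n_trend_decreasing"] = dec if dec is not None else pd.NA
        row["pct_trend"] = percent(inc + dec, n_het, 2) if inc is not None else pd.NA
        row["n_size"] = len(size.flagged) if size is not None else pd.NA
        row["pct_size"] = percent(len(size.flagged), n_het, 2) if size is not None else pd.NA
        row["size_overlap_chisq"] = blk.get("size_overlap_chisq", pd.NA)
        row["size_overlap_trend"] = blk.get("size_overlap_trend", pd.NA)
        rows.append(row)
        if via is None or size is None or trend is None:
            logger.info(
                "replicate F%s.M%s.R%s summarized with missing stages",
                blk["female"], blk["male"], blk["replicate"],
            )
    out = pd.DataFrame(rows)
    audit_summary(out)
    return out


def audit_summary(summary: pd.DataFrame) -> None:
    """Re-derive every percentage from its numerator/denominator columns."""
    for _, row in summary.iterrows():
        checks = [
            ("pct_viability", row["n_viability"], row["n_het"], 3),
            ("pct_size", row["n_size"], row["n_het"], 2),
        ]
        if not pd.isna(row["n_trend_increasing"]):
            checks.append(
                ("pct_trend", row["n_trend_increasing"] + row["n_trend_decreasing"],
                 row["n_het"], 2)
            )
        for col, num, den, dec in checks:
            if pd.isna(row[col]) or pd.isna(num):
                continue
            expected = percent(num, den, dec)
            if row[col] != expected:
                raise LarvascanError(
                    f"summary audit failed: {col}={row[col]} but {num}/{den} -> {expected}"
                )


def heterozygosity_summary(
    freqs: pd.DataFrame,
    markers: Sequence[str],
    female: int,
    male: int,
    replicate: int,
) -> dict:
    """Per-day mean heterozygosity and day-23 divergence of a marker set."""
    hets = dyn.sample_mean_heterozygosity(
        freqs[
            (freqs["female"] == female)
            & (freqs["male"] == male)
            & ((freqs["replicate"] == replicate) | freqs["replicate"].isna())
        ],
        markers,
    )
    out = {"female": female, "male": male, "replicate": replicate,
           "n_markers": len(set(markers))}
    for _, row in hets.iterrows():
        day = int(row["day"])
        sg = row["size_group"]
        label = f"het_d{day}" + (str(sg).lower() if pd.notna(sg) else "")
        out[label] = float(row["mean_heterozygosity"])
    for group in ("Big", "Small"):
        try:
            div = dyn.divergence_direction(freqs, markers, female, male, replicate,
                                           size_group=group)
        except Exception:
            continue
        n = div.increase + div.decrease + div.ties
        if n == 0:
            continue
        out[f"divergence_increase_{group.lower()}"] = div.increase
        out[f"divergence_decrease_{group.lower()}"] = div.decrease
        out[f"divergence_ties_{group.lower()}"] = div.ties
        out[f"pct_increase_{group.lower()}"] = percent(div.increase, n, 2)
        out[f"pct_decrease_{group.lower()}"] = percent(div.decrease, n, 2)
    return out


# ---------------------------------------------------------------------------
# phenotype correlation


def survival_size_correlation(
    phenotypes: pd.DataFrame,
    exclude: Sequence[tuple[int, int, int]] = (),
    day: int = 23,
) -> tuple[float, float, int]:
    """Pearson correlation of day-23 survival count and mean size.

    One point per replicate tank; outlier exclusion is an explicit list of
    (female, male, replicate) ids, never automatic.  Returns ``(r, p, n)``;
    a zero-variance input is reported as undefined (NaN, NaN, n).
    """
    pts = phenotypes[phenotypes["day"] == day].copy()
    if exclude:
        drop = pts.apply(
            lambda r: (r["female"], r["male"], r["replicate"]) in set(exclude), axis=1
        )
        pts = pts[~drop]
    pts = pts.dropna(subset=["survival_count", "mean_size"])
    n = len(pts)
    if n < 3:
        raise ParameterError(f"need >= 3 replicates for a correlation, have {n}")
    x = pts["survival_count"].to_numpy(dtype=float)
    y = pts["mean_size"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    counts: pd.DataFrame
    freqs: pd.DataFrame
    het_markers: dict
    summary: pd.DataFrame
    het_summaries: list[dict]
    replicate_blocks: list[dict]
    manifest: dict
    truth: object | None = None
    phenotypes: pd.DataFrame | None = None


def run_pipeline(
    config: SimConfig | None = None,
    counts: pd.DataFrame | None = None,
    parental: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    scan_config: scan.ScanConfig | None = None,
    drift_n_sims: int = 0,
) -> PipelineResult:
    """Filter -> dynamics -> scans -> trend (-> drift) -> summary.

    Either a :class:`SimConfig` (synthetic run) or explicit ``counts`` and
    ``parental`` tables must be supplied.  Writes TSV/JSON artifacts and a
    reproducibility manifest when ``out_dir`` is given.
    """
    scan_config = scan_config or scan.ScanConfig()
    truth = phenotypes = None
    if config is not None:
        if seed is not None:
            config = SimConfig(**{**config.__dict__, "seed": seed})
        sim = simulate_experiment(config)
        counts, parental = sim.counts, sim.parental
        truth, phenotypes = sim.truth, sim.phenotypes
        source = {"kind": "synthetic", "config": {k: (np.asarray(v).tolist()
                  if isinstance(v, np.ndarray) else v) for k, v in config.__dict__.items()}}
    elif counts is None or parental is None:
        raise ParameterError("need a SimConfig or counts + parental tables")
    else:
        source = {"kind": "tables"}

    pg = iof.filter_parental_depth(parental)
    counts_f = iof.apply_zero_recovery_rule(counts)
    het_markers, filter_report = iof.select_heterozygous_markers(counts_f, pg)
    freqs = dyn.compute_allele_freq(counts_f)

    blocks: list[dict] = []
    het_summaries: list[dict] = []
    for (f, m, r), markers in sorted(het_markers.items()):
        if not markers:
            logger.warning("F%d.M%d.R%d: no heterozygous markers; skipped", f, m, r)
            continue
        n_het = len(markers)
        blk: dict = {"female": f, "male": m, "replicate": r, "n_het": n_het,
                     "markers": markers}
        try:
            blk["viability"] = scan.viability_scan(
                counts_f, markers, f, m, r, n_het, scan_config)
        except ScanError as exc:
            raise ScanError(f"viability scan failed for F{f}.M{m}.R{r}: {exc}") from exc
        try:
            blk["size"] = scan.size_scan(counts_f, markers, f, m, r, n_het, scan_config)
        except ScanError:
            blk["size"] = None
        blk["haplotype"] = scan.haplotype_scan(counts_f, pg, markers, f, m, r, scan_config)
        blk["contig"] = scan.contig_scan(counts_f, pg, markers, f, m, r, scan_config)
        sig_contigs = set(blk["contig"].intersection)
        members = freqs[
            (freqs["female"] == f) & (freqs["male"] == m)
            & freqs["marker_id"].isin(markers) & freqs["contig"].isin(sig_contigs)
        ]["marker_id"].unique()
        blk["trend"] = td.monotonic_trend_markers(freqs, members, f, m, r)
        trend_flagged = (
            set(blk["trend"].loc[blk["trend"]["monotone"], "marker_id"])
            if not blk["trend"].empty else set()
        )
        blk["trend_flagged"] = sorted(trend_flagged)
        if blk["size"] is not None:
            blk["size_overlap_chisq"] = len(set(blk["size"].flagged)
                                            & set(blk["viability"].flagged))
            blk["size_overlap_trend"] = len(set(blk["size"].flagged) & trend_flagged)
        if drift_n_sims:
            drift = td.drift_for_markers(
                counts_f, freqs, blk["viability"].flagged, f, m, r,
                n_sims=drift_n_sims, seed=seed,
            )
            blk["drift"] = drift
            blk["mean_chance_of_drift"] = (
                float(drift["chance_of_drift"].mean()) if len(drift) else float("nan")
            )
        if blk["viability"].flagged:
            het_summaries.append(
                heterozygosity_summary(freqs, blk["viability"].flagged, f, m, r)
            )
        blocks.append(blk)

    summary = build_summary(blocks) if blocks else pd.DataFrame()
    manifest = {
        "package_version": __version__,
        "source": source,
        "seed": seed,
        "thresholds": {
            "parental_min_depth": 40,
            "allele_min_depth": 20,
            "alpha_base": scan_config.alpha_base,
            "q_threshold": scan_config.q_threshold,
            "yates": scan_config.yates,
            "fdr_method": scan_config.fdr_method,
        },
        "filter_report": filter_report.__dict__,
        "n_replicates_analyzed": len(blocks),
    }
    result = PipelineResult(
        counts=counts_f, freqs=freqs, het_markers=het_markers, summary=summary,
        het_summaries=het_summaries, replicate_blocks=blocks, manifest=manifest,
        truth=truth, phenotypes=phenotypes,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    iof.write_pool_counts(result.counts, out_dir / "counts.filtered.tsv")
    result.freqs.to_csv(out_dir / "frequencies.tsv", sep="\t", index=False)
    if not result.summary.empty:
        result.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    for blk in result.replicate_blocks:
        tag = f"F{blk['female']}.M{blk['male']}.R{blk['replicate']}"
        for key in ("viability", "size", "haplotype"):
            if blk.get(key) is not None:
                blk[key].results.to_csv(out_dir / f"scan.{key}.{tag}.tsv",
                                        sep="\t", index=False)
        blk["contig"].results.to_csv(out_dir / f"scan.contig.{tag}.tsv",
                                     sep="\t", index=False)
        if blk.get("trend") is not None and not blk["trend"].empty:
            blk["trend"].to_csv(out_dir / f"trend.{tag}.tsv", sep="\t", index=False)
    with open(out_dir / "het_summaries.json", "w") as fh:
        json.dump(result.het_summaries, fh, indent=2, default=float)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
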