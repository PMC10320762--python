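"""Synthetic pool-seq larval cohort generator with known ground truth.

Emulates the statistical structure of a single-generation mussel larval
experiment: an NC-II factorial cross (every female mated to every male),
replicate tanks of ~1e5 fertilized embryos undergoing type-III mortality
across sampling days 0/11/16/23, stage-specific viability selection at
planted loci, a polygenic size liability that splits day-23 survivors into
Big/Small sieve fractions, and two-stage pooled sequencing (an individual
subsample followed by binomial read counts at negative-binomial depth).

Every marker is "informative": the parental calls are opposite homozygotes,
the maternal allele is the reference and the paternal allele the
alternative, so the expected F1 pool frequency is 0.5.  Cohort genotypes
segregate (Hardy-Weinberg at the marker's day-0 frequency) rather than
being uniformly heterozygous: a literally all-het cohort admits neither
drift nor a selection response, and observed day-0 heterozygosity in real
pooled data sits well below the theoretical 0.25, so causal day-0
frequencies are drawn off-centre (see ``SimConfig.causal_p0_range``).

Fitness is multiplicative per allele copy, ``w = prod_l (1+s_l)^x_l`` with
``x`` the dose of the focal (alternative) allele, which makes the expected
one-locus response follow the classical recursion
``p' = p(1+s) / (1+ps)`` exactly (additive on the logit scale).

Planted viability loci occupy whole contigs: all markers of a selected
contig are fully linked to one causal genotype, mirroring the physical
linkage that makes the contig-sum haplotype test informative.  Size loci
are independent single markers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError

__all__ = [
    "SimConfig",
    "SimTruth",
    "MarkerLayout",
    "Cohort",
    "SimResult",
    "simulate_cross",
    "apply_stage_selection",
    "assign_size_groups",
    "sample_pool_reads",
    "simulate_experiment",
]

#: sampling days of the phenotyping protocol
DAYS = (0, 11, 16, 23)
#: survival stages between consecutive sampling days
STAGES = ((0, 11), (11, 16), (16, 23))


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults are the study conditions: a 4 female x 2 male factorial cross,
    3 replicate tanks per family, 120,000 fertilized embryos per replicate,
    and a survival schedule compounding to 9% day-0 to day-23 survival
    (within the 2-20% window typical of type-III broadcast spawners).
    """

    n_females: int = 4
    n_males: int = 2
    n_replicates: int = 3
    n_markers: int = 2000
    n_contigs: int = 200
    start_cohort_size: int = 120_000
    #: per-stage survival fractions for D0->D11, D11->D16, D16->D23
    survival_schedule: tuple[float, float, float] = (0.45, 0.5, 0.4)
    n_viability_loci: int = 0
    n_size_loci: int = 0
    #: per-stage selection coefficient magnitude at viability loci
    viability_s: float = 0.6
    #: "directional": constant sign pushing the initially-minor focal allele
    #: toward loss (the classic diversity-eroding sweep); "balancing": sign
    #: alternates between stages, first stage oriented toward 0.5 (restoring)
    selection_regime: str = "directional"
    #: optional explicit (n_viability_contigs, 3) per-stage coefficients
    selection_coeffs: np.ndarray | None = None
    #: liability-scale effect per focal-allele copy at size loci; for a
    #: median sieve split the per-locus Big/Small frequency gap is
    #: 0.8*e*Var(dose)/sd(liability), so 0.54 gives ~0.2 for a single size
    #: locus and polygenic architectures dilute it by the total sd
    size_effect_scale: float = 0.54
    sieve_quantile: float = 0.5
    #: individuals drawn into each sequencing pool (capped at cohort size)
    pool_sample_size: int = 1000
    mean_depth: float = 100.0
    depth_dispersion: float = 0.2
    parent_mean_depth: float = 80.0
    #: minor-side day-0 frequency window for causal (viability) loci
    causal_p0_range: tuple[float, float] = (0.25, 0.40)
    #: replicate-level growth-rate spread (lognormal sd of mean size)
    growth_sd: float = 0.1
    #: >0 couples fast growth to reduced day-23 survival
    growth_survival_tradeoff: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_females, self.n_males, self.n_replicates) < 1:
            raise ConfigError("cross dimensions must be >= 1")
        if self.n_markers < 1 or self.n_contigs < 1 or self.n_contigs > self.n_markers:
            raise ConfigError("need 1 <= n_contigs <= n_markers")
        if self.start_cohort_size < 1:
            raise ConfigError("start_cohort_size must be positive")
        if len(self.survival_schedule) != len(STAGES):
            raise ConfigError("survival_schedule needs one fraction per stage")
        if not all(0 < f <= 1 for f in self.survival_schedule):
            raise ConfigError("survival fractions must lie in (0, 1]")
        if not 0 < self.sieve_quantile < 1:
            raise ConfigError("sieve_quantile must lie in (0, 1)")
        if self.n_viability_loci + self.n_size_loci > self.n_markers:
            raise ConfigError("more causal loci than markers")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")
        if self.selection_regime not in ("directional", "balancing"):
            raise ConfigError(f"unknown selection_regime {self.selection_regime!r}")

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        if d["selection_coeffs"] is not None:
            d["selection_coeffs"] = np.asarray(d["selection_coeffs"]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("selection_coeffs") is not None:
            d["selection_coeffs"] = np.asarray(d["selection_coeffs"], dtype=float)
        for key in ("survival_schedule", "causal_p0_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class MarkerLayout:
    """Static marker map: ids, contig membership and causal architecture.

    ``causal_col[i]`` indexes the causal genotype column backing marker ``i``
    (-1 for neutral markers); all markers of a planted viability contig share
    one column.  ``neutral_idx[i]`` indexes the marker's row in the neutral
    genotype-count array (-1 for causal markers).
    """

    marker_id: np.ndarray
    contig: np.ndarray
    position: np.ndarray
    label: np.ndarray  # "neutral" | "viability" | "size"
    causal_col: np.ndarray
    neutral_idx: np.ndarray
    causal_p0: np.ndarray  # day-0 alt frequency per causal column
    stage_s: np.ndarray  # (n_causal, n_stages) selection coefficients
    size_effect: np.ndarray  # liability effect per causal column

    @property
    def n_markers(self) -> int:
        return self.marker_id.size

    @property
    def n_causal(self) -> int:
        return self.causal_p0.size

    @property
    def n_neutral(self) -> int:
        return int((self.neutral_idx >= 0).sum())

    def marker_stage_s(self) -> np.ndarray:
        """Per-marker (n_markers, n_stages) selection coefficients."""
        out = np.zeros((self.n_markers, self.stage_s.shape[1] if self.n_causal else len(STAGES)))
        has = self.causal_col >= 0
        if self.n_causal:
            out[has] = self.stage_s[self.causal_col[has]]
        return out


@dataclass
class Cohort:
    """A set of individuals tracked at causal and neutral loci.

    Causal loci carry per-individual allele doses (small matrix); neutral
    loci carry genotype-class counts only, which is exact because uniform
    subsampling of individuals acts on unlinked neutral loci as a
    multivariate hypergeometric draw on (dose-0, dose-1, dose-2) counts.
    """

    n: int
    causal_dose: np.ndarray  # (n, n_causal) int8 doses of the alt allele
    neutral_counts: np.ndarray  # (n_neutral, 3) genotype counts

    def allele_freq(self, layout: MarkerLayout) -> np.ndarray:
        """True alt-allele frequency per marker in this cohort."""
        freq = np.empty(layout.n_markers)
        if self.n == 0:
            freq[:] = np.nan
            return freq
        if layout.n_causal:
            col = self.causal_dose.sum(axis=0, dtype=np.int64) / (2.0 * self.n)
        has = layout.causal_col >= 0
        if layout.n_causal:
            freq[has] = col[layout.causal_col[has]]
        nz = layout.neutral_idx >= 0
        counts = self.neutral_counts[layout.neutral_idx[nz]]
        freq[nz] = (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * self.n)
        return freq


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated counts."""

    labels: pd.Series  # marker_id -> neutral|viability|size
    stage_s: pd.DataFrame  # marker_id x stage selection coefficients
    true_freqs: pd.DataFrame  # marker,family,replicate,day,size_group,true_af
    config: SimConfig

    def markers(self, label: str) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "stage_s": {m: row.tolist() for m, row in zip(self.stage_s.index, self.stage_s.values)},
            "true_freqs": self.true_freqs.to_dict(orient="list"),
            "config": {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(self.config).items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SimResult:
    counts: pd.DataFrame
    parental: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# layout construction


def _build_layout(config: SimConfig, rng: np.random.Generator) -> MarkerLayout:
    n, nc = config.n_markers, config.n_contigs
    contig_of = np.sort(rng.permutation(np.arange(n) % nc))
    marker_id = np.array([f"M{i:06d}" for i in range(n)])
    contig = np.array([f"C{c:05d}" for c in contig_of])
    position = np.arange(n, dtype=np.int64) * 97 % 10_000 + 1

    label = np.full(n, "neutral", dtype=object)
    causal_col = np.full(n, -1, dtype=np.int64)
    p0_list: list[float] = []
    s_list: list[np.ndarray] = []
    eff_list: list[float] = []

    n_stages = len(STAGES)
    contig_order = rng.permutation(nc)
    # viability loci fill whole contigs (fully linked blocks)
    remaining = config.n_viability_loci
    ci = 0
    while remaining > 0:
        if ci >= nc:
            raise ConfigError("cannot place viability loci: not enough contigs")
        members = np.flatnonzero(contig_of == contig_order[ci])
        take = members[: min(remaining, members.size)]
        col = len(p0_list)
        label[take] = "viability"
        causal_col[take] = col
        minor = rng.uniform(*config.causal_p0_range)
        alt_is_minor = rng.random() < 0.5
        p0 = minor if alt_is_minor else 1.0 - minor
        if config.selection_coeffs is not None:
            s = np.asarray(config.selection_coeffs, dtype=float)[col % len(config.selection_coeffs)]
        else:
            step = config.viability_s
            # sign pushing the alt allele toward 0.5
            toward = 1.0 if p0 < 0.5 else -1.0
            if config.selection_regime == "directional":
                # constant sign away from 0.5: the minor allele is purged,
                # eroding heterozygosity stage after stage
                signs = np.full(n_stages, -toward)
            else:  # balancing: restoring, away, restoring, ...
                signs = toward * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_stages)])
            # equal logit step magnitude each stage: s or its reciprocal-1
            s = np.where(signs > 0, step, 1.0 / (1.0 + step) - 1.0)
        p0_list.append(p0)
        s_list.append(np.asarray(s, dtype=float))
        eff_list.append(0.0)
        remaining -= take.size
        ci += 1

    neutral_pool = np.flatnonzero(label == "neutral")
    size_pick = rng.choice(neutral_pool, size=config.n_size_loci, replace=False)
    for i in np.sort(size_pick):
        col = len(p0_list)
        label[i] = "size"
        causal_col[i] = col
        p0_list.append(0.5)
        s_list.append(np.zeros(n_stages))
        eff_list.append(config.size_effect_scale)

    neutral_idx = np.full(n, -1, dtype=np.int64)
    nz = np.flatnonzero(label == "neutral")
    neutral_idx[nz] = np.arange(nz.size)

    stage_s = np.array(s_list).reshape(len(p0_list), n_stages) if p0_list else np.zeros((0, n_stages))
    return MarkerLayout(
        marker_id=marker_id,
        contig=contig,
        position=position,
        label=label,
        causal_col=causal_col,
        neutral_idx=neutral_idx,
        causal_p0=np.asarray(p0_list),
        stage_s=stage_s,
        size_effect=np.asarray(eff_list),
    )


def _init_cohort(layout: MarkerLayout, n: int, rng: np.random.Generator) -> Cohort:
    dose = rng.binomial(2, layout.causal_p0, size=(n, layout.n_causal)).astype(np.int8)
    # neutral markers segregate Hardy-Weinberg at 0.5
    counts = rng.multinomial(n, [0.25, 0.5, 0.25], size=layout.n_neutral)
    return Cohort(n=n, causal_dose=dose, neutral_counts=counts)


def _subsample_neutral(counts: np.ndarray, total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k individuals without replacement; per-marker genotype counts."""
    if counts.shape[0] == 0:
        return counts[:0].copy()
    n0 = rng.hypergeometric(counts[:, 0], total - counts[:, 0], k)
    rest = total - counts[:, 0]
    n1 = np.where(
        rest > 0,
        rng.hypergeometric(np.maximum(counts[:, 1], 0), np.maximum(rest - counts[:, 1], 0), k - n0),
        0,
    )
    n2 = k - n0 - n1
    return np.stack([n0, n1, n2], axis=1)


def _take_individuals(cohort: Cohort, idx: np.ndarray, rng: np.random.Generator) -> Cohort:
    k = idx.size
    return Cohort(
        n=k,
        causal_dose=cohort.causal_dose[idx],
        neutral_counts=_subsample_neutral(cohort.neutral_counts, cohort.n, k, rng),
    )


# ---------------------------------------------------------------------------
# operations


def simulate_cross(config: SimConfig, rng: np.random.Generator | None = None):
    """Build the factorial cross: marker layout, parental calls and cohorts.

    Returns ``(layout, parental, populations, cohorts)`` where
    ``populations[(f, m)]`` is the pre-split fertilized population of a
    family (the day-0 sampling unit) and ``cohorts[(f, m, r)]`` the
    replicate tanks, each of ``start_cohort_size`` individuals.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = _build_layout(config, rng)

    rows = []
    populations: dict[tuple[int, int], Cohort] = {}
    cohorts: dict[tuple[int, int, int], Cohort] = {}
    for f in range(1, config.n_females + 1):
        for m in range(1, config.n_males + 1):
            fdep = rng.poisson(config.parent_mean_depth, layout.n_markers)
            mdep = rng.poisson(config.parent_mean_depth, layout.n_markers)
            for i in range(layout.n_markers):
                rows.append(
                    (layout.marker_id[i], layout.contig[i], int(layout.position[i]),
                     f, m, "hom_ref", "hom_alt", int(fdep[i]), int(mdep[i]))
                )
            pop = _init_cohort(layout, config.n_replicates * config.start_cohort_size, rng)
            populations[(f, m)] = pop
            perm = rng.permutation(pop.n)
            for r in range(1, config.n_replicates + 1):
                idx = perm[(r - 1) * config.start_cohort_size: r * config.start_cohort_size]
                cohorts[(f, m, r)] = _take_individuals(pop, idx, rng)
    parental = pd.DataFrame(
        rows,
        columns=["marker_id", "contig", "position", "female", "male",
                 "female_gt", "male_gt", "female_depth", "male_depth"],
    )
    return layout, parental, populations, cohorts


def apply_stage_selection(
    cohort: Cohort,
    stage_s: np.ndarray,
    survival_fraction: float,
    rng: np.random.Generator,
) -> Cohort:
    """One mortality episode with per-locus viability selection.

    Individual survival probability is proportional to
    ``prod_l (1+s_l)^(dose_l)`` and rescaled so the expected survivor count
    equals ``survival_fraction * cohort.n``; survivors are an independent
    Bernoulli thinning (so the expected one-locus response is exactly
    ``p' = p(1+s)/(1+ps)``).
    """
    if cohort.n == 0:
        raise ParameterError("cohort is empty")
    if not 0 < survival_fraction <= 1:
        raise ParameterError("survival_fraction must lie in (0, 1]")
    stage_s = np.asarray(stage_s, dtype=float)
    if np.any(stage_s <= -1):
        raise ParameterError("selection coefficient <= -1 gives nonpositive fitness")
    if stage_s.size:
        logw = cohort.causal_dose @ np.log1p(stage_s)
        w = np.exp(logw - logw.max())
    else:
        w = np.ones(cohort.n)
    p = survival_fraction * cohort.n * w / w.sum()
    if p.max() > 1:
        p = np.minimum(p, 1.0)
    survive = rng.random(cohort.n) < p
    idx = np.flatnonzero(survive)
    return _take_individuals(cohort, idx, rng)


def assign_size_groups(
    cohort: Cohort,
    size_effects: np.ndarray,
    sieve_quantile: float,
    rng: np.random.Generator,
) -> tuple[Cohort, Cohort]:
    """Split day-23 survivors into (Big, Small) at a sieve quantile.

    Size liability is ``sum_l effect_l * dose_l + N(0, 1)`` noise; the top
    ``1 - sieve_quantile`` fraction is Big.  Returns ``(big, small)``.
    """
    if cohort.n == 0:
        warnings.warn("empty cohort: no size groups assigned", stacklevel=2)
        return cohort, cohort
    size_effects = np.asarray(size_effects, dtype=float)
    liability = rng.standard_normal(cohort.n)
    if size_effects.size:
        liability = liability + cohort.causal_dose @ size_effects
    order = np.argsort(liability, kind="stable")
    n_small = int(np.floor(sieve_quantile * cohort.n))
    small = _take_individuals(cohort, order[:n_small], rng)
    big = _take_individuals(cohort, order[n_small:], rng)
    return big, small


def sample_pool_reads(
    cohort: Cohort,
    layout: MarkerLayout,
    pool_sample_size: int,
    mean_depth: float,
    depth_dispersion: float,
    rng: np.random.Generator,
    *,
    female: int,
    male: int,
    replicate: int | None,
    day: int,
    size_group: str | None = None,
) -> pd.DataFrame:
    """Two-stage pooled sequencing of a cohort or size group.

    A subsample of ``pool_sample_size`` individuals (all of them when the
    cohort is smaller) defines the pool allele frequency; per marker the
    depth is negative-binomial around ``mean_depth`` (Poisson when
    ``depth_dispersion`` is 0) and the alternative-read count binomial at
    the pool frequency.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if depth_dispersion < 0:
        raise ParameterError("depth_dispersion must be >= 0")
    k = min(pool_sample_size, cohort.n)
    if k == 0:
        raise ParameterError("cannot sequence an empty pool")
    if k < cohort.n:
        idx = rng.choice(cohort.n, size=k, replace=False)
        pool = _take_individuals(cohort, idx, rng)
    else:
        pool = cohort
    freq = pool.allele_freq(layout)

    m = layout.n_markers
    if depth_dispersion == 0:
        depth = rng.poisson(mean_depth, m)
    else:
        r = 1.0 / depth_dispersion
        depth = rng.negative_binomial(r, r / (r + mean_depth), m)
    alt = rng.binomial(depth, freq)
    return pd.DataFrame(
        {
            "marker_id": layout.marker_id,
            "contig": layout.contig,
            "position": layout.position,
            "female": female,
            "male": male,
            "replicate": pd.array([replicate] * m, dtype="Int64"),
            "day": day,
            "size_group": pd.array([size_group] * m, dtype="string"),
            "ref_count": pd.array(depth - alt, dtype="Int64"),
            "alt_count": pd.array(alt, dtype="Int64"),
        }
    )


# ---------------------------------------------------------------------------
# end-to-end experiment


def _truth_rows(layout, cohort, female, male, replicate, day, size_group, out):
    freq = cohort.allele_freq(layout)
    out.append(
        pd.DataFrame(
            {
                "marker_id": layout.marker_id,
                "female": female,
                "male": male,
                "replicate": pd.array([replicate] * layout.n_markers, dtype="Int64"),
                "day": day,
                "size_group": pd.array([size_group] * layout.n_markers, dtype="string"),
                "true_af": freq,
            }
        )
    )


#: mean larval size (um) at each sampling day, before replicate growth scatter
SIZE_BASELINE_UM = {0: 70.0, 11: 110.0, 16: 130.0, 23: 160.0}


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full design and emit counts, parental calls and ground truth.

    Day-0 pools are sampled from each family's fertilized population before
    the replicate split; each replicate tank is then carried through the
    three survival stages, sieved into Big/Small on day 23, and pooled-
    sequenced on every sampling day.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout, parental, populations, cohorts = simulate_cross(config, rng)

    count_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    pheno_rows: list[tuple] = []
    for (f, m), pop in populations.items():
        _truth_rows(layout, pop, f, m, None, 0, None, truth_frames)
        count_frames.append(
            sample_pool_reads(
                pop, layout, config.pool_sample_size, config.mean_depth,
                config.depth_dispersion, rng,
                female=f, male=m, replicate=None, day=0, size_group=None,
            )
        )
        for r in range(1, config.n_replicates + 1):
            cohort = cohorts[(f, m, r)]
            growth = rng.normal(0.0, 1.0)
            size_scale = float(np.exp(config.growth_sd * growth))
            pheno_rows.append((f, m, r, 0, cohort.n, SIZE_BASELINE_UM[0] * size_scale))
            for stage, (d_from, d_to) in enumerate(STAGES):
                frac = config.survival_schedule[stage]
                if d_to == 23 and config.growth_survival_tradeoff:
                    frac = float(
                        np.clip(frac * np.exp(-config.growth_survival_tradeoff * growth), 1e-6, 1.0)
                    )
                s_vec = layout.stage_s[:, stage] if layout.n_causal else np.empty(0)
                cohort = apply_stage_selection(cohort, s_vec, frac, rng)
                pheno_rows.append((f, m, r, d_to, cohort.n, SIZE_BASELINE_UM[d_to] * size_scale))
                if d_to < 23:
                    _truth_rows(layout, cohort, f, m, r, d_to, None, truth_frames)
                    count_frames.append(
                        sample_pool_reads(
                            cohort, layout, config.pool_sample_size, config.mean_depth,
                            config.depth_dispersion, rng,
                            female=f, male=m, replicate=r, day=d_to, size_group=None,
                        )
                    )
            big, small = assign_size_groups(cohort, layout.size_effect, config.sieve_quantile, rng)
            for group, name in ((big, "Big"), (small, "Small")):
                _truth_rows(layout, group, f, m, r, 23, name, truth_frames)
                count_frames.append(
                    sample_pool_reads(
                        group, layout, config.pool_sample_size, config.mean_depth,
                        config.depth_dispersion, rng,
                        female=f, male=m, replicate=r, day=23, size_group=name,
                    )
                )

    counts = pd.concat(count_frames, ignore_index=True)
    truth = SimTruth(
        labels=pd.Series(layout.label, index=layout.marker_id, name="label"),
        stage_s=pd.DataFrame(
            layout.marker_stage_s(), index=layout.marker_id,
            columns=[f"stage_{a}_{b}" for a, b in STAGES],
        ),
        true_freqs=pd.concat(truth_frames, ignore_index=True),
        config=config,
    )
    phenotypes = pd.DataFrame(
        pheno_rows, columns=["female", "male", "replicate", "day", "survival_count", "mean_size"]
    )
    return SimResult(counts=counts, parental=parental, phenotypes=phenotypes, truth=truth)
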