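# Methods

## The experimental design being modeled

`larvascan` analyzes pooled sequencing of larval cohorts from a factorial
(NC-II) cross: every female is mated to every male (default 4 × 2), each
family is reared in replicate tanks (default 3) stocked with 120,000
fertilized embryos, and cohorts are phenotyped and pool-sequenced on days
0, 11, 16 and 23. Day-0 samples are taken from each family's fertilized
population before the replicate split, so they carry no replicate id and
are shared by the family's tanks. On day 23 a sieve divides survivors into
Big and Small fractions that are sequenced separately. Survival is
type III: the compounded survival schedule (default 0.45 × 0.5 × 0.4 = 9%)
sits inside the 2–20% window typical of broadcast-spawning bivalves.

Only markers whose two parents are homozygous for opposite alleles are
analyzed; the maternal allele is, by construction of the variant calls,
the reference allele, so every F1 individual is expected heterozygous and
the pooled alternative-allele frequency starts near 0.5. Changes in that
frequency over larval development are the signal of interest.

## Statistical procedures

**Frequencies.** `ref_af = ref_count / (ref_count + alt_count)` per
(marker, sample); day-0 "normalization" is the difference
`alt_af(t) − alt_af(day 0)` (a ratio would lose the [−1, 1] bounds and the
common-origin reading of trajectory plots; a difference also makes the
deltas invariant to a uniform additive shift).

**Filtering order.** (1) parental depth ≥ 40× (inclusive: "at least"
semantics; unknown depths fail), (2) the zero-recovery rule — within each
marker's per-tank series, an allele count of 0 followed by a positive
count of the same allele at a later day marks the whole (marker, sample)
cell missing, both alleles, since a vanished-and-returned marker cannot be
trusted at that time point; terminal zeros stand — then (3) the 20×
both-allele rule at every nonmissing time point, which defines the
per-tank heterozygous marker set and its size *nHet*. Cells masked by the
zero-recovery rule are exempt from the 20× rule (they are missing data,
not low data), which is why this order retains a superset of any ordering
that applies the depth rule first. All filters are idempotent.

**Scans.** Every test is a Pearson 2×2 chi-square (df = 1, no continuity
correction by default, since the uncorrected Pearson statistic is the
named procedure; a Yates flag exists because R's `chisq.test` default
differs). The viability scan tests (ref, alt) × (day 0, day 23) for the
Big and, when recovered, Small pools and flags a marker only when **all**
available tests beat α = 0.05/nHet — a per-replicate Bonferroni-style
rule that is deliberately stricter than FDR control. When a tank has only
a Big day-23 pool, that single test decides. The haplotype scan is the
same table re-anchored to maternal/paternal counts (the statistic is
invariant to the orientation flip; tests pin this), with q < 0.05 per
comparison family. The contig scan sums maternal/paternal reads over each
contig's markers — the statistic on summed counts is identical to the
2×2 test of the summed table — and intersects the day 0 vs day 23
significant set (Big and Small both required when both exist) with the
day 16 vs day 23 (Big) set. The size scan tests (ref, alt) × (Big, Small)
at α = 0.05/nHet.

**q-values.** Benjamini–Hochberg step-up (via statsmodels) scaled by
Storey's π₀, estimated on the λ grid 0.05–0.95 (step 0.05) with a cubic
polynomial smoother evaluated at λ = 0.95 and clipped to (1/m, 1].
Families smaller than 100 tests always use plain BH (π₀ = 1): the
smoother has nothing to smooth there, and BH is deterministic.
Families are scoped per replicate × comparison. Zero-marginal tables are
skipped with a log entry; expected cells < 5 are logged but the test is
still run, uniformly.

**Trend selection.** Within significant contigs, a marker is a trend
(viability) marker when the chained comparisons D0→D11, D11→D16,
D16→D23Big and D16→D23Small all strictly share one sign. Ties break
monotonicity (conservative); a missing Small pool drops that branch
(3 comparisons); a missing intermediate day is skipped and the remaining
days chained in order.

**Chance of drift.** The null holds the true frequency at the marker's
day-0 value and asks how often sampling noise alone produces a monotone
trajectory. For each comparison the start and end alternative-read counts
are drawn as independent binomials at that comparison's observed depths,
so the comparison signs are independent fair coins in the deep-coverage
limit and the probability of k strictly same-sign comparisons is exactly
2·(1/2)^k — 12.5% for the four-comparison design, 25% for three. This
independent-pairs construction is a deliberate choice: re-using a single
draw per time point chains the comparisons through shared endpoints and
drives the limit to 2·2/5! = 1/30 ≈ 3.3%, which is not the exchangeable
"half the loci move either way between any two time points" null this
summary is meant to quantify. Finite depth only lowers the probability
(ties), and estimates are deterministic under a fixed seed with standard
error ∝ 1/√n_sims. The joint probability across replicates is the
product, under independence of tanks.

**Percentages and audit.** Reported percentages are
100·numerator/denominator rounded half-up (decimal arithmetic, not
binary floats) to the table's printed precision. Every percentage column
in a summary is recomputed from its own numerator/denominator columns at
build time and a mismatch is an error, so a summary can never carry a
percentage its own counts do not support.

**Survival–size correlation.** Pearson r across replicate tanks between
day-23 survivor count and mean size (µm). Outlier exclusion is an
explicit, logged list of tank ids — never automatic.

## The synthetic-data generator

The generator emulates the statistical structure of the design, not its
molecular biology (no reads, no restriction sites, no growth dynamics).

**Genotypes.** Parental *calls* are opposite homozygotes at every marker,
but cohort genotypes segregate (Hardy–Weinberg) rather than being
uniformly heterozygous: a literally all-het cohort admits neither drift
nor any selection response, and observed day-0 pooled heterozygosity in
real data of this kind sits well below the theoretical 0.25, consistent
with reference bias and imperfect parental calls. Neutral markers start
at frequency 0.5; causal viability loci draw their day-0 minor-side
frequency from `causal_p0_range` (default 0.25–0.40, matching day-0
heterozygosity ≈ 0.19–0.24) on a random side.

**Architecture.** Planted viability loci fill whole contigs, with all
markers of a selected contig fully linked to one causal genotype — this
is what makes the contig-sum test informative, exactly as physical
linkage does in real data; an isolated causal marker inside a 10-marker
contig dilutes the summed signal tenfold. Size loci are independent
single markers.

**Selection.** Fitness is multiplicative per allele copy,
`w = ∏ (1+s)^x` with x the focal-allele dose, making the expected
one-locus response the classical recursion `p' = p(1+s)/(1+ps)` —
additive on the logit scale, which makes per-stage effects composable and
analytically checkable. Survivors are an independent Bernoulli thinning
with probabilities rescaled so the expected survivor count matches the
stage's survival fraction. Two regimes: *directional* applies a constant
sign pushing the initially-minor allele toward loss (the classic
diversity-eroding case — a constant sign pointed at 0.5 would park the
frequency there and raise heterozygosity instead); *balancing* alternates
the sign between stages with the first stage restoring (toward 0.5), so
the net displacement moves off-centre frequencies toward 0.5 and day-23
heterozygosity rises, the signature that separates the two regimes in the
tests. Coefficients ≤ −1 are rejected (non-positive fitness).

**Size split.** Liability = Σ effect·dose + standard normal noise; the
top 1−`sieve_quantile` fraction is Big. For a median split the per-locus
Big/Small frequency gap is ≈ 0.8·effect·Var(dose)/sd(liability), so the
gap *dilutes with the total polygenic variance*: effect 0.54 gives ≈ 0.2
for a single size locus, and 20 equal loci cap the per-locus gap near
0.13 no matter how large the effect. Test scenarios that need a 0.2 gap
therefore use an oligogenic architecture (5 loci, effect 0.82; exact
mixture calculation gives 0.200).

**Pooling noise.** Two stages: a subsample of `pool_sample_size`
individuals (default 1,000, inside the 48–11,625 range of real pools;
capped at the cohort size) sets the pool frequency, then per marker a
depth is drawn — negative-binomial with variance `µ + d·µ²`
(`depth_dispersion` d, default 0.2; Poisson at 0) — and the
alternative-read count is binomial at the pool frequency. Neutral loci
are tracked as genotype-class counts updated by vectorized multivariate
hypergeometric draws (exact, since uniform subsampling of individuals is
exchangeable across unlinked loci), so fully neutral experiments never
materialize individuals and run in seconds at cohort size 120,000.

**Phenotypes.** Replicate-level survival counts and mean sizes follow a
fixed per-day size baseline scaled by a lognormal tank growth factor; a
`growth_survival_tradeoff` > 0 couples fast growth to reduced day-23
survival, for exercising the correlation machinery. This is a summary-
level emulation, not a growth model.

**What passing tests do not show.** The generator has unlinked loci
(except within planted contigs), no genotyping error, no reference bias,
no shared environmental batch effects between tanks, and selection acts
only at planted loci. Recovery and error rates on synthetic data
therefore bound what the pipeline can do when its assumptions hold; they
do not certify performance on real libraries, where overdispersion
beyond the depth model (e.g. unequal individual contributions to the
pool) inflates the chi-square statistics.

## Problem sizes and numerical choices

Simulation-backed checks run at reduced but structurally faithful sizes,
chosen by a priori power analysis: type-I error on 20 neutral tanks of
2,000 markers at depth 100 (the both-pool rule makes the expected false
positives per tank ≪ 0.05, so the 20-tank total is held to a Poisson(1)
bound); viability recovery with 20 loci in 2 contigs among 2,000 markers
at depth 200, day-0 frequencies 0.40–0.48 and per-stage s = 0.55 —
strong enough for monotone steps (per-step z ≈ 2) yet ending near
frequency 0.17–0.27, clear of the 20× filter's cliff, where stronger
selection would push the selected markers out of the analyzed panel
entirely; size recovery with 5 loci of effect 0.82 on a 1,000-marker
panel at depth 300. Recovery is scored at family level: a planted locus
counts as found when flagged in at least one of the three tanks, the
same replication logic the cross design exists to provide. Cohort sizes
of 20,000–60,000 keep genetic drift negligible relative to pooling noise
while running in seconds; the defaults retain the full 120,000.

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives an
entire experiment; identical configs give byte-identical tables. Ties in
divergence direction are reported as a third class, never forced. Depth
specifications for the drift null accept a scalar, the five time-point
depths, or explicit per-comparison pairs.

## Known limitations

* The chi-square tests treat read counts as binomial given the pool;
  individual-level overdispersion is represented only through the
  two-stage pooling model.
* Storey's π₀ smoother is a cubic polynomial, not a smoothing spline;
  on the λ grid used the difference is far below the Monte-Carlo noise of
  any q-value decision, and small families fall back to BH regardless.
* The drift null is sampling-noise-only (true frequency fixed); a
  declining-population Wright–Fisher null would add genuine drift
  variance and lower monotonicity probabilities further, making the
  current null the conservative choice for claiming selection.
* VCF ingestion reads GT/DP only; genotype likelihoods are ignored.
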