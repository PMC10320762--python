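"""Generator behavior: cross structure, selection response, pooling noise."""

import numpy as np
import pandas as pd
import pytest

import larvascan.synthetic_data as syn
from larvascan.errors import ConfigError, ParameterError
from larvascan.synthetic_data import (
    Cohort,
    SimConfig,
    apply_stage_selection,
    assign_size_groups,
    sample_pool_reads,
    simulate_cross,
    simulate_experiment,
)


def causal_cohort(n, p0, rng, n_loci=1):
    dose = rng.binomial(2, p0, (n, n_loci)).astype(np.int8)
    return Cohort(n=n, causal_dose=dose, neutral_counts=np.zeros((0, 3), dtype=np.int64))


class TestCross:
    def test_factorial_dimensions(self):
        cfg = SimConfig(n_females=4, n_males=2, n_replicates=3,
                        n_markers=50, n_contigs=10, start_cohort_size=500)
        layout, parental, populations, cohorts = simulate_cross(cfg)
        assert len(populations) == 8
        assert len(cohorts) == 24
        assert all(c.n == 500 for c in cohorts.values())
        # every marker informative: opposite-homozygote parents in every family
        assert (parental["female_gt"] == "hom_ref").all()
        assert (parental["male_gt"] == "hom_alt").all()
        assert parental.groupby(["female", "male"]).size().eq(50).all()

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_females=1, n_males=2, n_replicates=2, n_markers=100,
                        n_contigs=20, start_cohort_size=1000,
                        n_viability_loci=10, n_size_loci=5, seed=42)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth.true_freqs, b.truth.true_freqs)
        pd.testing.assert_series_equal(a.truth.labels, b.truth.labels)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_females=0).validate()
        with pytest.raises(ConfigError):
            SimConfig(n_markers=10, n_contigs=20).validate()
        with pytest.raises(ConfigError):
            SimConfig(survival_schedule=(0.5, 1.2, 0.5)).validate()
        with pytest.raises(ConfigError):
            SimConfig(n_markers=10, n_contigs=2,
                      n_viability_loci=8, n_size_loci=8).validate()

    def test_truth_labels_partition_markers(self, planted_sim):
        labels = planted_sim.truth.labels
        assert labels.isin(["neutral", "viability", "size"]).all()
        assert (labels == "viability").sum() == 20
        assert (labels == "size").sum() == 10
        tf = planted_sim.truth.true_freqs["true_af"]
        assert tf.between(0, 1).all()


class TestStageSelection:
    def test_neutral_subsample_preserves_frequency(self):
        rng = np.random.default_rng(0)
        deltas = []
        for _ in range(300):
            c = causal_cohort(2000, 0.5, rng)
            p_before = c.causal_dose.mean() / 2
            out = apply_stage_selection(c, np.array([0.0]), 0.5, rng)
            deltas.append(out.causal_dose.mean() / 2 - p_before)
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se
        assert out.n < 2000  # survivors are a strict subset

    def test_positive_s_matches_one_locus_recursion(self):
        # pooled allele ratio across replicates converges to p(1+s)/(1+ps)
        rng = np.random.default_rng(1)
        p0, s = 0.3, 0.3
        alt = survivors = 0
        freqs = []
        for _ in range(1000):
            c = causal_cohort(2000, p0, rng)
            out = apply_stage_selection(c, np.array([s]), 0.5, rng)
            alt += int(out.causal_dose.sum())
            survivors += out.n
            freqs.append(out.causal_dose.sum() / (2 * out.n))
        pooled = alt / (2 * survivors)
        oracle = p0 * (1 + s) / (1 + p0 * s)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(pooled - oracle) < 3 * se

    def test_frequency_increases_every_stage_under_positive_s(self):
        rng = np.random.default_rng(2)
        c = causal_cohort(200_000, 0.3, rng)
        p = [c.causal_dose.mean() / 2]
        for _ in range(3):
            c = apply_stage_selection(c, np.array([0.4]), 0.6, rng)
            p.append(c.causal_dose.mean() / 2)
        assert all(b > a for a, b in zip(p, p[1:]))

    def test_alternating_s_moves_less_than_directional(self):
        # balancing-style sign flips shrink the net D0->D23 change
        rng = np.random.default_rng(3)
        shifts = {"direct": [], "alternating": []}
        for _ in range(300):
            for name, signs in (("direct", [1, 1, 1]), ("alternating", [1, -1, 1])):
                c = causal_cohort(5000, 0.5, rng)
                p0 = c.causal_dose.mean() / 2
                for sign in signs:
                    s = 0.4 if sign > 0 else 1 / 1.4 - 1
                    c = apply_stage_selection(c, np.array([s]), 0.6, rng)
                shifts[name].append(abs(c.causal_dose.mean() / 2 - p0))
        assert np.mean(shifts["alternating"]) < np.mean(shifts["direct"])

    def test_lethal_coefficient_rejected(self):
        rng = np.random.default_rng(0)
        c = causal_cohort(100, 0.5, rng)
        with pytest.raises(ParameterError):
            apply_stage_selection(c, np.array([-1.0]), 0.5, rng)
        with pytest.raises(ParameterError):
            apply_stage_selection(c, np.array([0.0]), 1.5, rng)


class TestSizeGroups:
    def test_median_split_sizes(self):
        rng = np.random.default_rng(4)
        for n in (101, 100, 999):
            c = causal_cohort(n, 0.5, rng)
            big, small = assign_size_groups(c, np.array([0.0]), 0.5, rng)
            assert big.n + small.n == n
            assert abs(big.n - small.n) <= 1

    def test_null_effects_give_no_systematic_gap(self):
        rng = np.random.default_rng(5)
        gaps = []
        for _ in range(200):
            c = causal_cohort(1000, 0.5, rng)
            big, small = assign_size_groups(c, np.array([0.0]), 0.5, rng)
            gaps.append(big.causal_dose.mean() / 2 - small.causal_dose.mean() / 2)
        se = np.std(gaps) / np.sqrt(len(gaps))
        assert abs(np.mean(gaps)) < 3 * se

    def test_positive_effect_enriches_big_group(self):
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(200):
            c = causal_cohort(1000, 0.5, rng)
            big, small = assign_size_groups(c, np.array([0.8]), 0.5, rng)
            wins += big.causal_dose.mean() > small.causal_dose.mean()
        assert wins > 180  # one-sided sign test, overwhelmingly positive

    def test_empty_cohort_warns(self):
        rng = np.random.default_rng(0)
        empty = Cohort(n=0, causal_dose=np.zeros((0, 1), dtype=np.int8),
                       neutral_counts=np.zeros((0, 3), dtype=np.int64))
        with pytest.warns(UserWarning):
            big, small = assign_size_groups(empty, np.array([1.0]), 0.5, rng)
        assert big.n == small.n == 0


class TestPoolReads:
    def _layout(self, n_markers, rng):
        cfg = SimConfig(n_markers=n_markers, n_contigs=min(10, n_markers))
        return syn._build_layout(cfg, rng)

    def test_counts_sum_to_depth_and_fixed_allele(self):
        rng = np.random.default_rng(7)
        layout = self._layout(50, rng)
        # all-reference cohort: alt frequency 0 everywhere
        counts = np.zeros((50, 3), dtype=np.int64)
        counts[:, 0] = 200
        c = Cohort(n=200, causal_dose=np.zeros((200, 0), dtype=np.int8),
                   neutral_counts=counts)
        rows = sample_pool_reads(c, layout, 100, 80.0, 0.2, rng,
                                 female=1, male=1, replicate=1, day=11)
        assert (rows["alt_count"] == 0).all()
        assert (rows["ref_count"] >= 0).all()

    def test_deep_coverage_recovers_pool_frequency(self):
        rng = np.random.default_rng(8)
        layout = self._layout(200, rng)
        counts = np.zeros((200, 3), dtype=np.int64)
        counts[:, 1] = 500  # all heterozygous: frequency exactly 0.5
        c = Cohort(n=500, causal_dose=np.zeros((500, 0), dtype=np.int8),
                   neutral_counts=counts)
        rows = sample_pool_reads(c, layout, 500, 5000.0, 0.0, rng,
                                 female=1, male=1, replicate=1, day=11)
        af = rows["alt_count"] / (rows["ref_count"] + rows["alt_count"])
        se = af.std() / np.sqrt(len(af))
        assert abs(af.mean() - 0.5) < 3 * se

    def test_poisson_depth_variance(self):
        rng = np.random.default_rng(9)
        layout = self._layout(10_000, rng)
        counts = np.zeros((10_000, 3), dtype=np.int64)
        counts[:, 1] = 100
        c = Cohort(n=100, causal_dose=np.zeros((100, 0), dtype=np.int8),
                   neutral_counts=counts)
        rows = sample_pool_reads(c, layout, 100, 100.0, 0.0, rng,
                                 female=1, male=1, replicate=1, day=11)
        depth = (rows["ref_count"] + rows["alt_count"]).astype(float)
        # Poisson: variance ~ mean = 100; 4 sd of the variance estimator
        assert abs(depth.var() - 100.0) < 6.0

    def test_bad_depth_rejected(self):
        rng = np.random.default_rng(0)
        layout = self._layout(5, rng)
        c = syn._init_cohort(layout, 50, rng)
        with pytest.raises(ParameterError):
            sample_pool_reads(c, layout, 10, 0.0, 0.0, rng,
                              female=1, male=1, replicate=1, day=11)


class TestExperiment:
    def test_neutral_mean_change_near_zero(self, neutral_sim):
        # across ~500 unlinked neutral markers the mean D0->D23 true change
        # is a mean of iid drift deviations: within 3 SE of zero
        tf = neutral_sim.truth.true_freqs
        d0 = tf[tf["day"] == 0].set_index("marker_id")["true_af"]
        d23 = tf[(tf["day"] == 23) & (tf["size_group"] == "Big")]
        d23 = d23.set_index("marker_id")["true_af"]
        delta = (d23 - d0).dropna()
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 3 * se

    def test_survivorship_is_type_iii(self, planted_sim):
        ph = planted_sim.phenotypes
        for (_, _, r), grp in ph.groupby(["female", "male", "replicate"]):
            counts = grp.sort_values("day")["survival_count"].to_numpy()
            assert (np.diff(counts) <= 0).all()
            assert 0.02 <= counts[-1] / counts[0] <= 0.20

    def test_day0_pool_has_no_replicate(self, planted_sim):
        counts = planted_sim.counts
        d0 = counts[counts["day"] == 0]
        assert d0["replicate"].isna().all()
        assert counts.loc[counts["day"] != 0, "replicate"].notna().all()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(n_markers=123, n_contigs=7, seed=3,
                        survival_schedule=(0.5, 0.5, 0.5))
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
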