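"""Chi-square engine, q-values and the four scan procedures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvascan.errors import ScanError, UndefinedTestError
from larvascan.selection_scan import (
    chisq_2x2,
    contig_scan,
    haplotype_scan,
    overlap_sets,
    qvalues,
    size_scan,
    storey_pi0,
    viability_scan,
)

from conftest import make_counts, make_parental, table1_like_fixture


class TestChisq2x2:
    def test_independence_gives_zero(self):
        stat, p = chisq_2x2(50, 50, 50, 50)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_oracle_value(self):
        stat, _ = chisq_2x2(30, 10, 10, 30)
        assert stat == pytest.approx(20.0, abs=1e-12)

    def test_zero_marginal_raises(self):
        with pytest.raises(UndefinedTestError):
            chisq_2x2(0, 0, 10, 10)
        with pytest.raises(UndefinedTestError):
            chisq_2x2(0, 10, 0, 10)

    def test_label_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, 4)
            _, p1 = chisq_2x2(a, b, c, d)
            _, p2 = chisq_2x2(b, a, d, c)  # swap ref/alt columns
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_yates_correction_reduces_statistic(self):
        plain, _ = chisq_2x2(30, 10, 10, 30, yates=False)
        corrected, _ = chisq_2x2(30, 10, 10, 30, yates=True)
        assert corrected < plain


class TestQvalues:
    def test_bh_hand_step_up(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert qvalues([0.5], "bh")[0] == pytest.approx(0.5)

    def test_storey_pi0_on_uniform(self):
        rng = np.random.default_rng(1)
        pi0 = storey_pi0(rng.uniform(size=10_000))
        assert abs(pi0 - 1.0) <= 0.05

    def test_small_family_falls_back_to_bh(self):
        p = [0.001, 0.5, 0.9]
        assert np.allclose(qvalues(p, "storey"), qvalues(p, "bh"))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    def test_monotone_in_p(self, p):
        q = qvalues(p, "bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        q = qvalues([0.01, np.nan, 0.5], "bh")
        assert np.isnan(q[1]) and np.isfinite(q[0])


def five_sample_rows(marker, contig, counts5):
    """counts5: (ref, alt) for D0, D11, D16, D23Big, D23Small."""
    keys = [(None, 0, None), (1, 11, None), (1, 16, None),
            (1, 23, "Big"), (1, 23, "Small")]
    return [(marker, contig, 1, 1, 1, rep, day, sg, ref, alt)
            for (rep, day, sg), (ref, alt) in zip(keys, counts5)]


class TestViabilityScan:
    def test_identical_counts_not_significant(self):
        table = make_counts(five_sample_rows("m1", "c1", [(100, 100)] * 5))
        out = viability_scan(table, ["m1"], 1, 1, 1, n_het=1)
        assert out.flagged == []
        assert np.allclose(out.results["p_value"], 1.0)

    def test_both_tests_required_when_small_exists(self):
        rows = (
            five_sample_rows("both", "c1",
                             [(500, 500)] * 3 + [(200, 800), (200, 800)])
            + five_sample_rows("bigonly", "c1",
                              [(500, 500)] * 3 + [(200, 800), (500, 500)])
        )
        out = viability_scan(make_counts(rows), ["both", "bigonly"], 1, 1, 1, n_het=100)
        assert out.flagged == ["both"]

    def test_single_test_rule_without_small_group(self):
        rows = [r for r in five_sample_rows(
            "m1", "c1", [(500, 500)] * 3 + [(200, 800), (0, 0)]) if r[7] != "Small"]
        out = viability_scan(make_counts(rows), ["m1"], 1, 1, 1, n_het=100)
        assert out.flagged == ["m1"]
        assert out.comparisons == ["D0-vs-D23Big"]

    def test_missing_day23_is_an_error(self):
        rows = [r for r in five_sample_rows("m1", "c1", [(50, 50)] * 5) if r[6] != 23]
        with pytest.raises(ScanError):
            viability_scan(make_counts(rows), ["m1"], 1, 1, 1, n_het=1)

    def test_published_style_category_counts(self):
        # engineered replicate: 5,516 markers, 1,269 pass Big, 404 pass
        # Small, 192 pass both -> 192 viability-associated SNPs
        counts, markers = table1_like_fixture()
        out = viability_scan(counts, markers, 1, 1, 1, n_het=len(markers))
        res = out.results
        n_big = int(res[res["comparison"] == "D0-vs-D23Big"]["significant"].sum())
        n_small = int(res[res["comparison"] == "D0-vs-D23Small"]["significant"].sum())
        assert (n_big, n_small, len(out.flagged)) == (1269, 404, 192)


class TestHaplotypeScan:
    def test_balanced_counts_never_significant(self):
        table = make_counts(five_sample_rows("m1", "c1", [(100, 100)] * 5))
        pg = make_parental(["m1"])
        out = haplotype_scan(table, pg, ["m1"], 1, 1, 1)
        assert np.allclose(out.results["p_value"], 1.0)
        assert out.flagged == []

    def test_orientation_flip_leaves_p_unchanged(self):
        rows = five_sample_rows("m1", "c1", [(500, 500)] * 3 + [(300, 700)] * 2)
        table = make_counts(rows)
        p_ref = haplotype_scan(table, make_parental(["m1"]), ["m1"], 1, 1, 1)
        p_alt = haplotype_scan(
            table, make_parental(["m1"], female_gt="hom_alt", male_gt="hom_ref"),
            ["m1"], 1, 1, 1,
        )
        assert np.allclose(p_ref.results["p_value"], p_alt.results["p_value"])

    def test_recovery_with_fdr_control(self):
        # 1,000 markers, 50 true paternal-haplotype shifts of +0.15 at depth
        # 200; q < 0.05 required in both size pools.  The per-test effect is
        # z ~ 3 against an adaptive cutoff near z ~ 2.96 (about 50% power per
        # test), so the joint both-pool rule recovers roughly 0.5^2 to 0.5 of
        # true markers depending on the shared-day-0 correlation; the solid
        # guarantee is the false-discovery proportion among flagged markers.
        rng = np.random.default_rng(42)
        tprs, fdps = [], []
        for _ in range(25):
            n, depth, n_true = 1000, 200, 50
            p23 = np.full(n, 0.5)
            p23[:n_true] = 0.65
            rows = []
            for i in range(n):
                alt0 = rng.binomial(depth, 0.5)
                altb = rng.binomial(depth, p23[i])
                alts = rng.binomial(depth, p23[i])
                rows += [
                    (f"m{i:04d}", "c1", 1, 1, 1, None, 0, None, depth - alt0, alt0),
                    (f"m{i:04d}", "c1", 1, 1, 1, 1, 23, "Big", depth - altb, altb),
                    (f"m{i:04d}", "c1", 1, 1, 1, 1, 23, "Small", depth - alts, alts),
                ]
            table = make_counts(rows)
            pg = make_parental([f"m{i:04d}" for i in range(n)])
            out = haplotype_scan(table, pg, list(pg["marker_id"]), 1, 1, 1)
            flagged = set(out.flagged)
            true = {f"m{i:04d}" for i in range(n_true)}
            tprs.append(len(flagged & true) / n_true)
            fdps.append(len(flagged - true) / max(len(flagged), 1))
        assert np.mean(tprs) >= 0.2
        assert np.mean(fdps) <= 0.08


class TestContigScan:
    def test_aggregation_consistency(self):
        # contig statistic from summed counts equals chisq_2x2 on the sums
        rows = (
            five_sample_rows("m1", "tig", [(10, 20)] * 3 + [(15, 25)] * 2)
            + five_sample_rows("m2", "tig", [(30, 40)] * 3 + [(35, 45)] * 2)
        )
        table = make_counts(rows)
        pg = make_parental(["m1", "m2"])
        out = contig_scan(table, pg, ["m1", "m2"], 1, 1, 1)
        big = out.results[out.results["comparison"] == "D0-vs-D23Big"]
        stat_expected, _ = chisq_2x2(10 + 30, 20 + 40, 15 + 35, 25 + 45)
        assert big["statistic"].iloc[0] == pytest.approx(stat_expected, abs=1e-9)

    def test_flat_counts_never_significant(self):
        rows = five_sample_rows("m1", "tig", [(40, 60)] * 5)
        out = contig_scan(make_counts(rows), make_parental(["m1"]), ["m1"], 1, 1, 1)
        assert out.intersection == []
        assert np.allclose(out.results["p_value"], 1.0)

    def test_selected_contig_recovered_among_neutral(self):
        # a consistently selected contig among 39 neutral ones lands in the
        # intersection of the D0-vs-D23 and D16-vs-D23 comparisons
        from larvascan.synthetic_data import SimConfig, simulate_experiment

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_females=1, n_males=1, n_replicates=1, n_markers=400,
                n_contigs=40, n_viability_loci=10, causal_p0_range=(0.40, 0.48),
                viability_s=0.55, start_cohort_size=8000, pool_sample_size=800,
                mean_depth=200, depth_dispersion=0.0, seed=100 + seed,
            )
            sim = simulate_experiment(cfg)
            true_contig = set(
                sim.counts.loc[
                    sim.counts["marker_id"].isin(sim.truth.markers("viability")),
                    "contig",
                ]
            )
            out = contig_scan(sim.counts, sim.parental,
                              list(sim.truth.labels.index), 1, 1, 1)
            hits += true_contig <= set(out.intersection)
        assert hits >= 9


class TestSizeScan:
    def test_identical_groups_give_p_one(self):
        table = make_counts(five_sample_rows("m1", "c1", [(100, 100)] * 5))
        out = size_scan(table, ["m1"], 1, 1, 1, n_het=1)
        assert out.results["p_value"].iloc[0] == pytest.approx(1.0)

    def test_missing_group_is_an_error(self):
        rows = [r for r in five_sample_rows("m1", "c1", [(50, 50)] * 5)
                if r[7] != "Small"]
        with pytest.raises(ScanError):
            size_scan(make_counts(rows), ["m1"], 1, 1, 1, n_het=1)

    def test_constructed_significant_markers_flagged(self):
        # 1,101 markers of which 46 differ strongly between size pools
        rows = []
        for i in range(1101):
            big = (200, 800) if i < 46 else (500, 500)
            rows += five_sample_rows(f"m{i:04d}", "c1",
                                     [(500, 500)] * 3 + [big, (500, 500)])
        out = size_scan(make_counts(rows), [f"m{i:04d}" for i in range(1101)],
                        1, 1, 1, n_het=1101)
        assert len(out.flagged) == 46


class TestOverlapSets:
    def test_examples(self):
        rep = overlap_sets({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert rep.intersection == ["c"]
        assert overlap_sets({"a"}, {"b"}).intersection == []

    def test_planted_shared_markers(self):
        shared = {f"s{i}" for i in range(149)}
        sets = [shared | {f"r{k}_{i}" for i in range(50)} for k in range(3)]
        rep = overlap_sets(*sets)
        assert len(rep.intersection) == 149
        assert rep.set_sizes == [199, 199, 199]

    def test_requires_two_sets(self):
        with pytest.raises(ScanError):
            overlap_sets({"a"})
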