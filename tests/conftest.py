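"""Shared fixtures: small simulated experiments and hand-built count tables."""

import numpy as np
import pandas as pd
import pytest

from larvascan.synthetic_data import SimConfig, simulate_experiment


def make_counts(rows):
    """Build a pool count table from (marker, contig, pos, f, m, rep, day,
    size_group, ref, alt) tuples; None counts become missing cells."""
    df = pd.DataFrame(
        rows,
        columns=["marker_id", "contig", "position", "female", "male",
                 "replicate", "day", "size_group", "ref_count", "alt_count"],
    )
    df["replicate"] = df["replicate"].astype("Int64")
    df["size_group"] = df["size_group"].astype("string")
    df["ref_count"] = df["ref_count"].astype("Int64")
    df["alt_count"] = df["alt_count"].astype("Int64")
    return df


def make_parental(markers, female=1, male=1, female_gt="hom_ref", male_gt="hom_alt",
                  depth=100, contig=None):
    """All-informative parental genotype table for a marker list."""
    return pd.DataFrame(
        {
            "marker_id": list(markers),
            "contig": contig if contig is not None else ["c1"] * len(markers),
            "position": range(1, len(markers) + 1),
            "female": female,
            "male": male,
            "female_gt": female_gt,
            "male_gt": male_gt,
            "female_depth": depth,
            "male_depth": depth,
        }
    )


@pytest.fixture(scope="session")
def planted_sim():
    """One family, 3 tanks, 400 markers with 20 viability + 10 size loci."""
    cfg = SimConfig(
        n_females=1, n_males=1, n_replicates=3,
        n_markers=400, n_contigs=40,
        start_cohort_size=8000, pool_sample_size=800,
        n_viability_loci=20, n_size_loci=10, viability_s=0.55,
        causal_p0_range=(0.40, 0.48), mean_depth=200, depth_dispersion=0.0,
        seed=11,
    )
    return simulate_experiment(cfg)


def table1_like_fixture():
    """Counts engineered to the published worked example's marker categories.

    5,516 heterozygous markers in one replicate: 192 shift strongly in both
    day-23 size pools (viability-associated), 1,077 in Big only, 212 in
    Small only, the rest are null.  Of the 192, 17 carry a strictly
    increasing and 13 a strictly decreasing trajectory.  Returns
    ``(counts, markers, trend_freqs)``.
    """
    n = 5516
    markers = np.array([f"m{i:05d}" for i in range(n)])
    cat = np.array(["D"] * n, dtype=object)
    cat[:192] = "A"          # significant in Big and Small
    cat[192:192 + 1077] = "B"  # Big only
    cat[1269:1269 + 212] = "C"  # Small only

    null_c, shift_c = (500, 500), (200, 800)
    inc = dict(d0=(500, 500), d11=(460, 540), d16=(420, 580),
               big=(200, 800), small=(210, 790))
    dec = dict(d0=(500, 500), d11=(540, 460), d16=(580, 420),
               big=(800, 200), small=(790, 210))

    rows = []
    for i, m in enumerate(markers):
        special = inc if i < 17 else dec if i < 30 else None
        d0 = special["d0"] if special else null_c
        d11 = special["d11"] if special else null_c
        d16 = special["d16"] if special else null_c
        big = special["big"] if special else (
            shift_c if cat[i] in ("A", "B") else null_c)
        small = special["small"] if special else (
            shift_c if cat[i] in ("A", "C") else null_c)
        for rep, day, sg, (ref, alt) in [
            (None, 0, None, d0), (1, 11, None, d11), (1, 16, None, d16),
            (1, 23, "Big", big), (1, 23, "Small", small),
        ]:
            rows.append((m, f"c{i // 10:04d}", i + 1, 1, 1, rep, day, sg, ref, alt))
    counts = pd.DataFrame(
        rows,
        columns=["marker_id", "contig", "position", "female", "male",
                 "replicate", "day", "size_group", "ref_count", "alt_count"],
    )
    counts["replicate"] = counts["replicate"].astype("Int64")
    counts["size_group"] = counts["size_group"].astype("string")
    counts["ref_count"] = counts["ref_count"].astype("Int64")
    counts["alt_count"] = counts["alt_count"].astype("Int64")
    return counts, list(markers)


@pytest.fixture(scope="session")
def neutral_sim():
    """A fully neutral single-replicate experiment."""
    cfg = SimConfig(
        n_females=1, n_males=1, n_replicates=1,
        n_markers=500, n_contigs=50,
        start_cohort_size=5000, pool_sample_size=1000,
        mean_depth=200, depth_dispersion=0.0, seed=5,
    )
    return simulate_experiment(cfg)
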