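"""Coalescent engine: closed-form checks, structure, determinism."""

import numpy as np
import pytest

from ficipop.coalescent import (
    DemographicModel,
    Migration,
    SizeChange,
    Split,
    expected_joint_sfs,
    expected_sfs,
    simulate_genealogy,
    simulate_sequences,
    simulate_snp_matrix,
)


def test_pairwise_tmrca_matches_2n():
    """Constant diploid N: E[TMRCA] for two haploid samples is 2N."""
    model = DemographicModel({"pop": 1000.0})
    rng = np.random.default_rng(1)
    times = np.array(
        [simulate_genealogy(model, {"pop": 2}, rng).tmrca for _ in range(10_000)]
    )
    se = times.std() / np.sqrt(len(times))
    assert abs(times.mean() - 2000.0) < 3 * se


def test_total_branch_length_matches_harmonic_sum():
    """Constant N, n=10: E[L] = 4N * sum_{1..9} 1/i."""
    model = DemographicModel({"pop": 500.0})
    rng = np.random.default_rng(2)
    lengths = np.array(
        [
            simulate_genealogy(model, {"pop": 10}, rng).total_length
            for _ in range(10_000)
        ]
    )
    expect = 4 * 500.0 * sum(1.0 / i for i in range(1, 10))
    se = lengths.std() / np.sqrt(len(lengths))
    assert abs(lengths.mean() - expect) < 3 * se


def test_no_cross_deme_coalescence_before_split():
    model = DemographicModel(
        {"a": 500.0, "b": 500.0, "anc": 500.0},
        splits=[Split(3000.0, ["a", "b"], "anc")],
    )
    rng = np.random.default_rng(3)
    for _ in range(200):
        g = simulate_genealogy(model, {"a": 4, "b": 4}, rng)
        mask_a = sum(1 << i for i, d in enumerate(g.leaf_demes) if d == "a")
        for blen, mask, t_end in g.branches:
            if (mask & mask_a) and (mask & ~mask_a):
                # mixed-ancestry lineage must have been created after the split
                assert t_end - blen >= 3000.0 - 1e-9


def test_stranded_demes_rejected_before_simulating():
    with pytest.raises(ValueError, match="merge|stranded|migration"):
        DemographicModel({"a": 100.0, "b": 100.0})


def test_constant_n_spectrum_is_watterson_shaped():
    model = DemographicModel({"pop": 1000.0})
    p = expected_sfs(model, 10, n_replicates=10_000, seed=4)
    want = np.zeros(11)
    want[1:10] = 1.0 / np.arange(1, 10)
    want /= want.sum()
    assert np.allclose(p, want, atol=0.01)


def test_two_demes_merged_at_origin_equal_panmixia():
    merged = DemographicModel(
        {"a": 1000.0, "b": 1000.0, "anc": 1000.0},
        splits=[Split(1e-6, ["a", "b"], "anc")],
    )
    rng = np.random.default_rng(5)
    xi = np.zeros(9)
    reps = 4000
    for _ in range(reps):
        g = simulate_genealogy(merged, {"a": 4, "b": 4}, rng)
        xi += g.class_lengths()
    xi[0] = xi[8] = 0
    p_structured = xi / xi.sum()
    p_panmictic = expected_sfs(DemographicModel({"pop": 1000.0}), 8,
                               n_replicates=10_000, seed=6)
    assert np.allclose(p_structured, p_panmictic, atol=0.02)


def test_bottleneck_singleton_deficit_matches_msprime():
    """Recent 10x bottleneck: singleton deficit relative to constant N, and
    agreement with an independent coalescent simulator."""
    msprime = pytest.importorskip("msprime")
    n, n_bottle, t_b = 12, 1000.0, 400.0
    model = DemographicModel(
        {"pop": n_bottle}, size_changes=[SizeChange(t_b, "pop", 10_000.0)]
    )
    p = expected_sfs(model, n, n_replicates=20_000, seed=7)
    p_const = expected_sfs(DemographicModel({"pop": 10_000.0}), n,
                           n_replicates=20_000, seed=8)
    assert p[1] < p_const[1]  # singleton deficit

    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=n_bottle)
    dem.add_population_parameters_change(time=t_b, initial_size=10_000.0,
                                         population="pop")
    xi = np.zeros(n + 1)
    reps = 20_000
    # ploidy-2 sampling: n/2 individuals = n haploid genomes, and the
    # pairwise coalescence rate is 1/(2N), matching the engine's diploid
    # size convention
    for ts in msprime.sim_ancestry(
        samples={"pop": n // 2}, demography=dem, ploidy=2,
        num_replicates=reps, random_seed=9,
    ):
        xi += ts.allele_frequency_spectrum(mode="branch", polarised=True,
                                           span_normalise=False)
    xi[0] = xi[n] = 0
    p_oracle = xi / xi.sum()
    assert np.allclose(p, p_oracle, atol=0.01)


def test_fast_path_agrees_with_event_driven_engine():
    """The vectorized single-deme SFS path is statistically identical to
    the general structured engine on the same model."""
    model = DemographicModel(
        {"pop": 2000.0}, size_changes=[SizeChange(800.0, "pop", 20_000.0)]
    )
    fast = expected_sfs(model, 10, n_replicates=20_000, seed=10)
    rng = np.random.default_rng(11)
    xi = np.zeros(11)
    for _ in range(8000):
        xi += simulate_genealogy(model, {"pop": 10}, rng).class_lengths()
    xi[0] = xi[10] = 0
    slow = xi / xi.sum()
    assert np.allclose(fast, slow, atol=0.015)


def test_same_seed_bit_identical_outputs():
    model = DemographicModel({"pop": 1000.0})
    a = simulate_snp_matrix(model, {"pop": 10}, 50, seed=12)
    b = simulate_snp_matrix(model, {"pop": 10}, 50, seed=12)
    assert np.array_equal(a.dosage, b.dosage)
    s1 = simulate_sequences(model, {"pop": 6}, 500, 1e-4, seed=13)
    s2 = simulate_sequences(model, {"pop": 6}, 500, 1e-4, seed=13)
    assert s1.sequences == s2.sequences


def test_tajima_and_watterson_agree_under_constant_n():
    """Branch versions of pi and Watterson's theta have equal expectation."""
    model = DemographicModel({"pop": 1000.0})
    rng = np.random.default_rng(14)
    n = 10
    a_n = sum(1.0 / i for i in range(1, n))
    pis, watts = [], []
    for _ in range(10_000):
        g = simulate_genealogy(model, {"pop": n}, rng)
        cls = g.class_lengths()
        j = np.arange(n + 1)
        pis.append(np.sum(j * (n - j) * cls) / (n * (n - 1) / 2))
        watts.append(g.total_length / a_n)
    diff = np.array(pis) - np.array(watts)
    se = diff.std() / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * se


def test_full_inbreeding_removes_heterozygotes():
    gm = simulate_snp_matrix(
        DemographicModel({"pop": 1000.0}), {"pop": 20}, 200, seed=15,
        inbreeding_f=1.0,
    )
    assert not np.any(gm.dosage == 1)


def test_snp_matrix_shape_contract():
    gm = simulate_snp_matrix(
        DemographicModel({"pop": 1000.0}), {"pop": 56}, 2524, seed=16
    )
    assert gm.dosage.shape == (28, 2524)


def test_outcrossing_simulation_is_in_hwe():
    gm = simulate_snp_matrix(
        DemographicModel({"pop": 5000.0}), {"pop": 40}, 2000, seed=17
    )
    from ficipop.diversity import site_stats

    table = site_stats(gm)
    assert table.ho.mean() == pytest.approx(table.he.mean(), rel=0.05)


def test_odd_haploid_count_rejected():
    with pytest.raises(ValueError, match="odd"):
        simulate_snp_matrix(DemographicModel({"pop": 100.0}), {"pop": 5}, 10, seed=1)


def test_zero_mutation_rate_gives_identical_sequences():
    aln = simulate_sequences(
        DemographicModel({"pop": 500.0}, ploidy=1), {"pop": 8}, 1000, 0.0, seed=18
    )
    assert len(set(aln.sequences)) == 1


def test_haploid_pairwise_diversity_scaling():
    """Haploid locus: E[pairwise differences] = 2 N mu_locus."""
    from ficipop.mismatch import mismatch_distribution

    model = DemographicModel({"pop": 400.0}, ploidy=1)
    mu, L = 2e-4, 100
    means = []
    rng = np.random.default_rng(19)
    for _ in range(400):
        aln = simulate_sequences(model, {"pop": 6}, L, mu,
                                 seed=int(rng.integers(2**31 - 1)))
        if aln.n_columns == 0:
            means.append(0.0)
            continue
        counts = mismatch_distribution(aln)
        means.append(np.average(np.arange(len(counts)), weights=counts))
    expect = 2 * 400.0 * mu * L  # = 16
    got = np.mean(means)
    assert got == pytest.approx(expect, rel=0.1)


def test_sudden_expansion_mismatch_peaks_near_tau():
    """Large expansion: the mean pairwise difference approaches tau."""
    from ficipop.mismatch import mismatch_distribution

    # theta0 tiny, theta1 huge, tau = 2 u t = 2*0.5*8 = 8
    model = DemographicModel(
        {"pop": 5000.0}, size_changes=[SizeChange(8.0, "pop", 1.0)], ploidy=1
    )
    rng = np.random.default_rng(20)
    means = []
    for _ in range(300):
        aln = simulate_sequences(model, {"pop": 20}, 1, 0.5,
                                 seed=int(rng.integers(2**31 - 1)))
        counts = mismatch_distribution(aln)
        means.append(np.average(np.arange(len(counts)), weights=counts))
    assert np.mean(means) == pytest.approx(8.0, rel=0.25)


def test_migration_homogenizes_joint_spectrum():
    """Strong migration between two demes pushes shared polymorphism up
    relative to isolation."""
    base = dict(
        deme_sizes={"a": 1000.0, "b": 1000.0, "anc": 1000.0},
        splits=[Split(10_000.0, ["a", "b"], "anc")],
    )
    iso = DemographicModel(**base)
    mig = DemographicModel(
        **base,
        migrations=[Migration("a", "b", 5e-3), Migration("b", "a", 5e-3)],
    )

    def shared_fraction(model, seed):
        probs = expected_joint_sfs(model, {"a": 6, "b": 6}, n_replicates=1500,
                                   seed=seed)
        return sum(v for (i, j), v in probs.items() if 0 < i < 6 and 0 < j < 6)

    assert shared_fraction(mig, 21) > shared_fraction(iso, 22) + 0.05
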