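"""Filtering cascade: missingness, thinning, HWE exact test, LD pruning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ficipop.filtering import (
    filter_hwe,
    filter_missingness,
    hwe_exact_test,
    ld_prune,
    nuclear_filter_cascade,
    plastome_site_filter,
    thin_by_distance,
)

from conftest import make_gm


# --- missingness ----------------------------------------------------------

def test_missingness_boundary_inclusive():
    # 10 samples; 3 missing (30%) is retained, 4 missing (40%) is dropped
    col3 = [-1] * 3 + [0] * 7
    col4 = [-1] * 4 + [0] * 6
    gm = make_gm(np.array([col3, col4]).T)
    out = filter_missingness(gm, 0.30)
    assert out.pos.tolist() == [1000]


def test_missingness_matches_per_site_recount(rng):
    dosage = rng.integers(-1, 3, size=(10, 100)).astype(np.int8)
    gm = make_gm(dosage)
    out = filter_missingness(gm, 0.30)
    expected = [
        j for j in range(100) if (dosage[:, j] == -1).sum() / 10 <= 0.30
    ]
    assert out.pos.tolist() == [gm.pos[j] for j in expected]


# --- thinning -------------------------------------------------------------

def test_thinning_greedy_keeps_first_then_distance():
    gm = make_gm(np.zeros((2, 3), dtype=np.int8), pos=[100, 300, 450])
    out = thin_by_distance(gm, 250)
    assert out.pos.tolist() == [100, 450]


def test_thinning_one_site_per_chromosome_kept():
    gm = make_gm(
        np.zeros((2, 3), dtype=np.int8),
        pos=[100, 100, 100],
        chrom=["chr1", "chr2", "chr3"],
    )
    assert thin_by_distance(gm, 250).n_sites == 3


def test_thinning_zero_distance_is_identity():
    gm = make_gm(np.zeros((2, 5), dtype=np.int8), pos=[1, 2, 3, 4, 5])
    assert thin_by_distance(gm, 0).pos.tolist() == [1, 2, 3, 4, 5]


def test_thinning_rejects_unsorted():
    gm = make_gm(np.zeros((2, 2), dtype=np.int8), pos=[500, 100])
    with pytest.raises(ValueError):
        thin_by_distance(gm, 250)


# --- HWE exact test -------------------------------------------------------

def _hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact conditional test via rational enumeration with math.comb."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # P(h) proportional to n! / (hom_major! h! hom_minor!) * 2^h
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = (
            math.factorial(n)
            // (math.factorial(hom_major) * math.factorial(h) * math.factorial(hom_minor))
            * 2**h
        )
    total = sum(weights.values())
    w_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= w_obs) / total


def test_hwe_monomorphic_returns_one():
    assert hwe_exact_test(5, 0, 0) == 1.0


def test_hwe_most_probable_configuration_gives_one():
    assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)


def test_hwe_no_heterozygotes_matches_enumeration():
    assert hwe_exact_test(3, 0, 3) == pytest.approx(_hwe_enumeration_oracle(3, 0, 3))


def test_hwe_agrees_with_enumeration_all_small_triples():
    for n in range(1, 13):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                got = hwe_exact_test(n_aa, n_ab, n_bb)
                want = _hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)


def test_hwe_all_zero_counts_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_filter_drops_extreme_heterozygote_deficit():
    # 20 homozygotes of each kind, no hets: far out of HWE
    col_bad = [0] * 20 + [2] * 20
    col_ok = [0, 1, 1, 2] * 10
    gm = make_gm(np.array([col_bad, col_ok]).T)
    out = filter_hwe(gm, 1e-4)
    assert out.pos.tolist() == [2000]


# --- LD pruning -----------------------------------------------------------

def _ld_prune_oracle(gm, r2_max, window_bp):
    """Quadratic fixed-point pruning with the same removal policy."""
    from ficipop.filtering import _dosage_r2

    n_missing = (gm.dosage == -1).sum(axis=0)
    alive = set(range(gm.n_sites))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(sorted(alive), 2):
            if gm.chrom[i] != gm.chrom[j] or gm.pos[j] - gm.pos[i] > window_bp:
                continue
            r2 = _dosage_r2(gm.dosage[:, i], gm.dosage[:, j])
            if r2 is not None and r2 > r2_max:
                alive.remove(i if n_missing[i] > n_missing[j] else j)
                changed = True
                break
    return sorted(alive)


def test_ld_perfectly_correlated_pair_leaves_one():
    col = np.resize([0, 1, 2], 30)
    gm = make_gm(np.array([col, col]).T.reshape(30, 2), pos=[100, 150])
    out = ld_prune(gm, r2_max=0.25, window_bp=100_000, step_bp=100)
    assert out.n_sites == 1


def test_ld_independent_sites_survive(rng):
    dosage = rng.integers(0, 3, size=(100, 2)).astype(np.int8)
    gm = make_gm(dosage, pos=[100, 150])
    out = ld_prune(gm, r2_max=0.25, window_bp=100_000, step_bp=100)
    assert out.n_sites == 2


def test_ld_prune_matches_quadratic_oracle(rng):
    # correlated block: sites derived from two latent haplotypes + noise
    base = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
    cols = []
    for k in range(20):
        src = base[:, k % 4].copy()
        flip = rng.random(40) < 0.1
        src[flip] = rng.integers(0, 3, size=flip.sum())
        cols.append(src)
    dosage = np.array(cols).T
    # sprinkle missing data to exercise the removal policy
    miss = rng.random(dosage.shape) < 0.05
    dosage[miss] = -1
    gm = make_gm(dosage, pos=np.arange(20) * 200 + 1)
    out = ld_prune(gm, r2_max=0.25, window_bp=100_000, step_bp=100)
    want = _ld_prune_oracle(gm, 0.25, 100_000)
    assert out.pos.tolist() == [gm.pos[j] for j in want]


def test_ld_prune_idempotent(rng):
    dosage = rng.integers(-1, 3, size=(30, 25)).astype(np.int8)
    gm = make_gm(dosage, pos=np.arange(25) * 120 + 1)
    once = ld_prune(gm, 0.25, 100_000, 100)
    twice = ld_prune(once, 0.25, 100_000, 100)
    assert twice.pos.tolist() == once.pos.tolist()


def test_ld_prune_window_smaller_than_step_rejected():
    gm = make_gm(np.zeros((4, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        ld_prune(gm, 0.25, window_bp=50, step_bp=100)


# --- cascade & plastome ---------------------------------------------------

def test_cascade_is_subset_and_logged(rng):
    dosage = rng.integers(-1, 3, size=(20, 60)).astype(np.int8)
    gm = make_gm(dosage, pos=np.arange(60) * 137 + 1)
    out, log = nuclear_filter_cascade(gm)
    assert set(out.pos).issubset(set(gm.pos))
    assert out.sample_ids == gm.sample_ids
    assert log["input"] == 60
    assert (
        log["input"] >= log["missingness"] >= log["thinning"]
        >= log["hwe"] >= log["ld_prune"] == out.n_sites
    )


def test_plastome_filter_hand_count():
    # 10 sites, 5 haploid samples: 2 high-depth, 1 in excluded region,
    # 1 too-missing -> 6 retained
    dosage = np.zeros((5, 10), dtype=np.int8)
    dosage[0:2, 3] = -1  # 40% missing at site index 3
    depth = [100] * 10
    depth[5] = 801
    depth[6] = 900
    pos = np.arange(10) * 10 + 1  # 1, 11, ..., 91
    gm = make_gm(dosage, pos=pos, chrom=["pt"] * 10, ploidy=1, depth=depth)
    aln = plastome_site_filter(
        gm, max_missing=0.20, max_depth=800,
        excluded_regions={"pt": [(70, 75)]},  # holds pos 71 (index 7)
    )
    assert aln.n_columns == 6
    assert aln.n_samples == 5


def test_plastome_depth_bound_is_strict():
    dosage = np.zeros((4, 2), dtype=np.int8)
    gm = make_gm(dosage, ploidy=1, depth=[800, 801], chrom=["pt", "pt"])
    aln = plastome_site_filter(gm, max_missing=0.2, max_depth=800)
    assert aln.n_columns == 1


def test_plastome_rejects_overlapping_intervals():
    gm = make_gm(np.zeros((4, 2), dtype=np.int8), ploidy=1)
    with pytest.raises(ValueError):
        plastome_site_filter(gm, 0.2, 800, {"chr1": [(10, 50), (40, 60)]})


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1), st.floats(0.0, 1.0))
def test_filters_are_pure_subsets(seed, max_missing):
    r = np.random.default_rng(seed)
    dosage = r.integers(-1, 3, size=(8, 30)).astype(np.int8)
    gm = make_gm(dosage, pos=np.sort(r.choice(10_000, size=30, replace=False)) + 1)
    for out in (
        filter_missingness(gm, max_missing),
        thin_by_distance(gm, int(max_missing * 500)),
        ld_prune(gm, 0.25, 100_000, 100),
    ):
        assert set(out.pos).issubset(set(gm.pos))
        assert out.sample_ids == gm.sample_ids
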