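"""SNP filtering cascade for nuclear and plastome datasets.

The nuclear cascade mirrors a standard reduced-representation pipeline:
missingness (> 30% dropped), distance thinning (one SNP per locus), an
exact Hardy-Weinberg test (p < 1e-4 dropped), and window-based LD pruning
(r^2 > 0.25 within 100 kbp windows).  All filters are pure subset
operations on sites; the sample set is never altered.

The plastome path applies missingness/depth/region filters to a haploid
matrix and concatenates the surviving columns into a
:class:`~ficipop.genotypes.HaplotypeAlignment`.
"""

from __future__ import annotations

import math

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, HaplotypeAlignment


def filter_missingness(gm: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Keep sites whose missing-genotype fraction is <= ``max_missing``.

    The bound is inclusive: a site at exactly the threshold is retained
    (only sites *above* the threshold are excluded).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = gm.missing_mask().mean(axis=0)
    return gm.take_sites(np.flatnonzero(frac <= max_missing + 1e-12))


def thin_by_distance(gm: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right thinning: keep a site iff it lies at least
    ``min_bp`` from the last kept site on the same chromosome.

    The first site of each chromosome is always kept.  Input must be
    sorted by (chrom, pos).
    """
    gm.check_sorted()
    keep = []
    last_chrom, last_pos = None, None
    for j in range(gm.n_sites):
        c, p = gm.chrom[j], gm.pos[j]
        if c != last_chrom or p - last_pos >= min_bp:
            keep.append(j)
            last_chrom, last_pos = c, p
    return gm.take_sites(np.array(keep, dtype=int))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    the observed one.  Monomorphic sites return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0

    lgam = math.lgamma

    def logprob(h: int) -> float:
        # P(h hets | n genotypes, n_minor minor alleles); homozygote counts
        # follow from h.
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            lgam(n + 1)
            - lgam(hom_major + 1)
            - lgam(h + 1)
            - lgam(hom_minor + 1)
            + h * math.log(2)
            + lgam(n_minor + 1)
            + lgam(2 * n - n_minor + 1)
            - lgam(2 * n + 1)
        )

    h_obs = n_ab
    hs = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = {h: logprob(h) for h in hs}
    lp_obs = logs[h_obs]
    p = sum(math.exp(lp) for lp in logs.values() if lp <= lp_obs + 1e-9)
    return min(p, 1.0)


def filter_hwe(gm: GenotypeMatrix, p_threshold: float = 1e-4) -> GenotypeMatrix:
    """Drop sites with exact-test HWE p-value strictly below the threshold.

    Applied on all samples pooled (a single dataset-level filter).
    """
    if gm.ploidy != 2:
        raise ValueError("HWE filter requires diploid data")
    keep = []
    for j in range(gm.n_sites):
        col = gm.dosage[:, j]
        col = col[col != MISSING]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if sum(counts) == 0 or hwe_exact_test(*counts) >= p_threshold:
            keep.append(j)
    return gm.take_sites(np.array(keep, dtype=int))


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete observations; None if < 4 complete pairs or either
    vector is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 4:
        return None
    xf, yf = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xf.std(), yf.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(xf, yf)[0, 1])
    return r * r


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.25,
    window_bp: int = 100_000,
    step_bp: int = 100,
) -> GenotypeMatrix:
    """Window-based LD pruning on dosage correlations.

    Every pair of surviving sites within ``window_bp`` on the same
    chromosome ends up with r^2 <= ``r2_max``; when a pair exceeds the
    threshold the member with more missing data is dropped (tie: the
    downstream site).  The scan visits candidate pairs in coordinate
    order and skips pairs with an already-removed member, which makes the
    operation idempotent.  ``step_bp`` is validated against the window
    size for interface compatibility; the pairwise scan itself is
    step-independent.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if gm.ploidy != 2:
        raise ValueError("LD pruning expects diploid dosages")
    gm.check_sorted()

    n_missing = gm.missing_mask().sum(axis=0)
    removed = np.zeros(gm.n_sites, dtype=bool)
    for i in range(gm.n_sites):
        if removed[i]:
            continue
        j = i + 1
        while j < gm.n_sites and gm.chrom[j] == gm.chrom[i] and gm.pos[j] - gm.pos[i] <= window_bp:
            if not removed[j] and not removed[i]:
                r2 = _dosage_r2(gm.dosage[:, i], gm.dosage[:, j])
                if r2 is not None and r2 > r2_max:
                    if n_missing[i] > n_missing[j]:
                        removed[i] = True
                    else:
                        removed[j] = True
            j += 1
    return gm.take_sites(np.flatnonzero(~removed))


def nuclear_filter_cascade(
    gm: GenotypeMatrix,
    max_missing: float = 0.30,
    thin_bp: int = 250,
    hwe_p: float = 1e-4,
    r2_max: float = 0.25,
    window_bp: int = 100_000,
    step_bp: int = 100,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Missingness -> thinning -> HWE -> LD pruning, with per-stage counts.

    Returns the filtered matrix and a stage -> retained-site-count log.
    """
    log = {"input": gm.n_sites}
    gm = filter_missingness(gm, max_missing)
    log["missingness"] = gm.n_sites
    gm = thin_by_distance(gm, thin_bp)
    log["thinning"] = gm.n_sites
    gm = filter_hwe(gm, hwe_p)
    log["hwe"] = gm.n_sites
    gm = ld_prune(gm, r2_max, window_bp, step_bp)
    log["ld_prune"] = gm.n_sites
    return gm, log


def plastome_site_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.20,
    max_depth: float = 800.0,
    excluded_regions: dict[str, list[tuple[int, int]]] | None = None,
    total_locus_length: int | None = None,
) -> HaplotypeAlignment:
    """Filter a haploid plastome matrix and concatenate into an alignment.

    A site survives if its missing fraction is <= ``max_missing``, its mean
    depth is <= ``max_depth`` (strictly greater is dropped), and it does
    not fall in an excluded region (half-open 0-based intervals, e.g. the
    inverted repeats).  ``total_locus_length`` (m_T) defaults to the number
    of retained columns if not supplied.
    """
    if gm.ploidy != 1:
        raise ValueError("plastome filter expects haploid data")
    excluded_regions = excluded_regions or {}
    for c, ivals in excluded_regions.items():
        prev_end = -1
        for s, e in ivals:
            if s >= e or s < prev_end:
                raise ValueError(f"malformed/overlapping interval {c}:{s}-{e}")
            prev_end = e

    frac = gm.missing_mask().mean(axis=0)
    keep = frac <= max_missing + 1e-12
    if gm.depth is not None:
        keep &= ~(gm.depth > max_depth)
    for j in range(gm.n_sites):
        if not keep[j]:
            continue
        for s, e in excluded_regions.get(gm.chrom[j], []):
            if s <= gm.pos[j] - 1 < e:  # convert 1-based pos to 0-based
                keep[j] = False
                break

    sub = gm.dosage[:, keep]
    seqs = []
    for i in range(gm.n_samples):
        row = sub[i]
        seqs.append("".join("N" if d == MISSING else str(int(d)) for d in row))
    m_t = total_locus_length if total_locus_length is not None else int(keep.sum())
    return HaplotypeAlignment(
        sample_ids=list(gm.sample_ids), sequences=seqs, total_locus_length=m_t
    )
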