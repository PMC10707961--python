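"""Frequency-based ABBA-BABA (Patterson's D) with block-jackknife tests.

For a trio (P1, P2, P3) and an outgroup, each biallelic site contributes
pattern mass computed from derived-allele frequencies p1..p4 (p4 = the
outgroup), keeping both orientations of the site:

    ABBA = (1-p1) p2 p3 (1-p4) + p1 (1-p2)(1-p3) p4
    BABA = p1 (1-p2) p3 (1-p4) + (1-p1) p2 (1-p3) p4
    BBAA = p1 p2 (1-p3)(1-p4) + (1-p1)(1-p2) p3 p4

D = (ABBA - BABA) / (ABBA + BABA).  Under the species tree ((P1,P2),P3)
with no gene flow E[D] = 0; significance comes from a delete-one block
jackknife over contiguous genomic blocks of SNPs, with a one-tailed
normal p-value (directional introgression hypothesis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DTrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    bbaa_sum: float
    abba_sum: float
    baba_sum: float
    d: float | None
    z: float | None
    p: float | None
    n_blocks: int
    n_sites: int


def pattern_sums(
    freqs_p1: np.ndarray,
    freqs_p2: np.ndarray,
    freqs_p3: np.ndarray,
    freqs_outgroup: np.ndarray,
) -> tuple[float, float, float]:
    """Summed (BBAA, ABBA, BABA) pattern mass over sites.

    Inputs are per-site derived-allele frequencies in [0, 1]; sites where
    any group has no data should be removed beforehand (see
    :func:`trio_table`)."""
    arrs = [np.asarray(a, dtype=float) for a in
            (freqs_p1, freqs_p2, freqs_p3, freqs_outgroup)]
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise ValueError("allele frequency outside [0, 1]")
    bbaa, abba, baba = _per_site_patterns(*arrs)
    return float(bbaa.sum()), float(abba.sum()), float(baba.sum())


def _per_site_patterns(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4) + p1 * (1 - p2) * (1 - p3) * p4
    baba = p1 * (1 - p2) * p3 * (1 - p4) + (1 - p1) * p2 * (1 - p3) * p4
    bbaa = p1 * p2 * (1 - p3) * (1 - p4) + (1 - p1) * (1 - p2) * p3 * p4
    return bbaa, abba, baba


def d_statistic(abba: float, baba: float) -> float | None:
    """Patterson's D = (ABBA - BABA) / (ABBA + BABA); None when the
    denominator is zero."""
    denom = abba + baba
    if denom == 0:
        return None
    return (abba - baba) / denom


def jackknife_test(
    per_site_abba: np.ndarray,
    per_site_baba: np.ndarray,
    n_blocks: int = 20,
) -> tuple[float | None, float | None]:
    """Block-jackknife Z and one-tailed p for D.

    Sites (in genome order) are cut into ``n_blocks`` contiguous,
    near-equal blocks; the delete-one-block D estimates give
    SE = sqrt((B-1)/B * sum_j (D_(-j) - mean)^2) and z = D / SE.
    """
    abba = np.asarray(per_site_abba, dtype=float)
    baba = np.asarray(per_site_baba, dtype=float)
    n_sites = len(abba)
    if not 2 <= n_blocks <= n_sites:
        raise ValueError("need 2 <= n_blocks <= number of sites")
    d_total = d_statistic(abba.sum(), baba.sum())
    if d_total is None:
        return None, None
    edges = np.linspace(0, n_sites, n_blocks + 1).astype(int)
    d_loo = []
    for j in range(n_blocks):
        sl = slice(edges[j], edges[j + 1])
        a = abba.sum() - abba[sl].sum()
        b = baba.sum() - baba[sl].sum()
        d_j = d_statistic(a, b)
        if d_j is None:
            return None, None
        d_loo.append(d_j)
    d_loo = np.array(d_loo)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_loo - d_loo.mean()) ** 2))
    if se == 0:
        if d_total == 0:
            return 0.0, 1.0
        return None, None  # degenerate: nonzero D with zero jackknife spread
    z = d_total / se
    p = float(norm.sf(z))
    return float(z), p


def _group_frequencies(gm: GenotypeMatrix, labels: list[str]) -> np.ndarray:
    """Non-missing alternate-allele frequency per site for pooled labels."""
    rows = [i for i, s in enumerate(gm.sample_ids) if gm.pop_labels[s] in labels]
    if not rows:
        raise ValueError(f"no samples for group {labels!r}")
    sub = gm.dosage[rows, :].astype(float)
    sub[sub == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub, axis=0) / gm.ploidy


def bonferroni_threshold(alpha: float, m: int) -> float:
    return alpha / m


def trio_table(
    gm: GenotypeMatrix,
    groups: dict[str, list[str]],
    trios: list[tuple[str, str, str]],
    outgroup: str,
    n_blocks: int = 20,
    alpha: float = 0.05,
) -> tuple[list[DTrioResult], float]:
    """One D-statistic row per (P1, P2, P3) trio plus the Bonferroni
    threshold alpha / n_trios.

    ``groups`` maps group names to the taxon labels pooled into them
    (e.g. a joint group of two wild taxa).  Alleles are polarized per
    site by the outgroup major allele; sites where any group of a trio
    (or the outgroup) has no data are skipped.
    """
    for trio in trios:
        for g in trio:
            if g not in groups:
                raise ValueError(f"unknown group label {g!r}")
    if outgroup not in groups:
        raise ValueError(f"unknown outgroup label {outgroup!r}")

    freqs = {g: _group_frequencies(gm, labels) for g, labels in groups.items()}
    og = freqs[outgroup]
    # polarize: derived = allele that is minor in the outgroup
    flip = og > 0.5
    pol = {g: np.where(flip, 1.0 - f, f) for g, f in freqs.items()}

    results = []
    for p1, p2, p3 in trios:
        cols = np.column_stack([pol[p1], pol[p2], pol[p3], pol[outgroup]])
        ok = ~np.isnan(cols).any(axis=1)
        f1, f2, f3, f4 = cols[ok].T
        bbaa, abba, baba = _per_site_patterns(f1, f2, f3, f4)
        d = d_statistic(abba.sum(), baba.sum())
        nb = min(n_blocks, max(2, ok.sum()))
        z, pval = jackknife_test(abba, baba, nb)
        results.append(
            DTrioResult(
                p1=p1, p2=p2, p3=p3, outgroup=outgroup,
                bbaa_sum=float(bbaa.sum()),
                abba_sum=float(abba.sum()),
                baba_sum=float(baba.sum()),
                d=d, z=z, p=pval,
                n_blocks=nb, n_sites=int(ok.sum()),
            )
        )
    return results, bonferroni_threshold(alpha, len(trios))


def trio_table_frame(results: list[DTrioResult], threshold: float) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "P1": [r.p1 for r in results],
            "P2": [r.p2 for r in results],
            "P3": [r.p3 for r in results],
            "BBAA": [r.bbaa_sum for r in results],
            "ABBA": [r.abba_sum for r in results],
            "BABA": [r.baba_sum for r in results],
            "D": [r.d for r in results],
            "Z": [r.z for r in results],
            "p": [r.p for r in results],
        }
    )
    df.attrs["bonferroni_threshold"] = threshold
    return df
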