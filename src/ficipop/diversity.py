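"""Per-site diversity statistics and multi-group differentiation.

Definitions follow the per-variant-site conventions of reduced-
representation pipelines: allele frequency p is taken over the 2n
non-missing allele copies at a site, nucleotide diversity uses the
unbiased pairwise estimator pi = (2n/(2n-1)) * 2p(1-p), expected
heterozygosity is 2p(1-p), observed heterozygosity is the fraction of
heterozygous calls, and F_IS = 1 - H_O/pi at sites with pi > 0.  Sums
and means run over variant sites only, so magnitudes are per-SNP, not
per-bp.

F_ST is the Hudson-style ratio-of-sums 1 - sum(Hw)/sum(Ht): per-site
within-group and total diversities are summed across sites before the
ratio is taken, which avoids the small-sample bias of averaging
per-site ratios and makes the estimator invariant to duplicating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    pi_mean: float
    pi_var: float
    he_mean: float
    he_var: float
    ho_mean: float
    ho_var: float
    fis_mean: float
    fis_var: float
    n_sites: int
    fst: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pi (var)": [f"{self.pi_mean:.3f} ({self.pi_var:.3f})"],
                "He (var)": [f"{self.he_mean:.3f} ({self.he_var:.3f})"],
                "Ho (var)": [f"{self.ho_mean:.3f} ({self.ho_var:.3f})"],
                "Fis (var)": [f"{self.fis_mean:.3f} ({self.fis_var:.3f})"],
                "n_sites": [self.n_sites],
            }
        )


def _site_row(col: np.ndarray) -> tuple[float, float, float, float]:
    """(pi, he, ho, fis) for one dosage column; NaNs when undefined."""
    col = col[col != MISSING]
    n = col.size
    if n < 2:
        return (np.nan, np.nan, np.nan, np.nan)
    two_n = 2 * n
    p = col.sum() / two_n
    he = 2.0 * p * (1.0 - p)
    pi = two_n / (two_n - 1.0) * he
    ho = float((col == 1).sum()) / n
    fis = 1.0 - ho / pi if pi > 0 else np.nan
    return (pi, he, ho, fis)


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site table of pi, H_E, H_O and F_IS for a diploid matrix."""
    if gm.ploidy != 2:
        raise ValueError("site_stats requires diploid data")
    rows = [_site_row(gm.dosage[:, j]) for j in range(gm.n_sites)]
    return pd.DataFrame(rows, columns=["pi", "he", "ho", "fis"]).assign(
        chrom=gm.chrom, pos=gm.pos
    )


def summarize(table: pd.DataFrame) -> DiversitySummary:
    """Unweighted mean and sample variance (n-1) across variant sites.

    F_IS is averaged over sites where it is defined (pi > 0).
    """
    valid = table.dropna(subset=["pi"])
    if valid.empty:
        raise ValueError("no valid sites to summarize")

    def mv(s: pd.Series) -> tuple[float, float]:
        s = s.dropna()
        return float(s.mean()), float(s.var(ddof=1)) if len(s) > 1 else 0.0

    pi_m, pi_v = mv(valid["pi"])
    he_m, he_v = mv(valid["he"])
    ho_m, ho_v = mv(valid["ho"])
    fis_m, fis_v = mv(valid["fis"])
    return DiversitySummary(
        pi_mean=pi_m, pi_var=pi_v, he_mean=he_m, he_var=he_v,
        ho_mean=ho_m, ho_var=ho_v, fis_mean=fis_m, fis_var=fis_v,
        n_sites=len(valid),
    )


def fst_among_groups(gm: GenotypeMatrix, group_labels: list[str] | None = None) -> float:
    """Multi-group Hudson-style F_ST = 1 - sum(Hw) / sum(Ht).

    Hw at a site is the mean unbiased within-group diversity over groups
    with >= 2 non-missing genotypes; Ht is the unbiased diversity of the
    pooled sample.  Sites where Ht or any group is undefined are skipped.
    """
    if group_labels is None:
        group_labels = sorted(set(gm.pop_labels.values()))
    if len(group_labels) < 2:
        raise ValueError("F_ST requires at least two groups")
    group_rows = [gm.samples_in(g) for g in group_labels]

    sum_hw = 0.0
    sum_ht = 0.0
    for j in range(gm.n_sites):
        col = gm.dosage[:, j]
        pooled = col[col != MISSING]
        if pooled.size < 2:
            continue
        two_n = 2 * pooled.size
        p = pooled.sum() / two_n
        ht = two_n / (two_n - 1.0) * 2.0 * p * (1.0 - p)
        hws = []
        ok = True
        for rows in group_rows:
            sub = col[rows]
            sub = sub[sub != MISSING]
            if sub.size < 2:
                ok = False
                break
            tn = 2 * sub.size
            q = sub.sum() / tn
            hws.append(tn / (tn - 1.0) * 2.0 * q * (1.0 - q))
        if not ok or ht == 0:
            continue
        sum_hw += float(np.mean(hws))
        sum_ht += ht
    if sum_ht == 0:
        raise ValueError("no informative sites for F_ST")
    return 1.0 - sum_hw / sum_ht
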