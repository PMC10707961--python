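"""Site-frequency spectra: construction, folding, projection, likelihood.

A spectrum over n haploid genomes is a vector of SNP counts indexed by
derived-allele class 0..n (unfolded, requires outgroup polarization) or
minor-allele class 0..floor(n/2) (folded).  The monomorphic classes are
always masked: the composite likelihood is conditioned on polymorphism.

Missing data are handled by per-site hypergeometric projection: a site
observed with n_site non-missing copies and i derived copies contributes
expected mass C(i,j)C(n_site-i,m-j)/C(n_site,m) to class j of a spectrum
down-projected to m copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, log

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SiteFrequencySpectrum:
    """Counts per allele-frequency class for n haploid genomes."""

    counts: np.ndarray  # length n+1, entries may be fractional (projection)
    folded: bool
    masked: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < -1e-9):
            raise ValueError("negative SFS entry")
        n = self.n
        self.masked = set(self.masked) | {0, n}
        if self.folded:
            self.masked |= set(range(n // 2 + 1, n + 1))
            if np.any(self.counts[n // 2 + 1 :] != 0):
                raise ValueError("folded SFS has mass above n/2")

    @property
    def n(self) -> int:
        return len(self.counts) - 1

    def unmasked_indices(self) -> np.ndarray:
        return np.array([j for j in range(self.n + 1) if j not in self.masked])

    @property
    def n_snps(self) -> float:
        return float(self.counts[self.unmasked_indices()].sum())

    def fold(self) -> "SiteFrequencySpectrum":
        """Fold onto minor-allele classes: eta_j = xi_j + xi_{n-j}."""
        if self.folded:
            return self
        n = self.n
        out = np.zeros(n + 1)
        for j in range(n // 2 + 1):
            out[j] = self.counts[j] + (self.counts[n - j] if j != n - j else 0)
        return SiteFrequencySpectrum(out, folded=True)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n} {'folded' if self.folded else 'unfolded'}\n")
            fh.write(" ".join(f"{c:.6g}" for c in self.counts) + "\n")

    @classmethod
    def read(cls, path) -> "SiteFrequencySpectrum":
        with open(path) as fh:
            header = fh.readline().split()
            counts = np.array([float(x) for x in fh.readline().split()])
        n, kind = int(header[0]), header[1]
        if len(counts) != n + 1:
            raise ValueError("SFS length does not match header")
        return cls(counts, folded=(kind == "folded"))


@dataclass
class JointSFS:
    """Sparse multidimensional SFS over several populations.

    ``axes`` is an ordered list of (population, haploid size); ``counts``
    maps derived-count tuples to (possibly fractional) SNP counts.  The
    all-zero and all-fixed configurations are the masked monomorphic
    corners.
    """

    axes: list[tuple[str, int]]
    counts: dict[tuple[int, ...], float]
    folded: bool = False

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(n + 1 for _, n in self.axes)

    def _corners(self) -> set[tuple[int, ...]]:
        return {
            tuple(0 for _ in self.axes),
            tuple(n for _, n in self.axes),
        }

    def unmasked_items(self) -> list[tuple[tuple[int, ...], float]]:
        corners = self._corners()
        return [(k, v) for k, v in sorted(self.counts.items()) if k not in corners]

    @property
    def n_snps(self) -> float:
        return float(sum(v for _, v in self.unmasked_items()))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                " ".join(f"{p}:{n}" for p, n in self.axes)
                + (" folded" if self.folded else " unfolded")
                + "\n"
            )
            for k, v in sorted(self.counts.items()):
                fh.write(" ".join(map(str, k)) + f"\t{v:.6g}\n")

    @classmethod
    def read(cls, path) -> "JointSFS":
        with open(path) as fh:
            head = fh.readline().split()
            folded = head[-1] == "folded"
            axes = [(t.split(":")[0], int(t.split(":")[1])) for t in head[:-1]]
            counts: dict[tuple[int, ...], float] = {}
            for line in fh:
                cfg, v = line.rsplit("\t", 1)
                counts[tuple(int(x) for x in cfg.split())] = float(v)
        return cls(axes=axes, counts=counts, folded=folded)


def _project_mass(i: int, n: int, m: int) -> np.ndarray:
    """Expected class mass of one site with i derived of n copies,
    down-sampled to m copies (hypergeometric)."""
    denom = comb(n, m)
    out = np.zeros(m + 1)
    for j in range(max(0, m - (n - i)), min(i, m) + 1):
        out[j] = comb(i, j) * comb(n - i, m - j) / denom
    return out


def project_sfs(sfs: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Expected hypergeometric projection of a spectrum to m copies."""
    n = sfs.n
    if m > n:
        raise ValueError("cannot project to a larger sample size")
    if m == n:
        return sfs
    out = np.zeros(m + 1)
    for i in range(n + 1):
        if sfs.counts[i]:
            out += sfs.counts[i] * _project_mass(i, n, m)
    if sfs.folded:
        # projection of a folded spectrum spreads mass above m/2; refold
        res = SiteFrequencySpectrum(out, folded=False)
        return res.fold()
    return SiteFrequencySpectrum(out, folded=False)


def _polarize(gm: GenotypeMatrix, outgroup_rows: list[int]):
    """Per-site ancestral state from the outgroup: 0 if outgroup is fixed
    for the reference allele, 1 if fixed for the alternate; None when the
    outgroup is polymorphic or has no calls (site excluded from unfolded
    spectra)."""
    anc = []
    for j in range(gm.n_sites):
        og = gm.dosage[outgroup_rows, j]
        og = og[og != MISSING]
        if og.size == 0:
            anc.append(None)
            continue
        alt = int(og.sum())
        total = gm.ploidy * og.size
        if alt == 0:
            anc.append(0)
        elif alt == total:
            anc.append(1)
        else:
            anc.append(None)
    return anc


def build_sfs(
    gm: GenotypeMatrix,
    fold: bool = True,
    outgroup_label: str | None = None,
    project_to: int | None = None,
) -> SiteFrequencySpectrum:
    """Build a (folded or unfolded) SFS from a genotype matrix.

    Unfolded spectra require an outgroup label for polarization; sites
    where the outgroup is polymorphic or uncalled are excluded (logged).
    With ``project_to=m`` each site with >= m non-missing allele copies is
    individually projected to m copies; otherwise only complete-data sites
    contribute at the full sample size.
    """
    if not fold and outgroup_label is None:
        raise ValueError("unfolded SFS requires an outgroup for polarization")
    out_rows = gm.samples_in(outgroup_label) if outgroup_label else []
    in_rows = [i for i in range(gm.n_samples) if i not in set(out_rows)]
    anc = _polarize(gm, out_rows) if outgroup_label else [0] * gm.n_sites

    n_full = gm.ploidy * len(in_rows)
    m = project_to if project_to is not None else n_full
    if m > n_full:
        raise ValueError("projection size exceeds sample size")
    counts = np.zeros(m + 1)
    n_excluded_polarization = 0
    n_excluded_missing = 0
    for j in range(gm.n_sites):
        if anc[j] is None:
            n_excluded_polarization += 1
            continue
        col = gm.dosage[in_rows, j]
        col = col[col != MISSING]
        n_site = gm.ploidy * col.size
        if n_site < m or (project_to is None and n_site < n_full):
            n_excluded_missing += 1
            continue
        derived = int(col.sum()) if anc[j] == 0 else n_site - int(col.sum())
        counts += _project_mass(derived, n_site, m)
    if n_excluded_polarization:
        logger.info("excluded %d site(s) lacking outgroup polarization", n_excluded_polarization)
    if n_excluded_missing:
        logger.info("excluded %d site(s) with too much missing data", n_excluded_missing)
    spec = SiteFrequencySpectrum(counts, folded=False)
    return spec.fold() if fold else spec


def build_joint_sfs(
    gm: GenotypeMatrix,
    populations: list[str],
    outgroup_label: str,
) -> JointSFS:
    """Unfolded joint SFS over several populations, polarized by the
    outgroup major state; complete-data sites only."""
    out_rows = gm.samples_in(outgroup_label)
    pop_rows = [gm.samples_in(p) for p in populations]
    for p, rows in zip(populations, pop_rows):
        if not rows:
            raise ValueError(f"no samples for population {p!r}")
    anc = _polarize(gm, out_rows)
    axes = [(p, gm.ploidy * len(rows)) for p, rows in zip(populations, pop_rows)]
    counts: dict[tuple[int, ...], float] = {}
    for j in range(gm.n_sites):
        if anc[j] is None:
            continue
        cfg = []
        ok = True
        for rows in pop_rows:
            col = gm.dosage[rows, j]
            if np.any(col == MISSING):
                ok = False
                break
            alt = int(col.sum())
            cfg.append(alt if anc[j] == 0 else gm.ploidy * len(rows) - alt)
        if ok:
            key = tuple(cfg)
            counts[key] = counts.get(key, 0.0) + 1.0
    return JointSFS(axes=axes, counts=counts, folded=False)


P_FLOOR = 1e-10


def composite_loglik(obs, expected_probs) -> float:
    """Composite log-likelihood sum_j m_j ln(p_j) over unmasked entries.

    ``expected_probs`` is an array matching a :class:`SiteFrequencySpectrum`
    or a dict matching a :class:`JointSFS`; probabilities are floored at
    1e-10 and renormalized over the unmasked entries before use.
    """
    if isinstance(obs, SiteFrequencySpectrum):
        idx = obs.unmasked_indices()
        m = obs.counts[idx]
        p = np.asarray(expected_probs, dtype=float)
        if len(p) != obs.n + 1:
            raise ValueError("expected_probs length mismatch")
        p = np.maximum(p[idx], P_FLOOR)
    elif isinstance(obs, JointSFS):
        items = obs.unmasked_items()
        m = np.array([v for _, v in items])
        p = np.array([max(float(expected_probs.get(k, 0.0)), P_FLOOR) for k, _ in items])
    else:
        raise TypeError("obs must be a SiteFrequencySpectrum or JointSFS")
    p = p / p.sum()
    mask = m > 0
    return float(np.sum(m[mask] * np.log(p[mask])))


def aic(lnl: float, k: int) -> float:
    """Akaike information criterion, AIC = 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 2.0 * k - 2.0 * lnl
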