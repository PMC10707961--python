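"""Mismatch distributions and sudden-expansion dating.

The mismatch distribution counts pairwise sequence differences among
haplotypes.  Under a sudden expansion (haploid effective size theta0/2u
jumping to theta1/2u at tau = 2ut mutational units before the present)
the expected distribution is the classic closed form

    F_j(tau) = G_j(theta1)
             + exp(-tau (theta1+1)/theta1)
               * sum_{i<=j} tau^{j-i}/(j-i)! * (G_i(theta0) - G_i(theta1))

with G_j(theta) = theta^j / (1+theta)^{j+1} the equilibrium geometric.
At tau = 0 it reduces to G(theta0); as tau -> inf, to G(theta1).

Fitting minimizes the sum of squared differences (SSD) between observed
and expected frequencies over the observed difference classes (grid over
log tau and log theta, then local refinement); significance comes from a
parametric bootstrap that re-simulates a single non-recombining locus
under the fitted expansion and refits each replicate.  tau converts to
calendar time as t = tau / (2 m_T mu) with m_T the concatenated locus
length in bp and mu the per-site per-year mutation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import poisson

from .coalescent import DemographicModel, SizeChange, simulate_sequences
from .genotypes import HaplotypeAlignment

logger = logging.getLogger(__name__)

_MISSING_SYMBOLS = {"N", "n", "-", "?"}


@dataclass
class MismatchFit:
    observed: np.ndarray  # counts of difference classes 0..max
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_value: float | None = None
    tau_ci: tuple[float, float] | None = None


def mismatch_distribution(haplotypes) -> np.ndarray:
    """Counts of unordered pairs differing at exactly d columns.

    Accepts a :class:`HaplotypeAlignment` or a list of equal-length
    strings; missing symbols (N, -, ?) are excluded pairwise.
    """
    if isinstance(haplotypes, HaplotypeAlignment):
        seqs = haplotypes.sequences
    else:
        seqs = list(haplotypes)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences differ in length")
    arr = np.array([list(s) for s in seqs])
    ok = ~np.isin(arr, list(_MISSING_SYMBOLS))
    n = len(seqs)
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            diffs.append(int(np.sum((arr[i] != arr[j]) & both)))
    counts = np.zeros(max(diffs) + 1, dtype=int)
    for d in diffs:
        counts[d] += 1
    return counts


def _geometric(theta: float, max_d: int) -> np.ndarray:
    """Equilibrium pairwise-difference distribution G_j(theta)."""
    j = np.arange(max_d + 1)
    if theta <= 0:
        out = np.zeros(max_d + 1)
        out[0] = 1.0
        return out
    theta = min(theta, 1e12)  # finite cap; the shape is flat-zero beyond
    # log form avoids overflow of theta**j at large theta or j
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(
    theta0: float, theta1: float, tau: float, max_d: int | None = None
) -> np.ndarray:
    """Expected sudden-expansion mismatch probabilities for classes
    0..max_d; max_d is chosen adaptively (tail mass < 1e-6) when omitted."""
    if min(theta0, theta1, tau) < 0:
        raise ValueError("parameters must be nonnegative")
    if max_d is None:
        max_d = 20
        while True:
            f = expected_mismatch(theta0, theta1, tau, max_d)
            if 1.0 - f.sum() < 1e-6 or max_d > 100_000:
                return f
            max_d *= 2
    g1 = _geometric(theta1, max_d)
    if tau == 0:
        return _geometric(theta0, max_d)
    g0 = _geometric(theta0, max_d)
    delta = g0 - g1
    w = poisson.pmf(np.arange(max_d + 1), tau)  # exp(-tau) tau^k / k!
    conv = np.convolve(delta, w)[: max_d + 1]
    damp = np.exp(-tau / theta1) if theta1 > 0 else 0.0
    f = g1 + damp * conv
    return np.clip(f, 0.0, None)


def _ssd(obs_freq: np.ndarray, theta0: float, theta1: float, tau: float) -> float:
    exp_f = expected_mismatch(theta0, theta1, tau, max_d=len(obs_freq) - 1)
    return float(np.sum((obs_freq - exp_f) ** 2))


def fit_expansion(observed: np.ndarray) -> MismatchFit:
    """Fit (tau, theta0, theta1) by direct SSD minimization.

    Coarse grid over log tau in [-3, 2] and log theta, then Nelder-Mead
    refinement in (log tau, log theta0, log (theta1-theta0)) so that
    theta0 <= theta1 by construction.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.sum() <= 0:
        raise ValueError("empty observed distribution")
    obs_freq = observed / observed.sum()
    if len(observed) < 2 or np.count_nonzero(observed) < 2:
        logger.warning("degenerate mismatch distribution; returning tau = 0 fit")
        mean_d = float(np.average(np.arange(len(observed)), weights=observed))
        return MismatchFit(
            observed=observed, tau=0.0, theta0=mean_d, theta1=mean_d,
            ssd=_ssd(obs_freq, mean_d, mean_d, 0.0),
        )

    taus = np.concatenate([[0.0], np.logspace(-3, 2, 16)])
    thetas0 = np.logspace(-2, 1.5, 8)
    dthetas = np.logspace(-2, 3, 8)
    best = (np.inf, 1.0, 1.0, 1.0)
    for tau in taus:
        for t0 in thetas0:
            for dt in dthetas:
                s = _ssd(obs_freq, t0, t0 + dt, tau)
                if s < best[0]:
                    best = (s, tau, t0, t0 + dt)
    _, tau, t0, t1 = best

    def obj(x):
        lt, l0, ld = np.clip(x, -30.0, 30.0)
        return _ssd(obs_freq, np.exp(l0), np.exp(l0) + np.exp(ld), np.exp(lt))

    x0 = np.log([max(tau, 1e-4), t0, max(t1 - t0, 1e-4)])
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-12})
    if res.fun <= best[0]:
        lt, l0, ld = np.clip(res.x, -30.0, 30.0)
        tau = float(np.exp(lt))
        t0 = float(np.exp(l0))
        t1 = t0 + float(np.exp(ld))
        ssd = float(res.fun)
    else:
        ssd = float(best[0])
    if tau < 1e-3:
        tau = 0.0
        ssd = _ssd(obs_freq, t0, t1, tau)
    return MismatchFit(observed=observed, tau=tau, theta0=t0, theta1=t1, ssd=ssd)


def _expansion_model(theta0: float, theta1: float, tau: float) -> DemographicModel:
    """Haploid coalescent equivalent of the fitted expansion.

    With the per-locus rate fixed at u = 1/2, mutational units equal
    generations: sizes are theta1 (present) and theta0 (past), the change
    sits at tau generations.
    """
    n1 = max(theta1, 1e-3)
    n0 = max(theta0, 1e-3)
    changes = [SizeChange(max(tau, 1e-6), "pop", n0)]
    return DemographicModel({"pop": n1}, size_changes=changes, ploidy=1)


def ssd_pvalue(
    fit: MismatchFit,
    n_samples: int,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Parametric-bootstrap p-value for the SSD goodness-of-fit statistic.

    Simulates ``n_boot`` single-locus datasets of ``n_samples`` haplotypes
    under the fitted expansion, refits each, and returns the fraction with
    SSD >= the observed SSD.  Also stores the bootstrap percentile CI of
    tau (lower-bounded at 0) on ``fit``.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    model = _expansion_model(fit.theta0, fit.theta1, fit.tau)
    ssds = np.empty(n_boot)
    taus = np.empty(n_boot)
    for b in range(n_boot):
        aln = simulate_sequences(
            model, {"pop": n_samples}, seq_len=1, mu=0.5,
            seed=int(rng.integers(2**31 - 1)),
        )
        if aln.n_columns == 0:
            ssds[b], taus[b] = 0.0, 0.0
            continue
        refit = fit_expansion(mismatch_distribution(aln))
        ssds[b], taus[b] = refit.ssd, refit.tau
    p = float(np.mean(ssds >= fit.ssd - 1e-15))
    fit.p_value = p
    fit.tau_ci = (
        max(0.0, float(np.quantile(taus, 0.025))),
        float(np.quantile(taus, 0.975)),
    )
    return p


def expansion_time(tau: float, m_t: float, mu_per_site_per_year: float) -> float:
    """Calendar time of the expansion: t = tau / (2 m_T mu) years.

    ``mu_per_site_per_year`` is per site per year (divide a per-Myr rate
    by 1e6 first, or use :func:`expansion_time_myr`)."""
    if mu_per_site_per_year <= 0:
        raise ValueError("mutation rate must be positive")
    if m_t <= 0:
        raise ValueError("m_T must be positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return tau / (2.0 * m_t * mu_per_site_per_year)


def expansion_time_myr(tau: float, m_t: float, mu_per_site_per_myr: float) -> float:
    """Same as :func:`expansion_time` for a rate in substitutions/site/Myr."""
    return expansion_time(tau, m_t, mu_per_site_per_myr * 1e-6)
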