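"""Composite-likelihood fitting, AIC ranking, bootstrap intervals.

A model is fitted by maximizing the composite log-likelihood of the
observed SFS against the branch-statistic expected SFS of the model,
over log-scaled parameters, with multi-start derivative-free local
search (Nelder-Mead).  The expected-SFS Monte Carlo uses common random
numbers — the same simulation seed at every likelihood evaluation — so
the surface seen by the optimizer is deterministic and smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .coalescent import expected_joint_sfs, expected_sfs
from .models import ModelSpec
from .sfs import JointSFS, SiteFrequencySpectrum, aic, composite_loglik


@dataclass
class FitSettings:
    """Optimizer settings: starts, Monte Carlo replicates per likelihood
    evaluation, and local-search iteration cap."""

    n_starts: int = 20
    n_replicates: int = 5000
    maxiter: int = 200
    xatol: float = 0.01
    fatol: float = 0.01


@dataclass
class FitResult:
    model_name: str
    params: dict[str, float]
    lnl: float
    k: int
    aic: float
    converged: bool = True
    delta_aic: float | None = None
    rank: int | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot_failures: int = 0
    data_signature: tuple = ()


def _data_signature(obs) -> tuple:
    if isinstance(obs, SiteFrequencySpectrum):
        return ("sfs", obs.n, obs.folded, round(obs.n_snps, 6))
    return ("joint", tuple(obs.axes), round(obs.n_snps, 6))


def _expected_probs(spec: ModelSpec, free: dict[str, float], obs, settings, crn_seed):
    model = spec.build(free)
    if isinstance(obs, SiteFrequencySpectrum):
        return expected_sfs(
            model,
            obs.n,
            n_replicates=settings.n_replicates,
            seed=crn_seed,
            folded=obs.folded,
        )
    sample_config = {p: n for p, n in obs.axes}
    return expected_joint_sfs(
        model, sample_config, n_replicates=settings.n_replicates, seed=crn_seed
    )


def fit_model(
    obs,
    spec: ModelSpec,
    settings: FitSettings | None = None,
    seed: int | None = None,
    init_params: list[dict[str, float]] | None = None,
) -> FitResult:
    """Maximize the composite likelihood of ``obs`` under ``spec``.

    Starting points are drawn log-uniformly within the search bounds; each
    is refined by Nelder-Mead in log-parameter space.  ``init_params``
    supplies extra warm-start points (e.g. a nested model's solution).
    Reproducible given ``seed``.  A model with no free parameters is
    evaluated once.

    Note the scale invariance of the coalescent: multiplying every size
    and time by a constant leaves the normalized SFS unchanged, so only
    size ratios and times in units of N are identifiable from a
    polymorphism-conditioned SFS.
    """
    settings = settings or FitSettings()
    if isinstance(obs, SiteFrequencySpectrum):
        if obs.n_snps <= 0:
            raise ValueError("empty observed SFS")
    elif isinstance(obs, JointSFS):
        if obs.n_snps <= 0:
            raise ValueError("empty observed joint SFS")
    else:
        raise TypeError("obs must be an SFS or a joint SFS")

    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31 - 1))

    names = spec.param_names
    if not names:
        lnl = composite_loglik(
            obs, _expected_probs(spec, {}, obs, settings, crn_seed)
        )
        return FitResult(
            model_name=spec.name,
            params=spec.full_params({}),
            lnl=lnl,
            k=0,
            aic=aic(lnl, 0),
            data_signature=_data_signature(obs),
        )

    lo = np.log([spec.bounds[n][0] for n in names])
    hi = np.log([spec.bounds[n][1] for n in names])

    def objective(theta: np.ndarray) -> float:
        free = dict(zip(names, np.exp(np.clip(theta, lo, hi))))
        probs = _expected_probs(spec, free, obs, settings, crn_seed)
        return -composite_loglik(obs, probs)

    starts = []
    for init in init_params or []:
        starts.append(
            np.clip(np.log([init[n] for n in names]), lo, hi)
        )
    starts += [rng.uniform(lo, hi) for _ in range(settings.n_starts)]

    best_theta, best_val = None, np.inf
    improved = False
    for theta0 in starts:
        f0 = objective(theta0)
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxiter": settings.maxiter,
                "xatol": settings.xatol,
                "fatol": settings.fatol,
            },
        )
        if res.fun < f0 - 1e-9:
            improved = True
        cand_val, cand_theta = (
            (res.fun, res.x) if res.fun <= f0 else (f0, theta0)
        )
        if cand_val < best_val:
            best_val, best_theta = cand_val, cand_theta

    free = dict(zip(names, np.exp(np.clip(best_theta, lo, hi))))
    lnl = -best_val
    return FitResult(
        model_name=spec.name,
        params=spec.full_params(free),
        lnl=lnl,
        k=spec.k,
        aic=aic(lnl, spec.k),
        converged=improved,
        data_signature=_data_signature(obs),
    )


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """AIC ranking table with both published ΔAIC sign conventions.

    ``delta_aic_best_minus`` = AIC_best − AIC (≤ 0 for non-best models);
    ``delta_aic_minus_best`` = AIC − AIC_best (≥ 0).  Ties are broken in
    favour of the smaller parameter count.
    """
    if len(fits) < 2:
        raise ValueError("ranking needs at least two fits")
    sigs = {f.data_signature for f in fits if f.data_signature}
    if len(sigs) > 1:
        raise ValueError("fits were computed on different observed data")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k))
    best_aic = fits[order[0]].aic
    rows = []
    for rank, i in enumerate(order, start=1):
        f = fits[i]
        f.rank = rank
        f.delta_aic = f.aic - best_aic
        rows.append(
            {
                "Model": f.model_name,
                "LnMaxEstLhood": f.lnl,
                "Nparams": f.k,
                "AIC": f.aic,
                "delta_aic_best_minus": best_aic - f.aic,
                "delta_aic_minus_best": f.aic - best_aic,
                "Rank": rank,
            }
        )
    return pd.DataFrame(rows)


def likelihood_distribution(
    obs,
    spec: ModelSpec,
    params: dict[str, float],
    n_datasets: int = 100,
    settings: FitSettings | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Distribution of composite lnL for datasets simulated under a fitted
    model, each with the observed SNP total and scored against the model's
    own expected spectrum."""
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31 - 1))
    free = {k: params[k] for k in spec.param_names}
    probs = _expected_probs(spec, free, obs, settings, crn_seed)
    s_total = int(round(obs.n_snps))
    out = np.empty(n_datasets)
    if isinstance(obs, SiteFrequencySpectrum):
        idx = obs.unmasked_indices()
        p = np.maximum(np.asarray(probs)[idx], 1e-10)
        p = p / p.sum()
        for i in range(n_datasets):
            m = rng.multinomial(s_total, p)
            sim = SiteFrequencySpectrum(
                _scatter(m, idx, obs.n + 1), folded=obs.folded
            )
            out[i] = composite_loglik(sim, probs)
    else:
        keys = sorted(set(probs) | {k for k, _ in obs.unmasked_items()})
        p = np.maximum([probs.get(k, 0.0) for k in keys], 1e-10)
        p = p / p.sum()
        for i in range(n_datasets):
            m = rng.multinomial(s_total, p)
            sim = JointSFS(
                axes=obs.axes,
                counts={k: float(c) for k, c in zip(keys, m) if c},
                folded=obs.folded,
            )
            out[i] = composite_loglik(sim, probs)
    return out


def _scatter(values, idx, length):
    out = np.zeros(length)
    out[idx] = values
    return out


def distribution_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of points of each distribution falling inside the range of
    the other, averaged; 0 means complete separation."""
    a, b = np.asarray(a), np.asarray(b)
    in_b = np.mean((a >= b.min()) & (a <= b.max()))
    in_a = np.mean((b >= a.min()) & (b <= a.max()))
    return float((in_a + in_b) / 2.0)


def bootstrap_ci(
    obs,
    spec: ModelSpec,
    params: dict[str, float],
    n_boot: int = 100,
    level: float = 0.95,
    settings: FitSettings | None = None,
    seed: int | None = None,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Parametric-bootstrap percentile intervals for the free parameters.

    Datasets are simulated under the fitted model with the observed SNP
    total and refitted; replicates whose refit fails are dropped and
    counted.  Returns (per-parameter (low, high), n_failures).
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31 - 1))
    free = {k: params[k] for k in spec.param_names}
    probs = _expected_probs(spec, free, obs, settings, crn_seed)
    s_total = int(round(obs.n_snps))

    estimates: dict[str, list[float]] = {n: [] for n in spec.param_names}
    n_fail = 0
    for b in range(n_boot):
        boot_seed = int(rng.integers(2**31 - 1))
        try:
            if isinstance(obs, SiteFrequencySpectrum):
                idx = obs.unmasked_indices()
                p = np.maximum(np.asarray(probs)[idx], 1e-10)
                p = p / p.sum()
                m = np.random.default_rng(boot_seed).multinomial(s_total, p)
                sim = SiteFrequencySpectrum(
                    _scatter(m, idx, obs.n + 1), folded=obs.folded
                )
            else:
                keys = sorted(probs)
                p = np.maximum([probs[k] for k in keys], 1e-10)
                p = p / p.sum()
                m = np.random.default_rng(boot_seed).multinomial(s_total, p)
                sim = JointSFS(
                    axes=obs.axes,
                    counts={k: float(c) for k, c in zip(keys, m) if c},
                    folded=obs.folded,
                )
            refit = fit_model(sim, spec, settings, seed=boot_seed)
            if not np.isfinite(refit.lnl):
                raise RuntimeError("non-finite refit")
            for n in spec.param_names:
                estimates[n].append(refit.params[n])
        except Exception:
            n_fail += 1
    alpha = (1.0 - level) / 2.0
    ci = {}
    for n, vals in estimates.items():
        if vals:
            ci[n] = (
                float(np.quantile(vals, alpha)),
                float(np.quantile(vals, 1.0 - alpha)),
            )
    return ci, n_fail
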