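"""Model fitting, AIC ranking, likelihood distributions, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from ficipop.coalescent import DemographicModel, simulate_snp_matrix
from ficipop.fitting import (
    FitResult,
    FitSettings,
    bootstrap_ci,
    distribution_overlap,
    fit_model,
    likelihood_distribution,
    rank_models,
)
from ficipop.fixtures import ficifolia_model
from ficipop.models import ModelSpec, single_population_catalog
from ficipop.sfs import SiteFrequencySpectrum, aic, build_sfs

CATALOG = single_population_catalog(n_bounds=(10, 1e5), t_bounds=(1, 1e4))
FAST = FitSettings(n_starts=4, n_replicates=2000, maxiter=120)


def _simulate_obs(model, n_hap=36, n_snps=1500, seed=0, project_to=18):
    gm = simulate_snp_matrix(model, {next(iter(model.deme_sizes)): n_hap},
                             n_snps, seed=seed)
    return build_sfs(gm, fold=True, project_to=project_to)


def test_constant_n_fit_recovers_spectrum_shape():
    """The normalized SFS is invariant to jointly rescaling sizes and
    times, so absolute N is not identifiable from a polymorphism-
    conditioned spectrum; the fit must instead reproduce the Watterson
    shape of the generating constant-size model."""
    from ficipop.coalescent import expected_sfs

    truth = 3000.0
    obs = _simulate_obs(DemographicModel({"pop": truth}), n_snps=2524, seed=1)
    fit = fit_model(obs, CATALOG[0], FAST, seed=2)
    fitted = expected_sfs(
        DemographicModel({"pop": fit.params["n_curr"]}), obs.n,
        n_replicates=10_000, seed=3, folded=True,
    )
    want = expected_sfs(DemographicModel({"pop": truth}), obs.n,
                        n_replicates=10_000, seed=4, folded=True)
    assert np.allclose(fitted, want, atol=0.02)
    assert fit.k == 1
    assert fit.aic == pytest.approx(aic(fit.lnl, 1))


def test_added_parameters_do_not_lose_likelihood():
    """Nested catalog: more free parameters never decrease maximized lnL
    (same observed data and common-random-number stream); larger models
    are warm-started at the embedded smaller-model solution."""
    obs = _simulate_obs(ficifolia_model(scale=0.01), n_snps=2000, seed=3)
    fit0 = fit_model(obs, CATALOG[0], FAST, seed=4)
    embed1 = {"n_curr": fit0.params["n_curr"],
              "n_anc1": fit0.params["n_curr"], "t1": 100.0}
    fit1 = fit_model(obs, CATALOG[1], FAST, seed=4, init_params=[embed1])
    embed2 = {"n_curr": fit1.params["n_curr"], "n_anc1": fit1.params["n_anc1"],
              "n_anc2": fit1.params["n_anc1"], "t1": fit1.params["t1"],
              "dt2": 100.0}
    fit2 = fit_model(obs, CATALOG[2], FAST, seed=4, init_params=[embed2])
    assert fit1.lnl >= fit0.lnl - 1e-3
    assert fit2.lnl >= fit1.lnl - 1e-3


def test_zero_parameter_model_single_evaluation():
    fixed_spec = ModelSpec(
        name="fixed-constant",
        description="pinned size",
        param_names=[],
        bounds={},
        builder=lambda p: DemographicModel({"pop": p["n_curr"]}),
        fixed={"n_curr": 1000.0},
    )
    obs = _simulate_obs(DemographicModel({"pop": 1000.0}), n_snps=500, seed=5)
    fit = fit_model(obs, fixed_spec, FAST, seed=6)
    assert fit.k == 0
    assert fit.aic == pytest.approx(-2 * fit.lnl)


def test_empty_sfs_rejected():
    empty = SiteFrequencySpectrum(np.zeros(19), folded=True)
    with pytest.raises(ValueError):
        fit_model(empty, CATALOG[0], FAST, seed=1)


def _fit_from_printed(name, lnl, k, sig=("sfs", 18, True, 2524.0)):
    return FitResult(model_name=name, params={}, lnl=lnl, k=k,
                     aic=aic(lnl, k), data_signature=sig)


def test_rank_models_three_single_pop_models():
    """Published single-population stage: printed lnL/k triples rank the
    two-change model first and constant size last."""
    fits = [
        _fit_from_printed("constant", -5144.763, 1),
        _fit_from_printed("one-change", -5142.073, 3),
        _fit_from_printed("two-change", -5139.025, 5),
    ]
    table = rank_models(fits)
    ranks = dict(zip(table.Model, table.Rank))
    assert ranks == {"two-change": 1, "one-change": 2, "constant": 3}
    row = table.set_index("Model").loc["constant"]
    assert row.delta_aic_best_minus == pytest.approx(-3.48, abs=0.01)
    assert row.delta_aic_minus_best == pytest.approx(3.48, abs=0.01)


def test_rank_models_five_taxa_stage():
    """Published crop-wild stage: gene flow with the fourth relative wins,
    with the third-relative model second."""
    fits = [
        _fit_from_printed("I.1", -53713.31, 13),
        _fit_from_printed("I.2", -52057.21, 15),
        _fit_from_printed("I.3", -52272.53, 15),
        _fit_from_printed("I.4", -51958.6, 15),
        _fit_from_printed("I.5", -51269.55, 15),
    ]
    table = rank_models(fits).set_index("Model")
    assert table.loc["I.5", "Rank"] == 1
    assert table.loc["I.4", "Rank"] == 2
    assert table.loc["I.1", "delta_aic_minus_best"] == pytest.approx(4883.5, abs=0.1)


def test_rank_ties_broken_by_smaller_k():
    fits = [
        _fit_from_printed("big", -99.0, 3),
        _fit_from_printed("small", -101.0, 1),  # same AIC = 204
    ]
    table = rank_models(fits)
    assert table.iloc[0].Model == "small"


def test_rank_rejects_mismatched_data():
    fits = [
        _fit_from_printed("a", -10.0, 1, sig=("sfs", 18, True, 100.0)),
        _fit_from_printed("b", -11.0, 1, sig=("sfs", 18, True, 200.0)),
    ]
    with pytest.raises(ValueError):
        rank_models(fits)


def test_likelihood_distribution_self_overlap():
    obs = _simulate_obs(DemographicModel({"pop": 1000.0}), n_snps=800, seed=7)
    d1 = likelihood_distribution(obs, CATALOG[0], {"n_curr": 1000.0},
                                 n_datasets=40, settings=FAST, seed=8)
    d2 = likelihood_distribution(obs, CATALOG[0], {"n_curr": 1000.0},
                                 n_datasets=40, settings=FAST, seed=9)
    assert distribution_overlap(d1, d2) > 0


def test_likelihood_distribution_separates_wrong_model():
    """Strong-bottleneck truth vs constant size at the observed SNP count:
    the two likelihood distributions should not overlap."""
    obs = _simulate_obs(ficifolia_model(scale=0.01), n_snps=2524, seed=10)
    best2 = fit_model(obs, CATALOG[2], FAST, seed=11)
    bestc = fit_model(obs, CATALOG[0], FAST, seed=12)
    free2 = {k: best2.params[k] for k in CATALOG[2].param_names}
    freec = {k: bestc.params[k] for k in CATALOG[0].param_names}
    d2 = likelihood_distribution(obs, CATALOG[2], free2, n_datasets=30,
                                 settings=FAST, seed=13)
    dc = likelihood_distribution(obs, CATALOG[0], freec, n_datasets=30,
                                 settings=FAST, seed=14)
    assert distribution_overlap(d2, dc) == 0.0
    assert d2.mean() > dc.mean()


def test_likelihood_distribution_degenerate_single_dataset():
    obs = _simulate_obs(DemographicModel({"pop": 1000.0}), n_snps=300, seed=15)
    d = likelihood_distribution(obs, CATALOG[0], {"n_curr": 1000.0},
                                n_datasets=1, settings=FAST, seed=16)
    assert len(d) == 1
    assert distribution_overlap(d, d) in (0.0, 1.0)


def test_bootstrap_ci_percentile_definition_and_coverage():
    """Parametric bootstrap on a constant-size model: the interval is the
    2.5-97.5 percentile band of refits and covers the generating size in
    most seeded trials."""
    truth = 2000.0
    tiny = FitSettings(n_starts=3, n_replicates=1000, maxiter=80)
    hits = 0
    n_trials = 10
    for trial in range(n_trials):
        obs = _simulate_obs(DemographicModel({"pop": truth}), n_snps=800,
                            seed=100 + trial)
        fit = fit_model(obs, CATALOG[0], tiny, seed=200 + trial)
        ci, n_fail = bootstrap_ci(
            obs, CATALOG[0], fit.params, n_boot=10, level=0.95,
            settings=tiny, seed=300 + trial,
        )
        lo, hi = ci["n_curr"]
        assert lo <= hi
        assert n_fail >= 0
        if lo <= truth <= hi:
            hits += 1
    assert hits >= 6  # loose desk-scale coverage check


def test_bootstrap_requires_ten_replicates():
    obs = _simulate_obs(DemographicModel({"pop": 1000.0}), n_snps=300, seed=17)
    with pytest.raises(ValueError):
        bootstrap_ci(obs, CATALOG[0], {"n_curr": 1000.0}, n_boot=5)
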