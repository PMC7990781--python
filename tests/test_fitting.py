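import numpy as np
import pandas as pd
import pytest

from flornet.data_model import ConditionKey, ExpressionDataset, Trajectory
from flornet.fitting import (
    CostContext,
    DESettings,
    compare_models,
    fit_model,
    nrmse,
    run_ensemble,
    wrss,
)
from flornet.ode_models import model_spec
from flornet.synthetic_data import TRUE_PARAMS_MC

MC = model_spec("MC")
WT_LD = ConditionKey("WT", "LD")
WT_SD = ConditionKey("WT", "SD")
WT_SCOPE = [WT_LD, WT_SD]

TOY_SETTINGS = DESettings(popsize=8, maxiter=60, tol=1e-10)


def _one_gene_dataset(means, gene="DET", scale=1.0):
    times = 7.0 * np.arange(1, len(means) + 1)
    frame = pd.DataFrame({
        "gene": gene, "tissue": "apex", "genotype": "WT", "photoperiod": "LD",
        "time": times, "mean": scale * np.asarray(means, float),
        "sd": 0.1 * scale * np.asarray(means, float)})
    return ExpressionDataset(frame), times


def _solutions(gene, times, values):
    return {(gene, WT_LD): Trajectory(gene, "apex", times, np.asarray(values, float))}


def test_wrss_hand_example():
    ds, times = _one_gene_dataset([2.0, 4.0])
    sols = _solutions("DET", times, [3.0, 4.0])
    # range = 2, residuals (1, 0): (1/4 + 0)
    assert wrss(sols, ds, [WT_LD]) == pytest.approx(0.25)
    assert nrmse(sols, ds, [WT_LD]) == pytest.approx(np.sqrt(0.25 / 2))


def test_wrss_zero_for_perfect_fit():
    ds, times = _one_gene_dataset([2.0, 4.0, 8.0])
    sols = _solutions("DET", times, [2.0, 4.0, 8.0])
    assert wrss(sols, ds, [WT_LD]) == 0.0
    assert nrmse(sols, ds, [WT_LD]) == 0.0


def test_wrss_scale_invariance():
    base, times = _one_gene_dataset([2.0, 4.0])
    doubled, _ = _one_gene_dataset([2.0, 4.0], scale=2.0)
    s1 = wrss(_solutions("DET", times, [3.0, 4.0]), base, [WT_LD])
    s2 = wrss(_solutions("DET", times, [6.0, 8.0]), doubled, [WT_LD])
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_wrss_missing_solution_point_raises():
    ds, times = _one_gene_dataset([2.0, 4.0])
    sols = _solutions("DET", times[:1], [2.0])
    with pytest.raises(KeyError, match="DET"):
        wrss(sols, ds, [WT_LD])


def test_nrmse_wrss_identity_random_fixtures():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = rng.integers(2, 9)
        means = rng.uniform(0.5, 10, n)
        ds, times = _one_gene_dataset(means)
        sols = _solutions("DET", times, means + rng.normal(0, 1, n))
        w = wrss(sols, ds, [WT_LD])
        r = nrmse(sols, ds, [WT_LD])
        assert r ** 2 * n == pytest.approx(w, rel=1e-12)


def test_wrss_splits_over_photoperiods(mech_dataset):
    ctx = CostContext(MC, mech_dataset, WT_SCOPE)
    sols = ctx.solutions(TRUE_PARAMS_MC.replace(v2=2.0, tau=1.0))
    total = wrss(sols, mech_dataset, WT_SCOPE)
    part = (wrss(sols, mech_dataset, [WT_LD]) + wrss(sols, mech_dataset, [WT_SD]))
    assert total == pytest.approx(part, rel=1e-12)


def test_cost_context_zero_at_truth(mech_dataset):
    ctx = CostContext(MC, mech_dataset, WT_SCOPE)
    assert ctx.cost(TRUE_PARAMS_MC) <= 1e-12


def test_fit_recovers_single_free_parameter(mech_dataset):
    truth = {f: TRUE_PARAMS_MC.get(f) for f in MC.free_parameter_names}
    fixed = {k: v for k, v in truth.items() if k != "v4"}
    fit = fit_model(MC, mech_dataset, WT_SCOPE, seed=0, de_settings=TOY_SETTINGS,
                    fixed_params=fixed)
    assert fit.params.v4 == pytest.approx(TRUE_PARAMS_MC.v4, rel=0.01)
    assert fit.wrss < 1e-6


def test_fit_bounded_away_from_truth_lands_on_bound(mech_dataset):
    truth = {f: TRUE_PARAMS_MC.get(f) for f in MC.free_parameter_names}
    fixed = {k: v for k, v in truth.items() if k != "v4"}
    fit = fit_model(MC, mech_dataset, WT_SCOPE, seed=0, de_settings=TOY_SETTINGS,
                    fixed_params=fixed, bounds={"v4": (2.0, 10.0)})  # truth is 0.7
    assert fit.params.v4 == pytest.approx(2.0, rel=1e-3)


def test_fit_deterministic_given_seed(mech_dataset):
    truth = {f: TRUE_PARAMS_MC.get(f) for f in MC.free_parameter_names}
    fixed = {k: v for k, v in truth.items() if k not in ("v4", "K9")}
    quick = DESettings(popsize=5, maxiter=20)
    a = fit_model(MC, mech_dataset, WT_SCOPE, seed=3, de_settings=quick, fixed_params=fixed)
    b = fit_model(MC, mech_dataset, WT_SCOPE, seed=3, de_settings=quick, fixed_params=fixed)
    assert a.wrss == b.wrss
    assert a.params == b.params


def test_ensemble_minimum_bounds_members(mech_dataset):
    truth = {f: TRUE_PARAMS_MC.get(f) for f in MC.free_parameter_names}
    fixed = {k: v for k, v in truth.items() if k != "v4"}
    quick = DESettings(popsize=5, maxiter=15)
    ens = run_ensemble(MC, mech_dataset, WT_SCOPE, n_runs=3, base_seed=10,
                       de_settings=quick, fixed_params=fixed)
    assert len(ens.fits) == 3
    assert ens.best_fit.wrss == min(f.wrss for f in ens.fits)
    assert {f.seed for f in ens.fits} == {10, 11, 12}


def test_compare_models():
    a = [0.1] * 20
    b = [0.9] * 20
    assert compare_models(a, a) == 1.0  # identical pooled samples
    assert compare_models(a, b, alternative="less") < 1e-4
    p_less = compare_models(a, b, alternative="less")
    p_greater = compare_models(b, a, alternative="greater")
    assert p_less == pytest.approx(p_greater)
    with pytest.raises(ValueError):
        compare_models([], [0.1])
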