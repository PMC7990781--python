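"""Parameter estimation and model comparison.

The cost is a weighted residual sum of squares: for every gene and every
observation time in the fitted scope, the squared model-data residual is
normalized by the squared dynamic range (u_max - u_min) of that gene's
data, so genes with very different expression scales contribute
comparably.  Models are scored with the normalized root-mean-square error
NRMSE = sqrt(wRSS / (N*T)), the square root of the mean normalized
squared residual over the N*T terms actually summed.

Free parameters are estimated by differential evolution.  Because the
data span several orders of magnitude, rates and Michaelis constants are
searched in log10 space (bounds 1e-3..1e3 by default); the delay tau and
the Hill exponent n are searched linearly.  Each model is fitted as an
ensemble of independent runs (20 in the full protocol) and the resulting
NRMSE distributions are compared with the one-sided Mann-Whitney-Wilcoxon
rank-sum test.

Scoring conventions: VEG1 has no SD data, so its SD solution is computed
but never scored; in the *gigas-2* background PIM is excluded from the
cost; the dynamic range is taken per gene per (genotype, photoperiod)
series entering the fit (the most local reading), with a config toggle
for a global range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution
from scipy.stats import mannwhitneyu

from .data_model import (
    ConditionKey,
    ExpressionDataset,
    Trajectory,
    safe_range_width,
)
from .ode_models import (
    MODELED_GENES,
    MODELED_TO_DATA,
    DataRegulators,
    ModelSpec,
    ParameterSet,
    _integrate_linear_profile,
    genotype_spec,
    synthesis_rate,
)

# default search box: three decades either side of the O(1) data scale
DEFAULT_BOUNDS = {"log": (1e-3, 1e3), "tau": (0.0, 14.0), "n": (1.0, 4.0)}


@dataclass
class DESettings:
    """Differential-evolution settings.

    best/1/bin with dithered mutation converges markedly faster than
    rand/1/bin on this cost in the log-parametrized space and is the
    default; every knob is config-exposed.
    """

    popsize: int = 15          # population = popsize * n_free_parameters
    maxiter: int = 2000
    strategy: str = "best1bin"
    mutation: tuple | float = (0.5, 1.0)
    recombination: float = 0.9
    tol: float = 1e-12
    polish: bool = True
    init: str = "sobol"
    fast_step: float = 0.5     # refinement step (days) of the cost integrator


@dataclass
class FitResult:
    params: ParameterSet
    wrss: float
    nrmse_by_scope: dict
    seed: int
    n_cost_evals: int
    converged: bool = True
    message: str = ""

    @property
    def nrmse(self) -> float:
        """NRMSE over the full fitted scope."""
        return self.nrmse_by_scope.get("full", float("nan"))


@dataclass
class EnsembleResult:
    fits: list

    @property
    def best(self) -> int:
        return int(np.argmin([f.wrss for f in self.fits]))

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best]

    def wrss_values(self) -> np.ndarray:
        return np.array([f.wrss for f in self.fits])

    def nrmse_values(self) -> np.ndarray:
        return np.array([f.nrmse for f in self.fits])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _scored_points(dataset, scope, exclusions=None, range_scope="per_series"):
    """Yield (gene, condition, times, data_means, width) for every scored series."""
    from .data_model import min_max_range

    for condition in scope:
        gspec = genotype_spec(condition.genotype)
        excluded = set(gspec.cost_excluded_genes)
        if exclusions:
            excluded |= set(exclusions.get(condition.genotype, ()))
        for gene in MODELED_GENES:
            if gene in excluded:
                continue
            data_gene, tissue = MODELED_TO_DATA[gene]
            if not dataset.has_series(data_gene, tissue, condition):
                continue  # e.g. VEG1 under SD: solution exists, never scored
            tr = dataset.series(data_gene, tissue, condition)
            if range_scope == "per_series":
                lo, hi = float(tr.values.min()), float(tr.values.max())
            else:
                lo, hi = min_max_range(dataset, data_gene, list(scope), tissue=tissue)
            yield gene, condition, tr.times, tr.values, safe_range_width(lo, hi)


def _solution_at(solutions, gene, condition, times):
    key = (gene, condition)
    if key not in solutions:
        raise KeyError(f"missing solution for gene {gene} in "
                       f"{condition.genotype}-{condition.photoperiod}")
    tr = solutions[key]
    idx = np.searchsorted(tr.times, times)
    if np.any(idx >= tr.times.size) or not np.allclose(tr.times[np.minimum(idx, tr.times.size - 1)], times):
        missing = times[(idx >= tr.times.size) | ~np.isclose(tr.times[np.minimum(idx, tr.times.size - 1)], times)]
        raise KeyError(f"solution for gene {gene} lacks time point(s) {missing}")
    return tr.values[idx]


def _accumulate(solutions, dataset, scope, exclusions, range_scope):
    ss, count = 0.0, 0
    for gene, condition, times, means, width in _scored_points(
            dataset, scope, exclusions, range_scope):
        u = _solution_at(solutions, gene, condition, times)
        ss += float(np.sum((u - means) ** 2)) / width ** 2
        count += times.size
    return ss, count


def wrss(solutions: Mapping, dataset: ExpressionDataset, scope: Iterable[ConditionKey],
         exclusions: Mapping | None = None, range_scope: str = "per_series") -> float:
    """Weighted residual sum of squares over the scored points in scope.

    ``solutions`` maps (modeled_gene, ConditionKey) to a Trajectory whose
    time grid covers the data times exactly.
    """
    ss, _ = _accumulate(solutions, dataset, list(scope), exclusions, range_scope)
    return ss


def nrmse(solutions: Mapping, dataset: ExpressionDataset, scope: Iterable[ConditionKey],
          exclusions: Mapping | None = None, range_scope: str = "per_series") -> float:
    """sqrt(wRSS / (N*T)) with N*T the number of terms actually summed."""
    ss, count = _accumulate(solutions, dataset, list(scope), exclusions, range_scope)
    if count == 0:
        raise ValueError("no scored data points in scope")
    return float(np.sqrt(ss / count))


# ---------------------------------------------------------------------------
# Fast cost context
# ---------------------------------------------------------------------------

class CostContext:
    """Pre-resolved scoring layout for one (spec, dataset, scope).

    Regulator trajectories, data times, dynamic-range widths and the
    refined integration grid are all parameter-independent, so they are
    prepared once; evaluating the cost for a candidate parameter vector
    is then a handful of vectorized array operations per gene.
    """

    def __init__(self, spec: ModelSpec, dataset: ExpressionDataset,
                 scope: Sequence[ConditionKey], range_scope: str = "per_series",
                 fast_step: float = 0.5):
        self.spec = spec
        self.dataset = dataset
        self.scope = list(scope)
        self.fast_step = fast_step
        self.per_condition = []
        for condition in self.scope:
            regs = DataRegulators(dataset, condition)
            scored = [
                (gene, times, means, width)
                for gene, cond, times, means, width in _scored_points(
                    dataset, [condition], None, range_scope)
            ]
            t0 = regs.first_day()
            t_end = max(float(t[-1]) for _, t, _, _ in scored) if scored else t0
            fine = np.arange(t0, t_end + fast_step, fast_step)
            for _, t, _, _ in scored:
                fine = np.union1d(fine, t)
            self.per_condition.append((condition, regs, scored, fine))
        self.n_points = sum(t.size for _, _, sc, _ in self.per_condition
                            for _, t, _, _ in sc)

    def solutions(self, params: ParameterSet) -> dict:
        """Simulate every scored gene on its data grid (fast integrator)."""
        out = {}
        for condition, regs, scored, fine in self.per_condition:
            regdict = regs.at(fine, params, self.spec.binding_mode)
            forced = regs.genotype_spec.forced_zero_genes
            for gene, times, _, _ in scored:
                data_gene, _tissue = MODELED_TO_DATA[gene]
                if data_gene in forced:
                    out[(gene, condition)] = Trajectory(gene, "apex", times,
                                                        np.zeros_like(times))
                    continue
                s = np.asarray(synthesis_rate(self.spec, gene, params, regdict),
                               dtype=float)
                u = _integrate_linear_profile(fine, s, params.lam,
                                              regs.initial_value(gene), times)
                out[(gene, condition)] = Trajectory(gene, "apex", times, u)
        return out

    def cost(self, params: ParameterSet) -> float:
        sols = self.solutions(params)
        ss = 0.0
        for condition, regs, scored, _ in self.per_condition:
            for gene, times, means, width in scored:
                u = sols[(gene, condition)].values
                ss += float(np.sum((u - means) ** 2)) / width ** 2
        return ss


# ---------------------------------------------------------------------------
# Differential evolution
# ---------------------------------------------------------------------------

def default_bounds(spec: ModelSpec) -> dict:
    """Search bounds per free parameter (natural scale)."""
    out = {}
    for name in spec.free_parameter_names:
        if name == "tau":
            out[name] = DEFAULT_BOUNDS["tau"]
        elif name == "n":
            out[name] = DEFAULT_BOUNDS["n"]
        else:
            out[name] = DEFAULT_BOUNDS["log"]
    return out


def _is_log_scaled(name: str) -> bool:
    return name not in ("tau", "n")


def _to_natural(names, theta):
    return np.array([10.0 ** x if _is_log_scaled(nm) else x
                     for nm, x in zip(names, theta)])


def _transformed_bounds(names, bounds):
    tb = []
    for nm in names:
        lo, hi = bounds[nm]
        if _is_log_scaled(nm):
            tb.append((np.log10(lo), np.log10(hi)))
        else:
            tb.append((lo, hi))
    return tb


def fit_model(
    spec: ModelSpec,
    dataset: ExpressionDataset,
    scope: Sequence[ConditionKey],
    bounds: Mapping | None = None,
    seed: int = 0,
    de_settings: DESettings | None = None,
    fixed_params: Mapping | None = None,
    range_scope: str = "per_series",
) -> FitResult:
    """Estimate the variant's free parameters by differential evolution.

    ``fixed_params`` pins named parameters (removing them from the
    search); remaining parameters take their ParameterSet defaults.
    Deterministic for a given seed.  Non-convergence is flagged on the
    result, not raised.
    """
    settings = de_settings or DESettings()
    fixed = dict(fixed_params or {})
    names = [nm for nm in spec.free_parameter_names if nm not in fixed]
    if not names:
        raise ValueError("no free parameters left to fit")
    all_bounds = default_bounds(spec)
    if bounds:
        all_bounds.update(bounds)
    missing = [nm for nm in names if nm not in all_bounds]
    if missing:
        raise ValueError(f"bounds missing for parameters {missing}")

    ctx = CostContext(spec, dataset, scope, range_scope=range_scope,
                      fast_step=settings.fast_step)
    n_evals = 0

    def objective(theta):
        nonlocal n_evals
        n_evals += 1
        params = ParameterSet.from_vector(names, _to_natural(names, theta), **fixed)
        return ctx.cost(params)

    result = differential_evolution(
        objective,
        _transformed_bounds(names, all_bounds),
        seed=seed,
        popsize=settings.popsize,
        maxiter=settings.maxiter,
        strategy=settings.strategy,
        mutation=settings.mutation,
        recombination=settings.recombination,
        tol=settings.tol,
        init=settings.init,
        polish=settings.polish,
    )
    params = ParameterSet.from_vector(names, _to_natural(names, result.x), **fixed)
    sols = ctx.solutions(params)
    by_scope = {"full": nrmse(sols, dataset, scope, range_scope=range_scope)}
    for condition in scope:
        try:
            by_scope[(condition.genotype, condition.photoperiod)] = nrmse(
                sols, dataset, [condition], range_scope=range_scope)
        except ValueError:
            pass
    return FitResult(
        params=params,
        wrss=float(result.fun),
        nrmse_by_scope=by_scope,
        seed=seed,
        n_cost_evals=n_evals,
        converged=bool(result.success),
        message=str(result.message),
    )


def run_ensemble(
    spec: ModelSpec,
    dataset: ExpressionDataset,
    scope: Sequence[ConditionKey],
    n_runs: int = 20,
    base_seed: int = 0,
    **fit_kwargs,
) -> EnsembleResult:
    """Independent fits with seeds base_seed .. base_seed + n_runs - 1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    fits = [fit_model(spec, dataset, scope, seed=base_seed + i, **fit_kwargs)
            for i in range(n_runs)]
    return EnsembleResult(fits=fits)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(nrmse_a: Sequence[float], nrmse_b: Sequence[float],
                   alternative: str = "less") -> float:
    """Mann-Whitney-Wilcoxon rank-sum p-value comparing NRMSE ensembles.

    ``alternative='less'`` tests that distribution a is stochastically
    smaller than b (model a fits better).  Identical pooled samples
    return p = 1 by convention.
    """
    a = np.asarray(nrmse_a, dtype=float)
    b = np.asarray(nrmse_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(mannwhitneyu(a, b, alternative=alternative).pvalue)
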