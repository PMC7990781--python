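"""ODE models of the pea floral-transition network.

Six apical genes (*DET*, *PIM*, *VEG1*, *LF*, *FTc* and apically expressed
*FTa1*) are modeled with Michaelis-Menten synthesis terms driven by the
complexes of VEG2 (the pea FD homologue) with the FT proteins, plus
first-order degradation shared across all proteins::

    du_i/dt = v_i * F_i(regulators) - lambda * u_i

Every regulator on the right-hand side is replaced by data interpolated in
time, so the six equations decouple and each gene is a scalar *linear*
ODE with a time-varying synthesis rate.  That linearity is exploited twice:
an integrating-factor closed form serves as a verification oracle, and an
exact exponential-integrator step doubles as a fast fitting backend.

Model variants
--------------
``MM``            baseline; competitive VEG2-FT binding (shared-pool occupancy)
``MM_LF``         MM plus repression of *PIM* by LF (extra constant K16)
``MC``            noncompetitive binding: complexes are plain products
``MC_PIM``        MC with the Hill exponent n of the PIM activation free
``MC_Cdata_FTa1`` MC plus *FTa1* self-activation in the apex (extra K17)

``MC_Cdata``, ``MC_SDdata`` and ``MC_LDdata`` are the MC equations fitted
to different data scopes; they are scope configurations, not separate
equation sets.

Leaf-expressed FT proteins reach the apex with a transport delay ``tau``:
the total apical FTa1 is the apically expressed fraction plus the leaf
concentration read at ``t - tau``, and apical FTb2 is purely the delayed
leaf concentration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .data_model import (
    ConditionKey,
    ExpressionDataset,
    Trajectory,
    interpolate_trajectory,
)

# shared degradation constant: ln(2) / (3.49-day protein half-life), rounded
DEFAULT_LAMBDA = 0.199

MODELED_GENES = ("DET", "PIM", "VEG1", "LF", "FTc", "FTa1_apex")

#: modeled-gene name -> (data gene, tissue) carrying its observations
MODELED_TO_DATA = {
    "DET": ("DET", "apex"),
    "PIM": ("PIM", "apex"),
    "VEG1": ("VEG1", "apex"),
    "LF": ("LF", "apex"),
    "FTc": ("FTc", "apex"),
    "FTa1_apex": ("FTa1", "apex"),
}

#: equation index of each modeled gene (selects v_i)
GENE_INDEX = {g: i + 1 for i, g in enumerate(MODELED_GENES)}


class ConfigurationError(ValueError):
    """A model was asked to evaluate with a missing regulator or bad variant."""


# ---------------------------------------------------------------------------
# Parameters and model variants
# ---------------------------------------------------------------------------

_V_NAMES = tuple(f"v{i}" for i in range(1, 7))
_K_NAMES = tuple(f"K{i}" for i in range(1, 18))


@dataclass
class ParameterSet:
    """One point in parameter space for an ODE model variant.

    v1..v6 are maximal synthesis rates (expression units / day); K1..K12,
    K16, K17 are Michaelis-Menten constants in expression units; K13..K15
    are competitive-binding association constants (1 / expression units);
    ``n`` is the Hill exponent of the PIM activation term; ``tau`` the
    leaf-to-apex transport delay in days; ``lam`` the shared degradation
    constant in 1/day.
    """

    v1: float = 1.0
    v2: float = 1.0
    v3: float = 1.0
    v4: float = 1.0
    v5: float = 1.0
    v6: float = 1.0
    K1: float = 1.0
    K2: float = 1.0
    K3: float = 1.0
    K4: float = 1.0
    K5: float = 1.0
    K6: float = 1.0
    K7: float = 1.0
    K8: float = 1.0
    K9: float = 1.0
    K10: float = 1.0
    K11: float = 1.0
    K12: float = 1.0
    K13: float = 1.0
    K14: float = 1.0
    K15: float = 1.0
    K16: float = 1.0
    K17: float = 1.0
    n: float = 1.0
    tau: float = 0.0
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        for name in _V_NAMES + _K_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")
        if self.tau < 0:
            raise ValueError("transport delay tau must be >= 0")
        if self.lam <= 0:
            raise ValueError("degradation constant lam must be > 0")

    def get(self, name: str) -> float:
        return getattr(self, name)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_vector(self, names: Iterable[str]) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in names], dtype=float)

    @classmethod
    def from_vector(cls, names: Iterable[str], vector, **fixed) -> "ParameterSet":
        kw = dict(fixed)
        kw.update({nm: float(x) for nm, x in zip(names, vector)})
        return cls(**kw)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant."""

    variant: str
    binding_mode: str  # "competitive" | "noncompetitive"
    free_parameter_names: tuple
    modeled_genes: tuple = MODELED_GENES

    @property
    def ndim(self) -> int:
        return len(self.free_parameter_names)


_BASE_MM = _V_NAMES + tuple(f"K{i}" for i in range(1, 16)) + ("tau",)
_BASE_MC = _V_NAMES + tuple(f"K{i}" for i in range(1, 13)) + ("tau",)

_VARIANTS = {
    "MM": ("competitive", _BASE_MM),
    "MM_LF": ("competitive", _BASE_MM + ("K16",)),
    "MC": ("noncompetitive", _BASE_MC),
    "MC_PIM": ("noncompetitive", _BASE_MC + ("n",)),
    "MC_Cdata_FTa1": ("noncompetitive", _BASE_MC + ("K17",)),
    # scope aliases: same equations as MC, fitted to different data subsets
    "MC_Cdata": ("noncompetitive", _BASE_MC),
    "MC_SDdata": ("noncompetitive", _BASE_MC),
    "MC_LDdata": ("noncompetitive", _BASE_MC),
}


def model_spec(variant: str) -> ModelSpec:
    """Build the ModelSpec for a named variant."""
    try:
        mode, free = _VARIANTS[variant]
    except KeyError:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; one of {sorted(_VARIANTS)}"
        ) from None
    return ModelSpec(variant=variant, binding_mode=mode, free_parameter_names=free)


@dataclass(frozen=True)
class GenotypeSpec:
    """Structural consequences of a genotype for simulation and fitting.

    ``forced_zero_genes`` are data genes whose concentration reads zero in
    the mutant (null alleles); ``cost_excluded_genes`` are modeled genes
    left out of the fitting cost for this genotype.
    """

    name: str
    forced_zero_genes: frozenset = frozenset()
    cost_excluded_genes: frozenset = frozenset()


_GENOTYPES = {
    "WT": GenotypeSpec("WT"),
    "dne-1": GenotypeSpec("dne-1"),
    "late1-2": GenotypeSpec("late1-2"),
    # gigas-2 is the FTa1 null: FTa1 reads zero in leaf and apex, and PIM
    # (whose expression collapses in this background) is excluded from cost
    "gigas-2": GenotypeSpec(
        "gigas-2",
        forced_zero_genes=frozenset({"FTa1"}),
        cost_excluded_genes=frozenset({"PIM"}),
    ),
}


def genotype_spec(name: str) -> GenotypeSpec:
    try:
        return _GENOTYPES[name]
    except KeyError:
        raise ConfigurationError(f"unknown genotype {name!r}") from None


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant (1/day) from a half-life in days: ln2/t_half."""
    if t_half <= 0:
        raise ValueError("half-life must be strictly positive")
    return float(np.log(2.0) / t_half)


def competitive_complexes(uFTa1, uFTb2, uFTc, uVEG2, K13, K14, K15):
    """Equilibrium complexes of VEG2 with the FT proteins, shared-pool binding.

    All three FT ligands compete for one VEG2 pool; each complex is the
    fractional occupancy K_j*u_j / (1 + sum K*u) times uVEG2, so the
    complexes always sum to strictly less than the available VEG2.
    """
    uFTa1, uFTb2, uFTc, uVEG2 = (np.asarray(x, dtype=float) for x in (uFTa1, uFTb2, uFTc, uVEG2))
    if np.any(uFTa1 < 0) or np.any(uFTb2 < 0) or np.any(uFTc < 0) or np.any(uVEG2 < 0):
        raise ValueError("concentrations must be nonnegative")
    if K13 <= 0 or K14 <= 0 or K15 <= 0:
        raise ValueError("association constants must be strictly positive")
    denom = 1.0 + K13 * uFTa1 + K14 * uFTb2 + K15 * uFTc
    return (
        K13 * uFTa1 * uVEG2 / denom,
        K14 * uFTb2 * uVEG2 / denom,
        K15 * uFTc * uVEG2 / denom,
    )


def noncompetitive_complexes(uFTa1, uFTb2, uFTc, uVEG2):
    """Complexes under unconstrained binding: elementwise products u_FT * u_VEG2.

    Proportionality constants are absorbed into the free K's of the gene
    equations, so no extra parameters appear here.
    """
    uFTa1, uFTb2, uFTc, uVEG2 = (np.asarray(x, dtype=float) for x in (uFTa1, uFTb2, uFTc, uVEG2))
    if np.any(uFTa1 < 0) or np.any(uFTb2 < 0) or np.any(uFTc < 0) or np.any(uVEG2 < 0):
        raise ValueError("concentrations must be nonnegative")
    return uFTa1 * uVEG2, uFTb2 * uVEG2, uFTc * uVEG2


def apical_totals(t, apex_FTa1, leaf_FTa1: Trajectory, leaf_FTb2: Trajectory, tau: float):
    """Total apical FTa1 and FTb2 at time(s) t with transport delay tau.

    uFTa1(t) = u_FTa1_apex(t) + u_FTa1_leaf(t - tau);
    uFTb2(t) = u_FTb2_leaf(t - tau).  Leaf series are read with boundary
    clamping, so t - tau before the first observation returns the first
    value.  ``apex_FTa1`` may be a Trajectory, a callable of t, or a number.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    t = np.asarray(t, dtype=float)
    if isinstance(apex_FTa1, Trajectory):
        apex = interpolate_trajectory(apex_FTa1, t)
    elif callable(apex_FTa1):
        apex = np.asarray(apex_FTa1(t), dtype=float)
    else:
        apex = np.broadcast_to(np.asarray(apex_FTa1, dtype=float), t.shape).copy() if t.shape else float(apex_FTa1)
    uFTa1 = apex + interpolate_trajectory(leaf_FTa1, t - tau)
    uFTb2 = interpolate_trajectory(leaf_FTb2, t - tau)
    return uFTa1, uFTb2


def _act(x, K):
    return x / (K + x)


def _rep(x, K):
    return K / (K + x)


def _hill_act(x, K, n):
    xn = np.power(x, n)
    return xn / (K ** n + xn)


#: regulators each gene's synthesis term references (always / variant-extra)
_REQUIRED_REGULATORS = {
    "DET": ("VEG2FTb2", "VEG1"),
    "PIM": ("VEG2FTa1", "DET"),
    "VEG1": ("VEG2FTa1", "DET", "PIM", "LF"),
    "LF": ("VEG2FTb2",),
    "FTc": ("VEG2FTa1", "VEG2FTb2"),
    "FTa1_apex": ("VEG2FTb2",),
}


def synthesis_rate(spec: ModelSpec, gene: str, params: ParameterSet,
                   regulators: Mapping[str, float]):
    """The synthesis part v_i * F_i of the gene's equation (no degradation)."""
    if gene not in spec.modeled_genes:
        raise ConfigurationError(f"{gene} is not a modeled gene")
    req = list(_REQUIRED_REGULATORS[gene])
    if spec.variant == "MM_LF" and gene == "PIM":
        req.append("LF")
    if spec.variant == "MC_Cdata_FTa1" and gene == "FTa1_apex":
        req.append("VEG2FTa1")
    for r in req:
        if r not in regulators:
            raise ConfigurationError(f"gene {gene}: missing regulator {r!r}")
    g = regulators.get
    p = params
    if gene == "DET":
        return p.v1 * _act(g("VEG2FTb2"), p.K1) * _rep(g("VEG1"), p.K2)
    if gene == "PIM":
        term = p.v2 * _hill_act(g("VEG2FTa1"), p.K3, p.n) * _rep(g("DET"), p.K4)
        if spec.variant == "MM_LF":
            term = term * _rep(g("LF"), p.K16)
        return term
    if gene == "VEG1":
        return (p.v3 * _act(g("VEG2FTa1"), p.K5) * _rep(g("DET"), p.K6)
                * _rep(g("PIM"), p.K7) * _rep(g("LF"), p.K8))
    if gene == "LF":
        return p.v4 * _rep(g("VEG2FTb2"), p.K9)
    if gene == "FTc":
        return p.v5 * (_act(g("VEG2FTa1"), p.K10) + _act(g("VEG2FTb2"), p.K11))
    if gene == "FTa1_apex":
        term = p.v6 * _act(g("VEG2FTb2"), p.K12)
        if spec.variant == "MC_Cdata_FTa1":
            term = term + p.v6 * _act(g("VEG2FTa1"), p.K17)
        return term
    raise ConfigurationError(f"unknown gene {gene!r}")


def rhs_gene(spec: ModelSpec, gene: str, t, u, params: ParameterSet,
             regulators: Mapping[str, float]):
    """du/dt of one gene: synthesis from its regulators minus lambda*u."""
    return synthesis_rate(spec, gene, params, regulators) - params.lam * u


# ---------------------------------------------------------------------------
# Data-driven regulator accessor
# ---------------------------------------------------------------------------

def apply_genotype(dataset: ExpressionDataset, gspec: GenotypeSpec) -> ExpressionDataset:
    """Dataset with the genotype's null genes clamped to zero (idempotent)."""
    if not gspec.forced_zero_genes:
        return dataset
    frame = dataset.frame.copy()
    mask = frame["gene"].isin(gspec.forced_zero_genes)
    frame.loc[mask, ["mean", "sd"]] = 0.0
    return ExpressionDataset(frame)


class DataRegulators:
    """Interpolated regulator concentrations for one condition.

    Reads the apex series of VEG2, FTa1, FTc, DET, PIM, LF, VEG1 and the
    leaf series of FTa1 and FTb2 from the (genotype-clamped) data, and
    evaluates the VEG2-FT complexes for a given binding mode and delay.
    VEG1 has no SD observations; its regulator value is taken as zero
    there (no repression of DET), the only consistent data-driven choice.
    """

    def __init__(self, dataset: ExpressionDataset, condition: ConditionKey,
                 gspec: GenotypeSpec | None = None):
        if gspec is None:
            gspec = genotype_spec(condition.genotype)
        self.condition = condition
        self.genotype_spec = gspec
        data = apply_genotype(dataset, gspec)
        self._traj: dict[tuple, Trajectory] = {}
        for gene, tissue in [("VEG2", "apex"), ("FTa1", "apex"), ("FTc", "apex"),
                             ("DET", "apex"), ("PIM", "apex"), ("LF", "apex"),
                             ("VEG1", "apex"), ("FTa1", "leaf"), ("FTb2", "leaf")]:
            if data.has_series(gene, tissue, condition):
                self._traj[(gene, tissue)] = data.series(gene, tissue, condition)
            else:
                self._traj[(gene, tissue)] = None

    def _read(self, gene, tissue, t):
        traj = self._traj[(gene, tissue)]
        if traj is None:
            return np.zeros_like(np.asarray(t, dtype=float))
        return interpolate_trajectory(traj, t)

    def complexes(self, t, params: ParameterSet, binding_mode: str):
        apex_fta1 = self._traj[("FTa1", "apex")]
        leaf_fta1 = self._traj[("FTa1", "leaf")]
        leaf_ftb2 = self._traj[("FTb2", "leaf")]
        t = np.asarray(t, dtype=float)
        if leaf_fta1 is None:
            leaf_fta1 = Trajectory("FTa1", "leaf", [0.0], [0.0])
        if leaf_ftb2 is None:
            leaf_ftb2 = Trajectory("FTb2", "leaf", [0.0], [0.0])
        if apex_fta1 is None:
            apex_fta1 = Trajectory("FTa1", "apex", [0.0], [0.0])
        uFTa1, uFTb2 = apical_totals(t, apex_fta1, leaf_fta1, leaf_ftb2, params.tau)
        uFTc = self._read("FTc", "apex", t)
        uVEG2 = self._read("VEG2", "apex", t)
        if binding_mode == "competitive":
            return competitive_complexes(uFTa1, uFTb2, uFTc, uVEG2,
                                         params.K13, params.K14, params.K15)
        if binding_mode == "noncompetitive":
            return noncompetitive_complexes(uFTa1, uFTb2, uFTc, uVEG2)
        raise ConfigurationError(f"unknown binding mode {binding_mode!r}")

    def at(self, t, params: ParameterSet, binding_mode: str) -> dict:
        """Full regulator dictionary (complexes + apical proteins) at time(s) t."""
        ca1, cb2, cc = self.complexes(t, params, binding_mode)
        return {
            "VEG2FTa1": ca1,
            "VEG2FTb2": cb2,
            "VEG2FTc": cc,
            "DET": self._read("DET", "apex", t),
            "PIM": self._read("PIM", "apex", t),
            "LF": self._read("LF", "apex", t),
            "VEG1": self._read("VEG1", "apex", t),
        }

    def initial_value(self, gene: str) -> float:
        """Gene's data mean at the first observed day of the condition, else 0."""
        data_gene, tissue = MODELED_TO_DATA[gene]
        traj = self._traj[(data_gene, tissue)]
        if traj is None or traj.times.size == 0:
            return 0.0
        return float(traj.values[0])

    def first_day(self) -> float:
        days = [tr.times[0] for tr in self._traj.values() if tr is not None and tr.times.size]
        if not days:
            raise ConfigurationError("condition has no data series at all")
        return float(min(days))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _exp_step(u0, s0, s1, h, lam):
    """Exact step of du/dt = s(t) - lam*u with s linear from s0 to s1 over h."""
    e = np.exp(-lam * h)
    m = (s1 - s0) / h
    return u0 * e + s0 * (1.0 - e) / lam + m * (h / lam - (1.0 - e) / lam ** 2)


def _integrate_linear_profile(times, values, lam, u0, t_grid):
    """Exact solution on t_grid for a piecewise-linear synthesis profile
    with nodes exactly at `times` (t_grid must be a subset of times)."""
    u = np.empty_like(times)
    u[0] = u0
    for k in range(len(times) - 1):
        u[k + 1] = _exp_step(u[k], values[k], values[k + 1], times[k + 1] - times[k], lam)
    idx = np.searchsorted(times, t_grid)
    return u[idx]


def simulate_gene(
    spec: ModelSpec,
    gene: str,
    params: ParameterSet,
    dataset: ExpressionDataset,
    condition: ConditionKey,
    t_grid,
    method: str = "ivp",
    regulators: DataRegulators | None = None,
    fast_step: float = 0.5,
) -> Trajectory:
    """Integrate one gene's equation with data-interpolated regulators.

    The initial condition is the gene's data mean at the first day of the
    condition (zero when the gene has no data there).  ``method='ivp'``
    uses an adaptive stiff-capable solver (LSODA, rtol 1e-8 / atol 1e-10);
    ``method='fast'`` evaluates the synthesis rate on a refined fixed grid
    (step ``fast_step`` days) and applies the exact exponential-integrator
    recursion, which is what the fitting inner loop uses.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if regulators is None:
        regulators = DataRegulators(dataset, condition)
    gspec = regulators.genotype_spec
    data_gene, _ = MODELED_TO_DATA[gene]
    if data_gene in gspec.forced_zero_genes:
        # null allele: no synthesis, and the data series is clamped at zero
        return Trajectory(gene, "apex", t_grid, np.zeros_like(t_grid))

    u0 = regulators.initial_value(gene)
    t0 = min(regulators.first_day(), float(t_grid[0]))

    def s_of_t(t):
        return synthesis_rate(spec, gene, params, regulators.at(t, params, spec.binding_mode))

    if method == "ivp":
        sol = solve_ivp(
            lambda t, u: s_of_t(t) - params.lam * u,
            (t0, float(t_grid[-1])),
            [u0],
            method="LSODA",
            t_eval=t_grid,
            rtol=1e-8,
            atol=1e-10,
            max_step=1.0,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed for gene {gene} in condition "
                f"{condition.genotype}-{condition.photoperiod}: {sol.message}"
            )
        return Trajectory(gene, "apex", t_grid, sol.y[0])

    if method == "fast":
        fine = np.union1d(np.arange(t0, float(t_grid[-1]) + fast_step, fast_step), t_grid)
        s = np.asarray(s_of_t(fine), dtype=float)
        vals = _integrate_linear_profile(fine, s, params.lam, u0, t_grid)
        return Trajectory(gene, "apex", t_grid, vals)

    raise ConfigurationError(f"unknown simulation method {method!r}")


def closed_form_solution(synthesis_profile, lam: float, u0: float, t_grid) -> Trajectory:
    """Exact integrating-factor solution of du/dt = s(t) - lam*u.

    ``synthesis_profile`` is piecewise linear, given as a ``(times,
    values)`` pair or a :class:`Trajectory`, held constant outside its
    node range.  The convolution integral is evaluated analytically on
    each linear segment, so the result is exact to rounding.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if isinstance(synthesis_profile, Trajectory):
        pt, pv = synthesis_profile.times, synthesis_profile.values
    else:
        pt, pv = (np.asarray(a, dtype=float) for a in synthesis_profile)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    t0 = float(t_grid[0])
    nodes = np.union1d(pt[(pt >= t0) & (pt <= t_grid[-1])], t_grid)
    vals = np.interp(nodes, pt, pv)
    out = _integrate_linear_profile(nodes, vals, lam, u0, t_grid)
    return Trajectory("closed_form", "apex", t_grid, out)
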