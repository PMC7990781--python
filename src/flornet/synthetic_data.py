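"""Synthetic expression data with the structure the analysis assumes.

Three generators cover the pipeline's needs without any external data:

* :func:`generate_mechanistic` inverts the fitting problem — it simulates
  the ODE model with known parameters on the study design and emits the
  result as an expression table, so parameter/trajectory recovery can be
  tested against ground truth.  Because fitting drives the equations with
  *data-interpolated* regulators, the generator iterates the
  simulate-then-replace map to a fixed point: at convergence the table is
  exactly reproduced by the model that generated it.
* :func:`generate_phenomenological` emits smooth logistic/decay curves
  emulating the qualitative shapes of the measured series (sigmoid rises
  for the FT- and meristem-identity genes, early-high decaying LF under
  LD, delayed and damped dynamics under SD), plus mutants derived from
  the wild type by shift/attenuation rules.
* :func:`generate_network_benchmark` plants a signed one-step interaction
  network on the seven NN panel genes and simulates noisy trajectories
  from it, providing ground truth for knockout sign recovery.

Study design defaults: weekly sampling; WT-LD days 7-35, WT-SD days 7-56,
dne-1 (SD) 7-35, late1-2 (LD) 14-56, gigas-2 (LD) 7-56; VEG1 absent under
SD; reported sd = 10% of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ConditionKey,
    ExpressionDataset,
    interpolate_trajectory,
)
from .nn_models import INPUT_GENES, OUTPUT_GENES, ExpandedDataset, _NN_TISSUE
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


def _weekly(a: float, b: float) -> np.ndarray:
    return np.arange(a, b + 1e-9, 7.0)


DEFAULT_DESIGN = {
    ("WT", "LD"): _weekly(7, 35),
    ("WT", "SD"): _weekly(7, 56),
    ("dne-1", "SD"): _weekly(7, 35),
    ("late1-2", "LD"): _weekly(14, 56),
    ("gigas-2", "LD"): _weekly(7, 56),
}


@dataclass
class GeneratorConfig:
    """Design grids, reporting noise level and seed for the generators."""

    design: dict = field(default_factory=lambda: {k: v.copy() for k, v in DEFAULT_DESIGN.items()})
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        bad = set(self.design) - set(DEFAULT_DESIGN)
        if bad:
            raise ValueError(f"design contains invalid conditions: {sorted(bad)}")


def _rows(gene, tissue, genotype, photoperiod, times, means, cv):
    means = np.clip(np.asarray(means, dtype=float), 0.0, None)
    return pd.DataFrame({
        "gene": gene, "tissue": tissue, "genotype": genotype,
        "photoperiod": photoperiod, "time": np.asarray(times, dtype=float),
        "mean": means, "sd": cv * means,
    })


# ---------------------------------------------------------------------------
# Phenomenological curves
# ---------------------------------------------------------------------------

def _logistic(t, amp, t50, k, base=0.0):
    return base + amp / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t50)))


def _decay(t, amp, rate, base):
    return base + amp * np.exp(-rate * (np.asarray(t, dtype=float) - 7.0))


def _wt_curves(photoperiod: str) -> dict:
    """(gene, tissue) -> callable mean curve for the wild type."""
    if photoperiod == "LD":
        return {
            ("FTa1", "leaf"): lambda t: _logistic(t, 4.0, 18, 0.30),
            ("FTb2", "leaf"): lambda t: _logistic(t, 6.0, 16, 0.35),
            ("FTa1", "apex"): lambda t: _logistic(t, 2.0, 24, 0.30),
            ("FTc", "apex"): lambda t: _logistic(t, 3.0, 26, 0.30),
            ("VEG2", "apex"): lambda t: _logistic(t, 1.0, 20, 0.25, base=1.5),
            ("DET", "apex"): lambda t: _logistic(t, 2.5, 20, 0.25, base=0.3),
            ("LF", "apex"): lambda t: _decay(t, 3.0, 0.08, 0.4),
            ("VEG1", "apex"): lambda t: _logistic(t, 2.0, 28, 0.30),
            ("PIM", "apex"): lambda t: _logistic(t, 5.0, 28, 0.35),
        }
    # SD: delayed midpoints, damped amplitudes, suppressed leaf FT signals,
    # LF stays high much longer; no VEG1 observations
    return {
        ("FTa1", "leaf"): lambda t: _logistic(t, 1.0, 32, 0.30),
        ("FTb2", "leaf"): lambda t: _logistic(t, 0.9, 30, 0.35),
        ("FTa1", "apex"): lambda t: _logistic(t, 1.2, 38, 0.30),
        ("FTc", "apex"): lambda t: _logistic(t, 1.8, 40, 0.30),
        ("VEG2", "apex"): lambda t: _logistic(t, 0.6, 34, 0.25, base=1.5),
        ("DET", "apex"): lambda t: _logistic(t, 1.5, 34, 0.25, base=0.3),
        ("LF", "apex"): lambda t: _decay(t, 3.0, 0.02, 0.5),
        ("PIM", "apex"): lambda t: _logistic(t, 3.0, 42, 0.35),
    }


@dataclass
class MutantRules:
    """Shift/attenuation recipe deriving a mutant from wild-type curves."""

    source_photoperiod: str
    gene_scale: dict = field(default_factory=dict)
    gene_shift: dict = field(default_factory=dict)  # days, + = delayed


#: default emulation: dne-1 under SD behaves like WT under LD (early
#: flowering); late1-2 is delayed/damped in LD; gigas-2 is the FTa1 null
#: with collapsed PIM
DEFAULT_MUTANT_RULES = {
    "dne-1": MutantRules(source_photoperiod="LD"),
    "late1-2": MutantRules(source_photoperiod="LD",
                           gene_scale={g: 0.6 for g in ("FTa1", "FTb2", "FTc", "PIM", "VEG1")},
                           gene_shift={g: 14.0 for g in ("FTa1", "FTb2", "FTc", "PIM", "VEG1", "DET")}),
    "gigas-2": MutantRules(source_photoperiod="LD", gene_scale={"PIM": 0.02}),
}


def derive_mutant(wild_dataset: ExpressionDataset, gspec, config: GeneratorConfig,
                  rules: MutantRules | None = None) -> ExpressionDataset:
    """Mutant expression table from wild-type series via shift/scale rules.

    The mutant's series are the wild-type series of the rule's source
    photoperiod, read at shifted times, scaled, and resampled on the
    mutant's design grid; the genotype's null genes are then forced to
    zero.  gspec may be a GenotypeSpec or a genotype name.
    """
    if isinstance(gspec, str):
        gspec = genotype_spec(gspec)
    if gspec.name == "WT":
        return wild_dataset
    if rules is None:
        rules = DEFAULT_MUTANT_RULES[gspec.name]
    (photoperiod,) = {p for g, p in config.design if g == gspec.name}
    grid = config.design[(gspec.name, photoperiod)]
    src = ConditionKey("WT", rules.source_photoperiod)
    frames = []
    wt = wild_dataset.frame
    series_keys = wt[(wt["genotype"] == "WT") & (wt["photoperiod"] == rules.source_photoperiod)][
        ["gene", "tissue"]].drop_duplicates()
    for gene, tissue in series_keys.itertuples(index=False):
        if gene == "VEG1" and photoperiod == "SD":
            continue
        scale = rules.gene_scale.get(gene, 1.0)
        shift = rules.gene_shift.get(gene, 0.0)
        if gene in gspec.forced_zero_genes:
            means = np.zeros_like(grid)
        else:
            tr = wild_dataset.series(gene, tissue, src)
            means = scale * interpolate_trajectory(tr, grid - shift)
        frames.append(_rows(gene, tissue, gspec.name, photoperiod, grid, means,
                            config.noise_cv))
    return ExpressionDataset(pd.concat(frames, ignore_index=True))


def generate_phenomenological(config: GeneratorConfig | None = None) -> ExpressionDataset:
    """Full study-design dataset from smooth phenomenological curves."""
    config = config or GeneratorConfig()
    frames = []
    for photoperiod in ("LD", "SD"):
        key = ("WT", photoperiod)
        if key not in config.design:
            continue
        grid = config.design[key]
        for (gene, tissue), curve in _wt_curves(photoperiod).items():
            frames.append(_rows(gene, tissue, "WT", photoperiod, grid,
                                curve(grid), config.noise_cv))
    wild = ExpressionDataset(pd.concat(frames, ignore_index=True))
    parts = [wild.frame]
    for genotype in ("dne-1", "late1-2", "gigas-2"):
        if any(g == genotype for g, _p in config.design):
            parts.append(derive_mutant(wild, genotype, config).frame)
    return ExpressionDataset(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# Mechanistic generator
# ---------------------------------------------------------------------------

#: ground-truth parameters for recovery experiments: rates and constants
#: on the O(1)-O(10) scale of the relative-expression data, 3.5-day
#: transport delay, half-life-derived degradation
TRUE_PARAMS_MC = ParameterSet(
    v1=0.8, v2=1.2, v3=0.9, v4=0.7, v5=1.0, v6=0.6,
    K1=2.0, K2=1.0, K3=3.0, K4=1.2, K5=2.5, K6=1.5,
    K7=2.0, K8=1.0, K9=2.5, K10=3.0, K11=4.0, K12=3.0,
    tau=3.5, n=1.0,
)

#: initial (first-day) concentrations of the modeled genes
DEFAULT_INITIAL_VALUES = {
    "DET": 0.3, "PIM": 0.05, "VEG1": 0.05, "LF": 3.0, "FTc": 0.05,
    "FTa1_apex": 0.05,
}


def default_leaf_inputs(photoperiod: str) -> dict:
    """Prescribed input curves: leaf FTa1/FTb2 and apical VEG2."""
    curves = _wt_curves(photoperiod)
    return {
        ("FTa1", "leaf"): curves[("FTa1", "leaf")],
        ("FTb2", "leaf"): curves[("FTb2", "leaf")],
        ("VEG2", "apex"): curves[("VEG2", "apex")],
    }


def generate_mechanistic(
    spec: ModelSpec,
    true_params: ParameterSet = TRUE_PARAMS_MC,
    leaf_inputs: Mapping | None = None,
    config: GeneratorConfig | None = None,
    conditions: Sequence[ConditionKey] | None = None,
    initial_values: Mapping | None = None,
    jitter: bool = False,
    fast_step: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-13,
) -> ExpressionDataset:
    """Model-generated dataset, exactly self-consistent with data-driven fitting.

    For each condition the six apical genes are simulated with regulators
    interpolated from the current candidate table and the table is
    replaced by the simulated grid values, iterating to a fixed point.
    At convergence, re-simulating from the emitted table reproduces it
    exactly, so the fitting cost at ``true_params`` is zero (before any
    jitter).  ``jitter`` adds one Normal(0, noise_cv*mean) realization to
    the means.  VEG1 is omitted from SD outputs; genotypes' null genes
    are zeroed.
    """
    config = config or GeneratorConfig()
    if conditions is None:
        conditions = [ConditionKey("WT", "LD"), ConditionKey("WT", "SD")]
    init = dict(DEFAULT_INITIAL_VALUES)
    if initial_values:
        init.update(initial_values)
    rng = np.random.default_rng(config.seed)

    parts = []
    for condition in conditions:
        grid = config.design[tuple(condition)]
        gspec = genotype_spec(condition.genotype)
        inputs = dict(leaf_inputs) if leaf_inputs is not None else default_leaf_inputs(condition.photoperiod)

        frames = [
            _rows(gene, tissue, condition.genotype, condition.photoperiod,
                  grid, np.zeros_like(grid) if gene in gspec.forced_zero_genes
                  else curve(grid), config.noise_cv)
            for (gene, tissue), curve in inputs.items()
        ]
        sim_genes = [g for g in MODELED_GENES
                     if not (g == "VEG1" and condition.photoperiod == "SD")]
        for gene in sim_genes:
            data_gene, tissue = MODELED_TO_DATA[gene]
            start = 0.0 if data_gene in gspec.forced_zero_genes else init[gene]
            means = np.full_like(grid, start)
            frames.append(_rows(data_gene, tissue, condition.genotype,
                                condition.photoperiod, grid, means, config.noise_cv))
        table = pd.concat(frames, ignore_index=True)

        fine = np.union1d(np.arange(grid[0], grid[-1] + fast_step, fast_step), grid)
        for _ in range(max_iter):
            dataset = ExpressionDataset(table.copy())
            regs = DataRegulators(dataset, condition)
            regdict = regs.at(fine, true_params, spec.binding_mode)
            new = table.copy()
            delta = 0.0
            for gene in sim_genes:
                data_gene, tissue = MODELED_TO_DATA[gene]
                if data_gene in gspec.forced_zero_genes:
                    continue
                s = np.asarray(synthesis_rate(spec, gene, true_params, regdict),
                               dtype=float)
                u = _integrate_linear_profile(fine, s, true_params.lam,
                                              regs.initial_value(gene), grid)
                mask = ((new["gene"] == data_gene) & (new["tissue"] == tissue))
                old = new.loc[mask, "mean"].to_numpy()
                delta = max(delta, float(np.max(np.abs(u - old))))
                new.loc[mask, "mean"] = np.clip(u, 0.0, None)
                new.loc[mask, "sd"] = config.noise_cv * np.clip(u, 0.0, None)
            table = new
            if delta < tol:
                break
        if jitter and config.noise_cv > 0:
            noisy = table["mean"] + rng.normal(0.0, config.noise_cv * table["mean"])
            table["mean"] = np.clip(noisy, 0.0, None)
        parts.append(table)
    return ExpressionDataset(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# Planted-network benchmark
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """Signed one-step interaction network on the NN gene panel."""

    genes: tuple = INPUT_GENES
    edges: tuple = ()  # (regulator, target, sign, strength)
    baseline: float = 0.3
    cap: float = 10.0
    persistence: float = 0.5

    def __post_init__(self) -> None:
        for reg, tgt, sign, strength in self.edges:
            if sign not in (+1, -1):
                raise ValueError("edge signs must be +1 or -1")
            if strength <= 0:
                raise ValueError("edge strengths must be > 0")

    def weight_matrix(self) -> np.ndarray:
        """W[regulator_idx, target_idx], persistence on the diagonal."""
        W = np.zeros((len(INPUT_GENES), len(OUTPUT_GENES)))
        for g in OUTPUT_GENES:
            W[INPUT_GENES.index(g), OUTPUT_GENES.index(g)] = self.persistence
        for reg, tgt, sign, strength in self.edges:
            W[INPUT_GENES.index(reg), OUTPUT_GENES.index(tgt)] = sign * strength
        return W

    def truth_signs(self) -> np.ndarray:
        """Signed adjacency (+1/-1/0), planted edges only (no diagonal)."""
        S = np.zeros((len(INPUT_GENES), len(OUTPUT_GENES)), dtype=int)
        for reg, tgt, sign, _ in self.edges:
            S[INPUT_GENES.index(reg), OUTPUT_GENES.index(tgt)] = sign
        return S


def default_planted_network() -> PlantedNetwork:
    """Benchmark network: a florigen-like activation cascade with two repressors."""
    return PlantedNetwork(edges=(
        ("FTb2", "FTa1", +1, 0.8),
        ("FTa1", "PIM", +1, 0.9),
        ("PIM", "FTc", +1, 0.8),
        ("VEG2", "FTc", +1, 0.7),
        ("DET", "PIM", -1, 0.7),
        ("LF", "DET", -1, 0.6),
    ))


def _saturate(z: np.ndarray, cap: float) -> np.ndarray:
    z = np.clip(z, 0.0, None)
    return cap * z / (cap + z)


def generate_network_benchmark(
    network: PlantedNetwork | None = None,
    n_times: int = 8,
    n_samples: int = 200,
    n_series: int = 4,
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """(ExpandedDataset, truth) from planted one-step dynamics.

    Mean trajectories follow x_{k+1} = g(b + W^T x_k) with a saturating g
    and the planted signed weights; leaf FTb2 follows an autonomous
    logistic course differing across series.  Gaussian noise of absolute
    scale ``noise_sd`` is added per sample (planted effect sizes sit well
    above twice this noise).  Series are stored under distinct study
    conditions purely as containers.
    """
    network = network or default_planted_network()
    rng = np.random.default_rng(seed)
    W = network.weight_matrix()
    times = 7.0 * np.arange(1, n_times + 1)
    conditions = list(DEFAULT_DESIGN)[:n_series]
    k_grid = np.arange(n_times)

    # genes that are never targets of a planted edge are exogenous drivers:
    # they follow smooth per-series courses (rises or decays with randomized
    # timing/amplitude) so that their influence is identifiable from data
    target_set = {tgt for _r, tgt, _s, _w in network.edges}
    exogenous = [g for g in INPUT_GENES if g not in target_set]

    entries = {}
    for s, (genotype, photoperiod) in enumerate(conditions):
        x = np.empty((n_times, len(INPUT_GENES)))
        courses = {}
        for g in exogenous:
            if rng.uniform() < 0.5:
                amp, mid = rng.uniform(1.5, 3.5), rng.uniform(1.5, n_times - 2.5)
                courses[g] = 0.4 + amp / (1.0 + np.exp(-0.8 * (k_grid - mid)))
            else:
                amp, rate = rng.uniform(1.5, 3.5), rng.uniform(0.15, 0.45)
                courses[g] = 0.3 + amp * np.exp(-rate * k_grid)
        for g, course in courses.items():
            x[:, INPUT_GENES.index(g)] = course
        endo = [g for g in OUTPUT_GENES if g in target_set]
        for g in endo:
            x[0, OUTPUT_GENES.index(g)] = rng.uniform(0.5, 2.5)
        for k in range(n_times - 1):
            drive = network.baseline + x[k] @ W
            for g in endo:
                j = OUTPUT_GENES.index(g)
                x[k + 1, j] = _saturate(drive[j], network.cap)
        for gi, gene in enumerate(INPUT_GENES):
            samples = x[:, gi][:, None] + rng.normal(0.0, noise_sd,
                                                     size=(n_times, n_samples))
            entries[(gene, _NN_TISSUE[gene], genotype, photoperiod)] = (
                times.copy(), np.clip(samples, 0.0, None))
    expanded = ExpandedDataset(entries=entries, n_samples=n_samples, seed=seed)
    return expanded, network.truth_signs()
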