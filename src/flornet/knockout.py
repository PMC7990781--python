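"""In-silico knockouts on trained one-step regressors.

To read the regulatory topology a trained neural model has captured, each
regulator gene is zeroed in turn while all other regulators stay fixed at
their data values, and one-step predictions are collected over the
measured time grid (no feedback rollout, by construction).  The influence
of a regulator on a target is summarized by the ratio of the areas under
the predicted expression curves,

    ratio = S_knock_out / S_wt,

where both areas come from the same one-step estimator so estimator bias
cancels.  A ratio below 1 means the knockout lowered the target's
expression (the regulator activates it), above 1 means repression, and
ratios within a tolerance band around 1 are called "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ConditionKey, Trajectory
from .nn_models import INPUT_GENES, OUTPUT_GENES, ExpandedDataset, RegressorEnsemble


@dataclass
class KnockoutMatrix:
    """Regulator x target grid of AUC ratios (7 x 6 for the full panel)."""

    ratios: np.ndarray
    regulators: tuple = INPUT_GENES
    targets: tuple = OUTPUT_GENES

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.regulators), len(self.targets)):
            raise ValueError("ratio grid shape must be regulators x targets")

    def ratio(self, regulator: str, target: str) -> float:
        return float(self.ratios[self.regulators.index(regulator),
                                 self.targets.index(target)])

    def is_self_effect(self, regulator: str, target: str) -> bool:
        return regulator == target


@dataclass(frozen=True)
class InteractionCall:
    regulator: str
    target: str
    ratio: float
    call: str  # activator | repressor | none
    tolerance: float


def auc(trajectory) -> float:
    """Trapezoidal area under an expression time course (expression * days)."""
    if isinstance(trajectory, Trajectory):
        times, values = trajectory.times, trajectory.values
    else:
        times, values = (np.asarray(a, dtype=float) for a in trajectory)
    if times.size < 2:
        raise ValueError("AUC needs at least 2 time points")
    return float(np.trapezoid(values, times))


def _mean_states(expanded: ExpandedDataset, condition: ConditionKey):
    """(times, X) with X the per-time mean 7-gene data state."""
    times = expanded.times(condition)
    X = np.vstack([
        expanded.state_matrix(condition, t, INPUT_GENES).mean(axis=0)
        for t in times
    ])
    return times, X


def one_step_predictions(ensemble: RegressorEnsemble, expanded: ExpandedDataset,
                         condition: ConditionKey, knockout_gene: str | None = None):
    """(times, preds): one-step ensemble-mean predictions at every data state.

    Every input vector is the data state at that time point (means of the
    unexpanded records), with ``knockout_gene``'s column forced to zero
    when given; targets are predicted independently per time point.
    """
    times, X = _mean_states(expanded, condition)
    if knockout_gene is not None:
        if knockout_gene not in INPUT_GENES:
            raise ValueError(f"unknown regulator {knockout_gene!r}")
        X = X.copy()
        X[:, INPUT_GENES.index(knockout_gene)] = 0.0
    # expression is nonnegative; clip regressor extrapolations below zero
    return times, np.clip(ensemble.predict(X), 0.0, None)


def simulate_knockout(ensemble: RegressorEnsemble, expanded: ExpandedDataset,
                      regulator: str, condition: ConditionKey) -> dict:
    """Per-target predicted trajectories with one regulator zeroed."""
    times, preds = one_step_predictions(ensemble, expanded, condition, regulator)
    return {g: Trajectory(g, "apex", times, preds[:, j])
            for j, g in enumerate(OUTPUT_GENES)}


def knockout_ratio_matrix(ensemble: RegressorEnsemble, expanded: ExpandedDataset,
                          condition: ConditionKey) -> KnockoutMatrix:
    """AUC ratios S_knock_out / S_wt for every regulator -> target pair.

    Targets whose unperturbed AUC is zero get NaN (ratio undefined).
    """
    times, wt = one_step_predictions(ensemble, expanded, condition)
    s_wt = np.array([auc((times, wt[:, j])) for j in range(len(OUTPUT_GENES))])
    ratios = np.empty((len(INPUT_GENES), len(OUTPUT_GENES)))
    for i, reg in enumerate(INPUT_GENES):
        _t, ko = one_step_predictions(ensemble, expanded, condition, reg)
        for j in range(len(OUTPUT_GENES)):
            if s_wt[j] == 0.0:
                ratios[i, j] = np.nan
            else:
                ratios[i, j] = auc((times, ko[:, j])) / s_wt[j]
    return KnockoutMatrix(ratios=ratios)


def classify_interactions(matrix: KnockoutMatrix,
                          tolerance: float = 0.05) -> list[InteractionCall]:
    """Threshold the ratio grid: <1-tol activator, >1+tol repressor, else none."""
    calls = []
    for i, reg in enumerate(matrix.regulators):
        for j, tgt in enumerate(matrix.targets):
            r = matrix.ratios[i, j]
            if np.isnan(r):
                continue
            if r < 1.0 - tolerance:
                call = "activator"
            elif r > 1.0 + tolerance:
                call = "repressor"
            else:
                call = "none"
            calls.append(InteractionCall(regulator=reg, target=tgt,
                                         ratio=float(r), call=call,
                                         tolerance=tolerance))
    return calls
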