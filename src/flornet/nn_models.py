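"""Neural one-step dynamical regression of the apical network.

Instead of a prescribed regulation scheme, a multilayer perceptron learns
the one-step map of the system directly from data: the apical expression
of six target genes (*DET*, *PIM*, *FTc*, *FTa1*, *LF*, *VEG2*) at one
measured time point is regressed on the expression of seven genes (the
six targets plus leaf *FTb2*, the mobile florigen input) at the previous
measured time point.  *VEG1* is excluded from this arm entirely.

Because only a handful of time points exist per condition, each data
record is expanded into ``n_samples`` draws (default 1000) from
Normal(mean, sd), truncated at zero; draws are paired by index across
consecutive time points to form training pairs.  Regressors use the
logistic sigmoid activation and are trained with Adam, each as an
ensemble of members with 5-fold cross-validation scores recorded.
Inputs and outputs are min-max scaled per gene before training and
inverse-transformed for reporting.

Protocols: ``NN`` trains on all conditions, ``NN_SDdata`` on the SD
conditions (WT-SD and *dne-1*), both holding out the last measured day
of every condition as the test set; ``NN_LDdata`` trains on WT-LD and
*gigas-2* and uses the whole *late1-2* condition as the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, cross_val_score
from sklearn.neural_network import MLPRegressor

from .data_model import ConditionKey, ExpressionDataset

INPUT_GENES = ("DET", "PIM", "FTc", "FTa1", "LF", "VEG2", "FTb2")
OUTPUT_GENES = ("DET", "PIM", "FTc", "FTa1", "LF", "VEG2")

#: tissue carrying each NN gene's series (FTb2 is the leaf-borne input)
_NN_TISSUE = {g: ("leaf" if g == "FTb2" else "apex") for g in INPUT_GENES}

_PROTOCOL_SCOPES = {
    "NN": [("WT", "SD"), ("WT", "LD"), ("dne-1", "SD"), ("late1-2", "LD"), ("gigas-2", "LD")],
    "NN_SDdata": [("WT", "SD"), ("dne-1", "SD")],
    "NN_LDdata": [("WT", "LD"), ("gigas-2", "LD"), ("late1-2", "LD")],
}


@dataclass
class ExpandedDataset:
    """Per-record normal resamples: key -> (times, samples[T, n_samples])."""

    entries: dict
    n_samples: int
    seed: int

    def conditions(self) -> list[ConditionKey]:
        seen = []
        for (_g, _t, genotype, photoperiod) in self.entries:
            ck = ConditionKey(genotype, photoperiod)
            if ck not in seen:
                seen.append(ck)
        return seen

    def times(self, condition: ConditionKey) -> np.ndarray:
        """Common time grid of the NN genes in this condition."""
        grids = [t for (g, ti, gt, pp), (t, _s) in self.entries.items()
                 if (gt, pp) == tuple(condition) and g in INPUT_GENES]
        if not grids:
            raise KeyError(f"no NN-gene records in condition {tuple(condition)}")
        common = grids[0]
        for t in grids[1:]:
            common = np.intersect1d(common, t)
        return common

    def state_matrix(self, condition: ConditionKey, t: float, genes: Sequence[str]) -> np.ndarray:
        """Samples x genes matrix at one time point (zeros for null genes)."""
        cols = []
        for g in genes:
            key = (g, _NN_TISSUE[g], condition.genotype, condition.photoperiod)
            if key not in self.entries:
                cols.append(np.zeros(self.n_samples))
                continue
            times, samples = self.entries[key]
            idx = np.searchsorted(times, t)
            if idx >= times.size or times[idx] != t:
                raise KeyError(f"gene {g} has no sample at t={t} in {tuple(condition)}")
            cols.append(samples[idx])
        return np.column_stack(cols)


def expand_dataset(dataset: ExpressionDataset, n_samples: int = 1000,
                   seed: int = 0) -> ExpandedDataset:
    """Draw n_samples values per record from Normal(mean, sd), clipped at 0."""
    rng = np.random.default_rng(seed)
    entries = {}
    groups = dataset.frame.groupby(["gene", "tissue", "genotype", "photoperiod"],
                                   sort=True)
    for key, sub in groups:
        times = sub["time"].to_numpy(dtype=float)
        means = sub["mean"].to_numpy(dtype=float)
        sds = sub["sd"].to_numpy(dtype=float)
        samples = rng.normal(means[:, None], sds[:, None], size=(times.size, n_samples))
        entries[key] = (times, np.clip(samples, 0.0, None))
    return ExpandedDataset(entries=entries, n_samples=n_samples, seed=seed)


def _filter(expanded: ExpandedDataset, keep) -> ExpandedDataset:
    """Subset an expanded dataset with keep(key, time) -> bool, per time point."""
    entries = {}
    for key, (times, samples) in expanded.entries.items():
        mask = np.array([keep(key, t) for t in times], dtype=bool)
        if mask.any():
            entries[key] = (times[mask], samples[mask])
    return ExpandedDataset(entries=entries, n_samples=expanded.n_samples,
                           seed=expanded.seed)


def protocol_conditions(protocol: str) -> list[ConditionKey]:
    try:
        pairs = _PROTOCOL_SCOPES[protocol]
    except KeyError:
        raise ValueError(f"unknown protocol {protocol!r}; one of {sorted(_PROTOCOL_SCOPES)}") from None
    return [ConditionKey(g, p) for g, p in pairs]


def split_train_test(expanded: ExpandedDataset, protocol: str):
    """(train, test) expanded datasets for a named training protocol."""
    conditions = protocol_conditions(protocol)
    cond_keys = {tuple(c) for c in conditions}
    scoped = _filter(expanded, lambda key, t: (key[2], key[3]) in cond_keys)

    if protocol == "NN_LDdata":
        in_test = lambda key, t: key[2] == "late1-2"
    else:
        last_day = {}
        for c in conditions:
            times = scoped.times(c)
            last_day[tuple(c)] = float(times[-1])
        in_test = lambda key, t: t == last_day[(key[2], key[3])]

    train = _filter(scoped, lambda key, t: not in_test(key, t))
    test = _filter(scoped, lambda key, t: in_test(key, t))
    return train, test


def build_training_pairs(expanded: ExpandedDataset,
                         conditions: Iterable[ConditionKey] | None = None):
    """(X, Y) one-step pairs: X rows are 7-gene states at t_k, Y rows the
    6-gene states at the next measured time t_{k+1}, samples paired by
    index; pairs never cross condition boundaries."""
    if conditions is None:
        conditions = expanded.conditions()
    xs, ys = [], []
    for condition in conditions:
        times = expanded.times(condition)
        if times.size < 2:
            warnings.warn(f"condition {tuple(condition)} has a single time point; skipped")
            continue
        for k in range(times.size - 1):
            xs.append(expanded.state_matrix(condition, times[k], INPUT_GENES))
            ys.append(expanded.state_matrix(condition, times[k + 1], OUTPUT_GENES))
    if not xs:
        raise ValueError("no training pairs could be built")
    return np.vstack(xs), np.vstack(ys)


def evaluation_pairs(expanded: ExpandedDataset, protocol: str):
    """(X, Y) pairs whose target time point belongs to the protocol's test set."""
    conditions = protocol_conditions(protocol)
    _train, test = split_train_test(expanded, protocol)
    cond_keys = {tuple(c) for c in conditions}
    scoped = _filter(expanded, lambda key, t: (key[2], key[3]) in cond_keys)
    test_times = {}
    for c in test.conditions():
        test_times[tuple(c)] = set(test.times(c).tolist())
    xs, ys = [], []
    for condition in scoped.conditions():
        times = scoped.times(condition)
        tt = test_times.get(tuple(condition), set())
        for k in range(times.size - 1):
            if times[k + 1] in tt:
                xs.append(scoped.state_matrix(condition, times[k], INPUT_GENES))
                ys.append(scoped.state_matrix(condition, times[k + 1], OUTPUT_GENES))
    if not xs:
        raise ValueError(f"protocol {protocol} yields no evaluation pairs")
    return np.vstack(xs), np.vstack(ys)


# ---------------------------------------------------------------------------
# Regressor ensemble
# ---------------------------------------------------------------------------

@dataclass
class _MinMaxScaler:
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_MinMaxScaler":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)  # constant column guard
        return cls(lo=lo, hi=hi)

    def transform(self, X):
        return (X - self.lo) / (self.hi - self.lo)

    def inverse(self, Z):
        return Z * (self.hi - self.lo) + self.lo


@dataclass
class RegressorEnsemble:
    topology: tuple
    members: list
    cv_scores: list
    x_scaler: _MinMaxScaler
    y_scaler: _MinMaxScaler
    input_genes: tuple = INPUT_GENES
    output_genes: tuple = OUTPUT_GENES
    flags: list = field(default_factory=list)

    def predict_members(self, X: np.ndarray) -> np.ndarray:
        """Per-member predictions, shape (n_members, n_rows, 6), natural units."""
        Z = self.x_scaler.transform(np.atleast_2d(X))
        preds = [self.y_scaler.inverse(m.predict(Z)) for m in self.members]
        return np.stack(preds)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-mean prediction in natural units, shape (n_rows, 6)."""
        return self.predict_members(X).mean(axis=0)


def train_regressor(pairs, topology=(16,), n_members: int = 20, seed: int = 0,
                    cv: int = 5, max_iter: int = 500,
                    tol: float = 1e-6) -> RegressorEnsemble:
    """Train an ensemble of one-step MLP regressors on (X, Y) pairs.

    Each member gets its own initialization seed and a k-fold CV score
    (coefficient of determination) recorded before the final fit on all
    pairs.  Non-converged members are flagged but retained.  The loss
    tolerance defaults well below sklearn's, because with min-max-scaled
    multi-output targets the mean loss is small and the default stops
    training long before the informative outputs are learned.
    """
    X, Y = pairs
    if len(X) == 0:
        raise ValueError("empty training pairs")
    x_scaler = _MinMaxScaler.fit(X)
    y_scaler = _MinMaxScaler.fit(Y)
    Xs, Ys = x_scaler.transform(X), y_scaler.transform(Y)
    members, scores, flags = [], [], []
    for i in range(n_members):
        member_seed = seed + i
        mlp = MLPRegressor(hidden_layer_sizes=topology, activation="logistic",
                           solver="adam", random_state=member_seed,
                           max_iter=max_iter, tol=tol)
        folds = KFold(n_splits=cv, shuffle=True, random_state=member_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cv_score = float(np.mean(cross_val_score(mlp, Xs, Ys, cv=folds, scoring="r2")))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                mlp.fit(Xs, Ys)
                converged = not any(issubclass(w.category, ConvergenceWarning)
                                    for w in caught)
        members.append(mlp)
        scores.append(cv_score)
        flags.append("ok" if converged else "not_converged")
    return RegressorEnsemble(topology=tuple(np.atleast_1d(topology).tolist()),
                             members=members, cv_scores=scores,
                             x_scaler=x_scaler, y_scaler=y_scaler, flags=flags)


def select_topology(pairs, grid=((8,), (16,), (32,), (16, 8)), seed: int = 0,
                    cv: int = 5, max_iter: int = 300) -> tuple:
    """Pick the hidden-layer layout with the best mean CV score on the grid."""
    best, best_score = None, -np.inf
    for topology in grid:
        ens = train_regressor(pairs, topology=topology, n_members=1, seed=seed,
                              cv=cv, max_iter=max_iter)
        score = ens.cv_scores[0]
        if score > best_score:
            best, best_score = tuple(topology), score
    return best


def save_ensemble(ensemble: RegressorEnsemble, path) -> None:
    """Serialize a trained ensemble (topology, scalers, weights) to JSON."""
    import json

    payload = {
        "topology": list(ensemble.topology),
        "cv_scores": ensemble.cv_scores,
        "flags": ensemble.flags,
        "input_genes": list(ensemble.input_genes),
        "output_genes": list(ensemble.output_genes),
        "x_scaler": {"lo": ensemble.x_scaler.lo.tolist(), "hi": ensemble.x_scaler.hi.tolist()},
        "y_scaler": {"lo": ensemble.y_scaler.lo.tolist(), "hi": ensemble.y_scaler.hi.tolist()},
        "members": [
            {
                "coefs": [c.tolist() for c in m.coefs_],
                "intercepts": [b.tolist() for b in m.intercepts_],
            }
            for m in ensemble.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> RegressorEnsemble:
    """Inverse of :func:`save_ensemble`; rebuilds fitted MLPRegressor members."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    topology = tuple(payload["topology"])
    members = []
    for m in payload["members"]:
        coefs = [np.asarray(c) for c in m["coefs"]]
        intercepts = [np.asarray(b) for b in m["intercepts"]]
        mlp = MLPRegressor(hidden_layer_sizes=topology, activation="logistic",
                           solver="adam", max_iter=1)
        n_in = coefs[0].shape[0]
        n_out = intercepts[-1].shape[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.fit(np.zeros((max(n_out, 2), n_in)), np.zeros((max(n_out, 2), n_out)))
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        members.append(mlp)
    return RegressorEnsemble(
        topology=topology,
        members=members,
        cv_scores=payload["cv_scores"],
        x_scaler=_MinMaxScaler(lo=np.asarray(payload["x_scaler"]["lo"]),
                               hi=np.asarray(payload["x_scaler"]["hi"])),
        y_scaler=_MinMaxScaler(lo=np.asarray(payload["y_scaler"]["lo"]),
                               hi=np.asarray(payload["y_scaler"]["hi"])),
        input_genes=tuple(payload["input_genes"]),
        output_genes=tuple(payload["output_genes"]),
        flags=payload["flags"],
    )


def rollout(ensemble: RegressorEnsemble, initial: np.ndarray,
            ftb2_series: np.ndarray, times: np.ndarray):
    """Iterate one-step predictions across the measured time grid.

    ``initial`` is the 6-gene state at times[0]; ``ftb2_series`` supplies
    the leaf FTb2 input at every time point.  Returns (mean, members):
    the ensemble-mean trajectory array of shape (T, 6) and the per-member
    array of shape (n_members, T, 6).
    """
    times = np.asarray(times, dtype=float)
    ftb2 = np.asarray(ftb2_series, dtype=float)
    if ftb2.size < times.size:
        raise ValueError("FTb2 input series must cover every time point")
    n_m = len(ensemble.members)
    states = np.empty((n_m, times.size, len(OUTPUT_GENES)))
    states[:, 0, :] = np.asarray(initial, dtype=float)
    for k in range(times.size - 1):
        for m in range(n_m):
            x = np.append(states[m, k, :], ftb2[k])[None, :]
            # expression is nonnegative; clip before feeding the state back
            states[m, k + 1, :] = np.clip(ensemble.predict_members(x)[m, 0], 0.0, None)
    return states.mean(axis=0), states
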