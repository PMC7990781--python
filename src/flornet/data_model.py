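"""Expression-data types and accessors.

The currency of the whole pipeline is a tidy table of gene-expression time
series measured in pea (*Pisum sativum*) shoot apices and leaves across
genotypes and photoperiods: one row per (gene, tissue, genotype,
photoperiod, day-after-sowing) carrying a mean relative expression level
and its standard deviation.  Eight genes form the panel: the mobile
florigen-like genes *FTa1* (leaf and apex), *FTb2* (leaf only) and *FTc*,
the *FD* homologue *VEG2*, and the meristem-identity/repressor genes
*DET*, *LF*, *VEG1* and *PIM* (apex only).

This module defines the validated dataset container, CSV input/output,
piecewise-linear time interpolation of regulator trajectories, and the
per-gene dynamic-range lookup used to normalize model-to-data residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Panel constants
# ---------------------------------------------------------------------------

GENES = ("FTa1", "FTb2", "FTc", "DET", "LF", "VEG1", "VEG2", "PIM")

#: tissues each gene may legitimately carry records for
GENE_TISSUES = {
    "FTa1": ("leaf", "apex"),
    "FTb2": ("leaf",),
    "FTc": ("apex",),
    "DET": ("apex",),
    "LF": ("apex",),
    "VEG1": ("apex",),
    "VEG2": ("apex",),
    "PIM": ("apex",),
}

TISSUES = ("leaf", "apex")
GENOTYPES = ("WT", "dne-1", "late1-2", "gigas-2")
PHOTOPERIODS = ("SD", "LD")

#: the genotype x photoperiod combinations present in the study design
VALID_CONDITIONS = (
    ("WT", "SD"),
    ("WT", "LD"),
    ("dne-1", "SD"),
    ("late1-2", "LD"),
    ("gigas-2", "LD"),
)

COLUMNS = ["gene", "tissue", "genotype", "photoperiod", "time", "mean", "sd"]

EPS_RANGE = 1e-12  # guard for zero dynamic range in normalized residuals


class SchemaError(ValueError):
    """Input table is missing required columns."""


class ValidationError(ValueError):
    """Input table violates a dataset invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionKey:
    """One experimental condition: a genotype grown under one photoperiod."""

    genotype: str
    photoperiod: str

    def __post_init__(self) -> None:
        if (self.genotype, self.photoperiod) not in VALID_CONDITIONS:
            raise ValidationError(
                f"invalid condition {self.genotype} x {self.photoperiod}; "
                f"valid: {VALID_CONDITIONS}"
            )

    def __iter__(self):
        return iter((self.genotype, self.photoperiod))


@dataclass
class Trajectory:
    """A single time course of one gene in one tissue."""

    gene: str
    tissue: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite values in trajectory {self.gene}")

    def __call__(self, t):
        return interpolate_trajectory(self, t)


@dataclass
class ExpressionDataset:
    """Validated multi-condition expression table.

    Thin wrapper over a tidy :class:`pandas.DataFrame` with columns
    ``gene, tissue, genotype, photoperiod, time, mean, sd``; construction
    enforces the panel invariants (valid gene/tissue pairs, valid
    conditions, strictly increasing times within each series, nonnegative
    finite means and SDs, no VEG1 records under SD).
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    # -- accessors ----------------------------------------------------------

    def series(self, gene: str, tissue: str, condition: ConditionKey) -> Trajectory:
        """Return one (gene, tissue, condition) series as a Trajectory of means."""
        sub = self._select(gene, tissue, condition)
        if sub.empty:
            raise KeyError(
                f"no records for {gene}/{tissue} in {condition.genotype}-{condition.photoperiod}"
            )
        return Trajectory(gene, tissue, sub["time"].to_numpy(), sub["mean"].to_numpy())

    def sd_series(self, gene: str, tissue: str, condition: ConditionKey) -> Trajectory:
        sub = self._select(gene, tissue, condition)
        if sub.empty:
            raise KeyError(f"no records for {gene}/{tissue} in {tuple(condition)}")
        return Trajectory(gene, tissue, sub["time"].to_numpy(), sub["sd"].to_numpy())

    def has_series(self, gene: str, tissue: str, condition: ConditionKey) -> bool:
        return not self._select(gene, tissue, condition).empty

    def conditions(self) -> list[ConditionKey]:
        keys = self.frame[["genotype", "photoperiod"]].drop_duplicates()
        return [ConditionKey(g, p) for g, p in keys.itertuples(index=False)]

    def _select(self, gene, tissue, condition) -> pd.DataFrame:
        f = self.frame
        return f[
            (f["gene"] == gene)
            & (f["tissue"] == tissue)
            & (f["genotype"] == condition.genotype)
            & (f["photoperiod"] == condition.photoperiod)
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    f = frame[COLUMNS].copy()
    if len(f) == 0:
        return f.astype({"time": float, "mean": float, "sd": float}, errors="ignore")
    f["time"] = pd.to_numeric(f["time"])
    f["mean"] = pd.to_numeric(f["mean"])
    f["sd"] = pd.to_numeric(f["sd"])

    bad_gene = set(f["gene"]) - set(GENES)
    if bad_gene:
        raise ValidationError(f"unknown genes: {sorted(bad_gene)}")
    for gene, sub in f.groupby("gene", sort=False):
        bad = set(sub["tissue"]) - set(GENE_TISSUES[gene])
        if bad:
            raise ValidationError(f"gene {gene} has records in invalid tissue(s) {sorted(bad)}")
    conds = set(map(tuple, f[["genotype", "photoperiod"]].drop_duplicates().to_numpy()))
    bad_cond = conds - set(VALID_CONDITIONS)
    if bad_cond:
        raise ValidationError(f"invalid genotype x photoperiod combinations: {sorted(bad_cond)}")

    vals = f[["time", "mean", "sd"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite time/mean/sd values present")
    if (f["mean"] < 0).any() or (f["sd"] < 0).any():
        raise ValidationError("negative mean or sd values present")

    veg1_sd = f[(f["gene"] == "VEG1") & (f["photoperiod"] == "SD")]
    if not veg1_sd.empty:
        raise ValidationError("VEG1 must have no records under SD")

    for key, sub in f.groupby(["gene", "tissue", "genotype", "photoperiod"], sort=False):
        t = sub["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"times not strictly increasing within series {key} "
                "(unsorted or duplicated time points)"
            )
    return f


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_expression_table(path) -> ExpressionDataset:
    """Read a tidy expression CSV and return a validated dataset.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for rows violating dataset invariants.
    """
    frame = pd.read_csv(path)
    return ExpressionDataset(frame)


def write_expression_table(dataset: ExpressionDataset, path) -> None:
    """Write the dataset in the canonical column order; inverse of load."""
    dataset.frame.to_csv(path, index=False, columns=COLUMNS)


# ---------------------------------------------------------------------------
# Interpolation and ranges
# ---------------------------------------------------------------------------

def interpolate_trajectory(series, t):
    """Piecewise-linear interpolation of a series at time(s) ``t``.

    Outside the observed window the boundary value is held constant
    (required because the leaf-to-apex transport delay queries t - tau
    before the first observation day).  ``series`` may be a
    :class:`Trajectory` or a ``(times, values)`` pair.
    """
    if isinstance(series, Trajectory):
        times, values = series.times, series.values
    else:
        times, values = (np.asarray(a, dtype=float) for a in series)
    if times.size == 0:
        raise ValidationError("cannot interpolate an empty series")
    return np.interp(t, times, values)


def min_max_range(
    dataset: ExpressionDataset,
    gene: str,
    scope: Iterable[ConditionKey] | ConditionKey,
    tissue: str | None = None,
) -> tuple[float, float]:
    """(min, max) of the data means for ``gene`` within the given scope.

    The scope is the same data subset that enters the fitting cost; the
    returned envelope supplies the (u_max - u_min) normalization of the
    residuals.  Raises if no records fall in scope.
    """
    if isinstance(scope, ConditionKey):
        scope = [scope]
    f = dataset.frame
    mask = f["gene"] == gene
    if tissue is not None:
        mask &= f["tissue"] == tissue
    cond_mask = False
    for c in scope:
        cond_mask = cond_mask | (
            (f["genotype"] == c.genotype) & (f["photoperiod"] == c.photoperiod)
        )
    sub = f[mask & cond_mask]
    if sub.empty:
        raise ValidationError(f"no records for gene {gene} in the requested scope")
    m = sub["mean"].to_numpy()
    return float(m.min()), float(m.max())


def safe_range_width(u_min: float, u_max: float) -> float:
    """Dynamic-range width with an epsilon floor for degenerate (flat) series."""
    return max(u_max - u_min, EPS_RANGE)
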