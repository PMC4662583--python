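"""Shielding-to-shift calibration, accuracy metrics and outlier flags.

Shifts relate to shieldings through delta = b - a * sigma with a and b
fitted per atom type by ordinary least squares.  RMSD and Pearson r are
computed after the regression; outliers are flagged with Rosner's
generalized extreme studentized deviate (GESD) test but are only removed
when a refit is explicitly requested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, GridShieldWarning, ShiftTableError
from .model_io import ShiftTable, read_shift_table
from .predictor import EnsemblePrediction, TermBreakdown
from .residues import ATOM_TYPES


@dataclass
class RandomCoilTable:
    """Sequence-corrected random-coil shifts keyed by (seq_index, atom_type)."""

    entries: dict = field(default_factory=dict)

    def get(self, seq_index: int, atom_type: str) -> float | None:
        return self.entries.get((seq_index, atom_type))

    @staticmethod
    def zeros() -> "RandomCoilTable":
        return RandomCoilTable({})

    def value_or_raise(self, seq_index: int, atom_type: str) -> float:
        if not self.entries:
            return 0.0  # the all-zeros default table
        v = self.entries.get((seq_index, atom_type))
        if v is None:
            raise ShiftTableError(
                f"random-coil table lacks ({seq_index}, {atom_type})")
        return v


def read_random_coil_table(path) -> RandomCoilTable:
    """Same flat format as experimental shift tables."""
    table = read_shift_table(path)
    return RandomCoilTable(dict(table.entries))


@dataclass
class CalibrationResult:
    atom_type: str
    a: float
    b: float
    n: int
    rmsd: float
    pearson_r: float
    outliers: list = field(default_factory=list)
    keys: list = field(default_factory=list)
    residuals: np.ndarray | None = None
    a_refit: float = math.nan
    b_refit: float = math.nan
    rmsd_refit: float = math.nan
    pearson_r_refit: float = math.nan


def fit(sigma, delta_exp, atom_type: str = "") -> CalibrationResult:
    """OLS of delta on sigma, reported in the delta = b - a*sigma convention.

    Pearson r is reported as a magnitude, as is conventional for
    shielding-shift correlations (the raw correlation is negative).
    """
    sigma = np.asarray(sigma, dtype=float)
    delta = np.asarray(delta_exp, dtype=float)
    if sigma.shape != delta.shape or sigma.ndim != 1:
        raise DegenerateFitError("sigma and delta must be matched 1-D series")
    n = sigma.size
    if n < 3:
        raise DegenerateFitError(f"{atom_type}: need >= 3 pairs, got {n}")
    if not (np.all(np.isfinite(sigma)) and np.all(np.isfinite(delta))):
        raise DegenerateFitError(f"{atom_type}: non-finite values in fit input")
    if np.ptp(sigma) < 1e-12:
        raise DegenerateFitError(f"{atom_type}: zero variance in sigma")
    slope, intercept = np.polyfit(sigma, delta, 1)
    resid = delta - (intercept + slope * sigma)
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    if np.ptp(delta) < 1e-12:
        raise DegenerateFitError(f"{atom_type}: zero variance in delta")
    r = float(np.corrcoef(sigma, delta)[0, 1])
    return CalibrationResult(atom_type=atom_type, a=float(-slope),
                             b=float(intercept), n=int(n), rmsd=rmsd,
                             pearson_r=abs(r), residuals=resid)


def apply_random_coil(values: dict, rc: RandomCoilTable) -> dict:
    """Subtract random-coil references from a (seq, atom) -> shift mapping."""
    out = {}
    for (seq, atom), val in values.items():
        out[(seq, atom)] = val - rc.value_or_raise(seq, atom)
    return out


def gesd_outliers(residuals, alpha: float = 0.05, max_k: int = 5) -> list[int]:
    """Indices flagged by Rosner's generalized ESD test.

    Iteratively removes the most extreme point and compares each test
    statistic R_j against its critical value lambda_j from the t
    distribution; flags all points up to the largest j with R_j > lambda_j.
    A zero-variance iteration stops the search.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n <= max_k + 2:
        raise ValueError(f"need n > max_k + 2 (n={n}, max_k={max_k})")
    remaining = list(range(n))
    removed: list[int] = []
    stats_r: list[float] = []
    lambdas: list[float] = []
    for j in range(1, max_k + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd < 1e-12:
            break
        dev = np.abs(sub - sub.mean())
        pos = int(np.argmax(dev))
        stats_r.append(float(dev[pos] / sd))
        m = len(remaining)
        p = 1.0 - alpha / (2.0 * m)
        t = stats.t.ppf(p, m - 2)
        lambdas.append(float((m - 1) * t / math.sqrt((m - 2 + t * t) * m)))
        removed.append(remaining.pop(pos))
    n_out = 0
    for j in range(len(stats_r)):
        if stats_r[j] > lambdas[j]:
            n_out = j + 1
    return sorted(removed[:n_out])


def _as_sigma_map(predictions) -> tuple[dict, dict]:
    if isinstance(predictions, EnsemblePrediction):
        return dict(predictions.values), dict(predictions.res_types)
    values: dict[tuple[int, str], float] = {}
    res_types: dict[int, str] = {}
    for b in predictions:
        if not isinstance(b, TermBreakdown):
            raise TypeError("predictions must be an EnsemblePrediction or "
                            "a TermBreakdown collection")
        key = (b.seq_index, b.atom_type)
        if key in values:
            raise ShiftTableError(f"duplicate prediction for {key}; "
                                  "average multi-model input first")
        values[key] = b.sigma_total
        res_types[b.seq_index] = b.res_type
    return values, res_types


@dataclass
class EvaluateOptions:
    gesd: bool = True
    alpha: float = 0.05
    max_k: int = 5
    refit: bool = False
    min_pairs: int = 3


def evaluate(predictions, exp: ShiftTable, rc: RandomCoilTable | None = None,
             options: EvaluateOptions | None = None) -> dict[str, CalibrationResult]:
    """Per-atom-type calibration of predicted shieldings to experiment.

    Experimental shifts are random-coil corrected before the fit when a
    table is given (this leaves the RMSD invariant only at unit slope).
    Keys present on one side only are ignored; atom types with fewer than
    ``options.min_pairs`` matches are skipped with a warning.
    """
    options = options or EvaluateOptions()
    rc = rc or RandomCoilTable.zeros()
    sigma_map, _ = _as_sigma_map(predictions)
    results: dict[str, CalibrationResult] = {}
    for atom_type in ATOM_TYPES:
        keys = sorted(k for k in sigma_map
                      if k[1] == atom_type and exp.get(*k) is not None)
        if len(keys) < options.min_pairs:
            if keys:
                warnings.warn(f"{atom_type}: only {len(keys)} matched pairs; "
                              "skipped", GridShieldWarning, stacklevel=2)
            continue
        sigma = np.array([sigma_map[k] for k in keys])
        delta = np.array([exp.get(*k) - rc.value_or_raise(*k) for k in keys])
        res = fit(sigma, delta, atom_type)
        res.keys = keys
        if options.gesd and len(keys) > options.max_k + 2:
            flagged = gesd_outliers(res.residuals, options.alpha, options.max_k)
            res.outliers = [keys[i] for i in flagged]
            if options.refit and flagged:
                keep = [i for i in range(len(keys)) if i not in flagged]
                refit = fit(sigma[keep], delta[keep], atom_type)
                res.a_refit, res.b_refit = refit.a, refit.b
                res.rmsd_refit = refit.rmsd
                res.pearson_r_refit = refit.pearson_r
        results[atom_type] = res
    return results
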