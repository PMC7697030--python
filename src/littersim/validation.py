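"""Split-sample validation of the conditional cosimulation.

A random subset of the survey conditions the simulation; the held-out
samples provide ground truth at unsampled locations.  Two diagnostics are
reported per variable:

* the least-squares regression of true values on the realization-mean
  estimates (close to the identity line for an accurate model), and
* the accuracy plot: for each nominal probability p, the fraction of
  held-out locations whose true value falls inside the symmetric
  p-probability interval of the local realization ensemble.  A
  well-calibrated ensemble puts these points on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cosimulation import DEFAULT_VAR_COLS, run_cosimulation
from .exceptions import DegenerateInputError
from .grids import GridSpec
from .variography import LMCModel

__all__ = [
    "split_samples",
    "regression_validation",
    "RegressionResult",
    "accuracy_plot",
    "CoverageCurve",
    "validate_simulation",
    "ValidationReport",
]


def split_samples(samples: pd.DataFrame, n_train: int, seed: int = 0):
    """Uniform random train/test split without replacement.

    Returns ``(train, test)`` DataFrames; the test set is the complement of
    the training draw.  Deterministic under ``seed``.
    """
    n = len(samples)
    if not 1 <= n_train < n:
        raise ValueError(f"n_train must be in [1, {n - 1}]")
    rng = np.random.default_rng(seed)
    train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return samples.iloc[mask].copy(), samples.iloc[~mask].copy()


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    correlation: float


def regression_validation(true_values, estimated) -> RegressionResult:
    """OLS regression of true on estimated values (identity-closeness check)."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimated, dtype=float).ravel()
    if t.size != e.size or t.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(e) == 0:
        raise DegenerateInputError("estimates have zero variance")
    res = stats.linregress(e, t)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
    )


@dataclass(frozen=True)
class CoverageCurve:
    probs: np.ndarray
    coverage: np.ndarray


def accuracy_plot(ensembles, true_values, probs=None) -> CoverageCurve:
    """Observed coverage of symmetric ensemble probability intervals.

    ``ensembles`` is (n_real, n_locations); for each nominal p the interval
    spans the (1-p)/2 and (1+p)/2 ensemble quantiles (linear interpolation of
    order statistics) at each location.
    """
    ens = np.asarray(ensembles, dtype=float)
    t = np.asarray(true_values, dtype=float).ravel()
    if ens.ndim != 2 or ens.shape[1] != t.size:
        raise ValueError("ensembles must be (n_real, n_locations)")
    if probs is None:
        probs = np.round(np.arange(0.1, 1.001, 0.1), 10)
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0) or np.any(probs > 1):
        raise ValueError("probs must lie in (0, 1]")
    cov = np.empty(probs.size)
    for i, p in enumerate(probs):
        lo = np.quantile(ens, (1 - p) / 2, axis=0)
        hi = np.quantile(ens, (1 + p) / 2, axis=0)
        cov[i] = np.mean((t >= lo) & (t <= hi))
    return CoverageCurve(probs=probs, coverage=cov)


@dataclass
class ValidationReport:
    train_index: np.ndarray
    test_index: np.ndarray
    true_values: np.ndarray  # (n_test, 2)
    estimates: np.ndarray  # (n_test, 2) realization means
    regressions: tuple[RegressionResult, ...]
    coverage: tuple[CoverageCurve, ...] | None
    var_names: tuple[str, ...]

    def to_dict(self) -> dict:
        out = {
            "n_train": int(self.train_index.size),
            "n_test": int(self.test_index.size),
            "regressions": {
                name: {"slope": r.slope, "intercept": r.intercept,
                       "correlation": r.correlation}
                for name, r in zip(self.var_names, self.regressions)
            },
        }
        if self.coverage is not None:
            out["accuracy"] = {
                name: {"probs": c.probs.tolist(),
                       "coverage": c.coverage.tolist()}
                for name, c in zip(self.var_names, self.coverage)
            }
        return out


def validate_simulation(
    samples: pd.DataFrame,
    model: LMCModel,
    grid: GridSpec,
    n_train: int = 200,
    n_real: int = 100,
    seed: int = 0,
    n_lines: int = 1000,
    var_cols=DEFAULT_VAR_COLS,
) -> ValidationReport:
    """Condition on a random training subset, simulate at the held-out
    locations, and report regression and accuracy-plot diagnostics."""
    train, test = split_samples(samples, n_train, seed=seed)
    test_xy = test[["x", "y"]].to_numpy(dtype=float)
    stack = run_cosimulation(
        train, model, grid,
        n_real=n_real, seed=seed + 1, n_lines=n_lines,
        targets=test_xy, var_cols=var_cols,
    )
    truth = test[list(var_cols)].to_numpy(dtype=float)
    est = stack.etype_mean()
    regs = tuple(
        regression_validation(truth[:, v], est[:, v]) for v in range(2)
    )
    if n_real >= 2:
        cover = tuple(
            accuracy_plot(stack.values[:, :, v], truth[:, v]) for v in range(2)
        )
    else:
        import logging

        logging.getLogger(__name__).warning(
            "n_real=%d gives no usable ensemble; skipping accuracy plot", n_real
        )
        cover = None
    return ValidationReport(
        train_index=train.index.to_numpy(),
        test_index=test.index.to_numpy(),
        true_values=truth,
        estimates=est,
        regressions=regs,
        coverage=cover,
        var_names=tuple(var_cols),
    )
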