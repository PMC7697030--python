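"""Normal-scores transform (Gaussian anamorphosis) and its inverse.

Turning-bands simulation operates on standard Gaussian fields, while litter
densities are skewed, non-negative quantities.  The bridge is the empirical
normal-scores transform: the value of rank ``r`` among ``n`` is mapped to the
standard-normal quantile at plotting position ``(r - 0.5) / n``.  The paired
(raw value, score) arrays form an :class:`AnamorphosisTable` used to map
simulated Gaussian values back to densities.

Ties — frequent in count-derived densities — are broken by a deterministic,
seeded ordering, and the raw column of the table receives an infinitesimal
jitter so that both columns are strictly increasing and the mapping is
invertible.  The lower tail is anchored at zero (densities cannot be
negative); the upper tail extrapolates hyperbolically in probability and is
capped at ``upper_cap`` times the sample maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import DegenerateInputError, InvalidTableError

__all__ = ["AnamorphosisTable", "normal_scores", "back_transform"]


@dataclass(frozen=True)
class AnamorphosisTable:
    """Monotone raw-value <-> normal-score lookup.

    Parameters
    ----------
    raw, score
        Paired strictly increasing arrays (raw in items/m^2, score
        dimensionless standard-normal).
    lower_bound
        Value toward which scores below the table are driven (0 for
        densities).
    upper_cap
        Upper-tail extrapolation cap, as a multiple of the largest raw value.
    tail_exponent
        Exponent omega of the hyperbolic upper-tail model
        ``v = v_max * ((1 - p_max) / (1 - p)) ** (1 / omega)``.
    """

    raw: np.ndarray
    score: np.ndarray
    lower_bound: float = 0.0
    upper_cap: float = 1.5
    tail_exponent: float = 1.5

    def __post_init__(self):
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "score", np.asarray(self.score, dtype=float))
        self.validate()

    def validate(self):
        if self.raw.ndim != 1 or self.raw.shape != self.score.shape:
            raise InvalidTableError("raw and score must be 1-D arrays of equal length")
        if self.raw.size < 2:
            raise InvalidTableError("table needs at least two entries")
        if not (np.all(np.diff(self.raw) > 0) and np.all(np.diff(self.score) > 0)):
            raise InvalidTableError("table columns must be strictly increasing")
        if self.lower_bound > self.raw[0]:
            raise InvalidTableError("lower bound exceeds smallest tabulated value")

    def back_transform(self, scores) -> np.ndarray:
        return back_transform(scores, self)


def normal_scores(values, tie_seed: int = 0, upper_cap: float = 1.5,
                  tail_exponent: float = 1.5):
    """Transform data to standard-normal scores.

    Parameters
    ----------
    values
        At least two finite raw values.
    tie_seed
        Seed for the deterministic ordering of tied values.

    Returns
    -------
    (scores, table)
        ``scores`` aligned with the input order; ``table`` the invertible
        :class:`AnamorphosisTable` built from the (jittered) sample.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise DegenerateInputError("need at least two values")
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("values must be finite")
    span = float(np.ptp(v))
    if span == 0.0:
        raise DegenerateInputError("all values identical; normal scores undefined")

    n = v.size
    rng = np.random.default_rng(tie_seed)
    order = np.lexsort((rng.random(n), v))  # seeded tie-breaking
    scores_sorted = ndtri((np.arange(1, n + 1) - 0.5) / n)
    scores = np.empty(n)
    scores[order] = scores_sorted

    # strictly increasing raw column: micro-jitter, negligible vs. data scale
    raw_sorted = v[order] + np.arange(n) * (1e-9 * max(span, 1.0) / n)
    lower = 0.0 if raw_sorted[0] >= 0 else float(raw_sorted[0])
    table = AnamorphosisTable(
        raw=raw_sorted,
        score=scores_sorted,
        lower_bound=lower,
        upper_cap=upper_cap,
        tail_exponent=tail_exponent,
    )
    return scores, table


def back_transform(scores, table: AnamorphosisTable) -> np.ndarray:
    """Map Gaussian scores back to the raw scale through ``table``.

    Monotone linear interpolation within the table; linear decay clamped at
    ``table.lower_bound`` below it; hyperbolic extrapolation capped at
    ``table.upper_cap * max(raw)`` above it.
    """
    table.validate()
    z = np.asarray(scores, dtype=float)
    shape = z.shape
    z = np.atleast_1d(z).ravel()
    out = np.interp(z, table.score, table.raw)

    below = z < table.score[0]
    if np.any(below):
        slope = (table.raw[1] - table.raw[0]) / (table.score[1] - table.score[0])
        ext = table.raw[0] + slope * (z[below] - table.score[0])
        out[below] = np.maximum(table.lower_bound, ext)

    above = z > table.score[-1]
    if np.any(above):
        p_max = ndtr(table.score[-1])
        p = ndtr(z[above])
        v_max = table.raw[-1]
        with np.errstate(divide="ignore"):
            ratio = (1.0 - p_max) / np.maximum(1.0 - p, np.finfo(float).tiny)
        ext = v_max * ratio ** (1.0 / table.tail_exponent)
        out[above] = np.minimum(ext, table.upper_cap * v_max)

    return out.reshape(shape)
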