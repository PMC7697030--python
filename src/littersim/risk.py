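"""Risk indices, per-node hazard classification and exceedance mapping.

Two beach-condition indices are computed from litter item counts with the
conventional multiplier K = 20:

* Clean Coast Index, ``CCI = (total items / beach area) * K``, with the
  usual five cleanliness categories (Very Clean <= 2 up to Extremely Dirty
  > 20).
* Hazardous Items Index.  The published formula's typesetting is ambiguous
  about the grouping of the log term; this package adopts
  ``HII = (hazardous items / log10(total items)) / area * K``, which
  reproduces the reported order of magnitude, and exposes the alternative
  grouping through ``variant=``.  Categories I-V, with V ("most of the area
  is covered by hazardous litter") above 8.

Node-level classification uses the published half-open bins: cigarette butts
[0,1) Very Clean, [1,2) Clean, [2,6) Dirty, [6,inf) Very Dirty; sharp items
[0,1) low, [1,3) moderate, [3,inf) high risk of injury.  Exceedance maps
report, per node, the fraction of realizations at or above a threshold
(e.g. 3 sharp items/m^2 for the injury-risk map).

Item counts are densities times cell area, so on the 1 m grid counts and
densities coincide numerically.  Indices are computed per realization and
averaged, and can be evaluated globally or per sector of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosimulation import RealizationStack
from .exceptions import PartitionError

__all__ = [
    "IndexResult",
    "RiskSummary",
    "compute_cci",
    "compute_hii",
    "cci_category",
    "hii_category",
    "classify_butts",
    "classify_sharp",
    "BUTT_LABELS",
    "SHARP_LABELS",
    "exceedance_probability",
    "classify_stack",
    "indices_by_sector",
    "summarize_risk",
    "HII_VARIANTS",
]

K_DEFAULT = 20.0

BUTT_EDGES = (1.0, 2.0, 6.0)
BUTT_LABELS = ("Very Clean", "Clean", "Dirty", "Very Dirty")
SHARP_EDGES = (1.0, 3.0)
SHARP_LABELS = ("Low risk", "Moderate risk", "High risk")

HII_VARIANTS = ("hazard_over_log_total", "hazard_times_log_total")


@dataclass(frozen=True)
class IndexResult:
    value: float
    category: str


def cci_category(value: float) -> str:
    if value <= 2.0:
        return "Very Clean"
    if value <= 5.0:
        return "Clean"
    if value <= 10.0:
        return "Moderate"
    if value <= 20.0:
        return "Dirty"
    return "Extremely Dirty"


def hii_category(value: float) -> str:
    if value == 0.0:
        return "I"
    if value <= 1.0:
        return "II"
    if value <= 4.0:
        return "III"
    if value <= 8.0:
        return "IV"
    return "V"


def compute_cci(total_litter: float, area: float, K: float = K_DEFAULT) -> IndexResult:
    """Clean Coast Index: ``total / area * K`` with its cleanliness category."""
    if not area > 0:
        raise ValueError("area must be positive")
    if total_litter < 0:
        raise ValueError("total litter must be non-negative")
    value = total_litter / area * K
    return IndexResult(value=float(value), category=cci_category(value))


def compute_hii(
    hazardous_litter: float,
    total_litter: float,
    area: float,
    K: float = K_DEFAULT,
    variant: str = "hazard_over_log_total",
) -> IndexResult:
    """Hazardous Items Index with its hazard category.

    Default reading: ``(hazardous / log10(total)) / area * K``.  Requires
    ``total > 10`` so the base-10 logarithm exceeds one.
    """
    if not area > 0:
        raise ValueError("area must be positive")
    if hazardous_litter < 0:
        raise ValueError("hazardous litter must be non-negative")
    if hazardous_litter > total_litter:
        raise ValueError("hazardous litter cannot exceed total litter")
    if hazardous_litter == 0:
        return IndexResult(value=0.0, category="I")
    if not total_litter > 10:
        raise ValueError("total litter must exceed 10 items (log10 guard)")
    log_total = np.log10(total_litter)
    if variant == "hazard_over_log_total":
        value = hazardous_litter / log_total / area * K
    elif variant == "hazard_times_log_total":
        value = hazardous_litter * log_total / area * K
    else:
        raise ValueError(f"unknown HII variant {variant!r}; use one of {HII_VARIANTS}")
    return IndexResult(value=float(value), category=hii_category(value))


def _classify(density, edges, labels, what):
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"negative {what} density")
    codes = np.digitize(d, edges, right=False)
    return codes


def classify_butts(density):
    """Cigarette-butt contamination class codes (0..3, see ``BUTT_LABELS``)."""
    return _classify(density, BUTT_EDGES, BUTT_LABELS, "cigarette-butt")


def classify_sharp(density):
    """Sharp-item injury-risk class codes (0..2, see ``SHARP_LABELS``)."""
    return _classify(density, SHARP_EDGES, SHARP_LABELS, "sharp-item")


def exceedance_probability(
    stack: RealizationStack, variable, threshold: float
) -> np.ndarray:
    """Per-node fraction of realizations with value >= threshold."""
    if stack.n_real < 1:
        raise ValueError("stack has no realizations")
    v = stack.variable_index(variable)
    return (stack.values[:, :, v] >= threshold).mean(axis=0)


def classify_stack(surface, classifier=classify_butts, labels=None):
    """Node-wise classification of a surface (default: an E-type mean column).

    Accepts a flat node vector or a :class:`RealizationStack` (whose E-type
    mean of variable 0 is then classified).  Returns ``(codes, frequencies)``
    where the frequency table sums to the node count.
    """
    if isinstance(surface, RealizationStack):
        surface = surface.etype_mean()[:, 0]
    codes = classifier(surface)
    if labels is None:
        labels = BUTT_LABELS if classifier is classify_butts else (
            SHARP_LABELS if classifier is classify_sharp else None
        )
    counts = np.bincount(codes, minlength=len(labels) if labels else codes.max() + 1)
    index = list(labels) if labels else list(range(len(counts)))
    freq = pd.Series(counts[: len(index)], index=index, name="nodes")
    return codes, freq


def _sector_masks(stack, sectors):
    n = stack.n_points
    try:
        arr = np.asarray(sectors)
    except ValueError:
        arr = None
    if (
        arr is not None
        and arr.ndim == 1
        and arr.shape[0] == n
        and np.issubdtype(arr.dtype, np.integer)
    ):
        if arr.min() < 0:
            raise PartitionError("sector labels must be non-negative for all nodes")
        return [arr == s for s in np.unique(arr)]
    masks = []
    covered = np.zeros(n, dtype=bool)
    for idx in sectors:
        m = np.zeros(n, dtype=bool)
        m[np.asarray(idx, dtype=int)] = True
        if np.any(covered & m):
            raise PartitionError("sectors overlap")
        covered |= m
        masks.append(m)
    if not covered.all():
        raise PartitionError("sectors do not cover every grid node")
    return masks


def indices_by_sector(
    stack: RealizationStack,
    sectors,
    K: float = K_DEFAULT,
    hazard_variable=1,
    variant: str = "hazard_over_log_total",
) -> pd.DataFrame:
    """Realization-averaged CCI/HII per sector of a grid partition.

    ``sectors`` is either an integer label per node or a list of node-index
    sets; overlaps or gaps raise :class:`PartitionError`.  Sector item counts
    are densities times cell area summed over the sector's nodes.
    """
    if stack.grid is None:
        raise ValueError("sector indices need a grid-based stack")
    masks = _sector_masks(stack, sectors)
    cell_area = stack.grid.cell_area
    hv = stack.variable_index(hazard_variable)
    rows = []
    for i, m in enumerate(masks):
        area = m.sum() * cell_area
        totals = stack.values[:, m, :].sum(axis=(1, 2)) * cell_area  # per real
        hazard = stack.values[:, m, hv].sum(axis=1) * cell_area
        cci = totals / area * K
        hii = np.array(
            [
                compute_hii(h, t, area, K, variant=variant).value
                for h, t in zip(hazard, totals)
            ]
        )
        rows.append(
            {
                "sector": i,
                "area_m2": area,
                "cci_mean": cci.mean(),
                "cci_category": cci_category(cci.mean()),
                "hii_mean": hii.mean(),
                "hii_category": hii_category(hii.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("sector")


@dataclass
class RiskSummary:
    """Global indices, per-node class maps and the injury-risk exceedance map."""

    K: float
    area: float
    hii: IndexResult
    cci: IndexResult
    hii_per_realization: np.ndarray
    cci_per_realization: np.ndarray
    butt_class_map: np.ndarray
    butt_class_freq: pd.Series
    sharp_class_map: np.ndarray
    sharp_class_freq: pd.Series
    exceedance: np.ndarray
    exceedance_threshold: float
    hii_variant: str

    @property
    def hii_sd(self) -> float:
        return float(self.hii_per_realization.std(ddof=1)) if len(
            self.hii_per_realization
        ) > 1 else 0.0

    @property
    def cci_sd(self) -> float:
        return float(self.cci_per_realization.std(ddof=1)) if len(
            self.cci_per_realization
        ) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "area_m2": self.area,
            "hii": {"value": self.hii.value, "category": self.hii.category,
                    "sd_over_realizations": self.hii_sd,
                    "variant": self.hii_variant},
            "cci": {"value": self.cci.value, "category": self.cci.category,
                    "sd_over_realizations": self.cci_sd},
            "butt_class_frequencies": self.butt_class_freq.to_dict(),
            "sharp_class_frequencies": self.sharp_class_freq.to_dict(),
            "exceedance_threshold_per_m2": self.exceedance_threshold,
            "exceedance_mean_probability": float(self.exceedance.mean()),
        }


def summarize_risk(
    stack: RealizationStack,
    K: float = K_DEFAULT,
    area: float | None = None,
    hazard_variable=1,
    sharp_threshold: float = 3.0,
    hii_variant: str = "hazard_over_log_total",
) -> RiskSummary:
    """Full risk post-processing of a realization stack.

    HII and CCI are computed per realization from total item counts and then
    averaged; class maps classify the E-type mean surfaces; the exceedance
    map uses the "at or above threshold" rule.
    """
    if area is None:
        if stack.grid is None:
            raise ValueError("area must be given for non-grid stacks")
        area = stack.grid.area
    cell_area = stack.grid.cell_area if stack.grid is not None else 1.0
    hv = stack.variable_index(hazard_variable)

    totals = stack.values.sum(axis=(1, 2)) * cell_area
    hazard = stack.values[:, :, hv].sum(axis=1) * cell_area
    cci_r = totals / area * K
    hii_r = np.array(
        [
            compute_hii(h, t, area, K, variant=hii_variant).value
            for h, t in zip(hazard, totals)
        ]
    )
    etype = stack.etype_mean()
    butt_codes, butt_freq = classify_stack(etype[:, 1 - hv], classify_butts)
    sharp_codes, sharp_freq = classify_stack(etype[:, hv], classify_sharp)
    exc = exceedance_probability(stack, hv, sharp_threshold)

    hii_mean = float(hii_r.mean())
    cci_mean = float(cci_r.mean())
    return RiskSummary(
        K=K,
        area=float(area),
        hii=IndexResult(hii_mean, hii_category(hii_mean)),
        cci=IndexResult(cci_mean, cci_category(cci_mean)),
        hii_per_realization=hii_r,
        cci_per_realization=cci_r,
        butt_class_map=butt_codes,
        butt_class_freq=butt_freq,
        sharp_class_map=sharp_codes,
        sharp_class_freq=sharp_freq,
        exceedance=exc,
        exceedance_threshold=float(sharp_threshold),
        hii_variant=hii_variant,
    )
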