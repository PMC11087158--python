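"""Dose-volume-histogram statistics and gold-vs-auto dose deltas.

``D1%``, ``D5%`` and ``D50%`` are read off the discrete cumulative DVH as
the minimum dose among the hottest x% of structure voxels: sort in-mask
doses descending and take the value at which the cumulative hot volume
first reaches x% of the total.  No sub-voxel DVH interpolation is applied.
``Dmax`` is the single hottest voxel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_grid import DoseGrid, StructureMask, require_compatible

__all__ = [
    "MetricKind",
    "OARTier",
    "OARSpec",
    "DoseDelta",
    "DVHCurve",
    "MetricUnavailableError",
    "dose_metric",
    "dose_delta",
    "dvh_curve",
]


class MetricKind(str, enum.Enum):
    D1 = "D1%"
    D5 = "D5%"
    D50 = "D50%"
    DMAX = "Dmax"

    @property
    def percent(self) -> Optional[float]:
        return {MetricKind.D1: 1.0, MetricKind.D5: 5.0, MetricKind.D50: 50.0}.get(self)


class OARTier(str, enum.Enum):
    """Routing tier for the clinical-significance classification."""

    FIRST_ORDER = "first_order"
    SECOND_ORDER_MEAN_LIKE = "second_order_mean_like"
    SECOND_ORDER_OTHER = "second_order_other"


@dataclass(frozen=True)
class OARSpec:
    """One organ-at-risk: tolerance dose, DVH metric and significance tier."""

    name: str
    tolerance_cGy: float
    metric: MetricKind
    tier: OARTier

    def __post_init__(self) -> None:
        if self.tolerance_cGy <= 0:
            raise ValueError("tolerance must be positive")


class MetricUnavailableError(ValueError):
    """Requested a dose metric on an absent or empty mask."""


def dose_metric(dose: DoseGrid, mask: StructureMask, metric: MetricKind) -> float:
    """Dose metric (cGy) of ``dose`` restricted to ``mask``.

    Raises :class:`MetricUnavailableError` on an absent mask — a failed
    segmentation never silently scores 0 cGy.
    """
    require_compatible(dose, mask, "dose and mask")
    if not mask.present:
        raise MetricUnavailableError(f"mask is absent (status={mask.status!r})")
    doses = dose.values[mask.values]
    if doses.size == 0:
        raise MetricUnavailableError("mask occupies no voxels")
    if metric is MetricKind.DMAX:
        return float(doses.max())
    # hottest ceil(x% * n) voxels; metric = the coolest of them
    n = doses.size
    k = max(1, math.ceil(n * metric.percent / 100.0))
    # partition is O(n) and traversal-order independent
    hottest = np.partition(doses, n - k)[n - k:]
    return float(hottest.min())


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each edge."""

    dose_edges_cGy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        if self.dose_edges_cGy.shape != self.volume_fraction.shape:
            raise ValueError("edges and fractions must align")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def dvh_curve(dose: DoseGrid, mask: StructureMask, n_bins: int = 200) -> DVHCurve:
    """Utility cumulative DVH on evenly spaced dose edges from 0 to Dmax."""
    require_compatible(dose, mask, "dose and mask")
    if not mask.present:
        raise MetricUnavailableError(f"mask is absent (status={mask.status!r})")
    doses = dose.values[mask.values]
    edges = np.linspace(0.0, float(doses.max()), n_bins)
    frac = np.array([(doses >= e).mean() for e in edges])
    return DVHCurve(edges, frac)


@dataclass
class DoseDelta:
    """Auto-minus-gold dose difference for one case/organ/model/metric.

    ``percent`` is relative to the gold metric dose by default (see
    ``normalization``); it is None when undefined (gold dose 0, or a
    prescription-relative request without a prescription).  ``status`` is
    one of ``ok``, ``failed``, ``eroded-away``, ``undefined-percent``.
    """

    gold_cGy: float
    auto_cGy: Optional[float]
    delta_cGy: Optional[float]
    percent: Optional[float]
    status: str
    normalization: str = "gold"

    @property
    def abs_percent(self) -> Optional[float]:
        return None if self.percent is None else abs(self.percent)

    @property
    def available(self) -> bool:
        return self.delta_cGy is not None


def dose_delta(
    dose: DoseGrid,
    gold: StructureMask,
    auto: StructureMask,
    metric: MetricKind,
    normalization: str = "gold",
    prescription_cGy: Optional[float] = None,
) -> DoseDelta:
    """Compare auto vs gold dose metrics on one dose grid.

    ``normalization`` selects the percent denominator: ``"gold"`` (default)
    divides by the gold metric dose, ``"prescription"`` by the protocol
    prescription.  A failed auto segmentation yields an unavailable delta
    carrying the failure status (it feeds the N* tally downstream, never an
    average).
    """
    if normalization not in ("gold", "prescription"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "prescription" and not prescription_cGy:
        raise ValueError("prescription normalization requires prescription_cGy")
    gold_val = dose_metric(dose, gold, metric)
    if not auto.present:
        return DoseDelta(
            gold_cGy=gold_val,
            auto_cGy=None,
            delta_cGy=None,
            percent=None,
            status=auto.status if auto.status != "ok" else "failed",
            normalization=normalization,
        )
    auto_val = dose_metric(dose, auto, metric)
    delta = auto_val - gold_val
    if normalization == "gold":
        denom = gold_val
    else:
        denom = float(prescription_cGy)
    if denom == 0.0:
        return DoseDelta(gold_val, auto_val, delta, None, "undefined-percent", normalization)
    return DoseDelta(gold_val, auto_val, delta, 100.0 * delta / denom, "ok", normalization)
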