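"""Headroom-based clinical-significance thresholds and per-case flagging.

The threshold for an organ under one protocol is half of the cohort's dose
headroom to the tolerance, computed from gold-standard contour doses only:
the *average* headroom for first-order organs (hard planning limits with
near-maximal metrics) and the *worst-case* (minimum) headroom for
second-order organs with mean-dose-like metrics.  Organs in the remaining
second-order tier are excluded from threshold classification entirely, as
are any organ/protocol groups whose computed threshold is non-positive
(treated beyond the optimal tolerance).  A case is flagged when its dose
change exceeds the threshold in either direction, strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .dvh import DoseDelta, OARSpec, OARTier

__all__ = [
    "MODE_AVERAGE",
    "MODE_WORST_CASE",
    "SignificanceThreshold",
    "SignificanceReport",
    "headroom",
    "compute_threshold",
    "classify_case",
    "tier_route",
    "build_report",
]

MODE_AVERAGE = "average_headroom"
MODE_WORST_CASE = "worst_case_headroom"


def headroom(gold_dose_cGy: float, tolerance_cGy: float) -> float:
    """Spare dose margin: tolerance minus gold-contour dose (may be negative)."""
    if tolerance_cGy <= 0:
        raise ValueError("tolerance must be positive")
    return tolerance_cGy - gold_dose_cGy


@dataclass(frozen=True)
class SignificanceThreshold:
    organ: str
    protocol: str
    mode: str
    threshold_cGy: Optional[float]
    n_cases_used: int
    excluded: bool = False
    excluded_reason: Optional[str] = None


def compute_threshold(
    gold_doses_cGy: Sequence[float],
    tolerance_cGy: float,
    mode: str,
    organ: str = "",
    protocol: str = "",
) -> SignificanceThreshold:
    """Half the (average | worst-case) headroom over one organ/protocol group.

    A non-positive result means the organ was treated past its tolerance in
    at least the relevant sense; the organ/protocol is then excluded with
    reason ``negative headroom``.
    """
    if mode not in (MODE_AVERAGE, MODE_WORST_CASE):
        raise ValueError(f"unknown mode {mode!r}")
    doses = [float(d) for d in gold_doses_cGy]
    if not doses:
        raise ValueError("need at least one gold dose")
    rooms = [headroom(d, tolerance_cGy) for d in doses]
    agg = float(np.mean(rooms)) if mode == MODE_AVERAGE else float(np.min(rooms))
    thr = 0.5 * agg
    if thr <= 0:
        return SignificanceThreshold(
            organ, protocol, mode, None, len(doses), excluded=True,
            excluded_reason="negative headroom",
        )
    return SignificanceThreshold(organ, protocol, mode, thr, len(doses))


def tier_route(oar: OARSpec) -> Optional[str]:
    """Map an organ tier to its threshold mode; None means tier-excluded."""
    if oar.tier is OARTier.FIRST_ORDER:
        return MODE_AVERAGE
    if oar.tier is OARTier.SECOND_ORDER_MEAN_LIKE:
        return MODE_WORST_CASE
    if oar.tier is OARTier.SECOND_ORDER_OTHER:
        return None
    raise ValueError(f"unknown tier {oar.tier!r}")


def classify_case(delta: DoseDelta, threshold: SignificanceThreshold) -> bool:
    """Flag iff |delta| strictly exceeds the threshold (either direction)."""
    if threshold.excluded:
        raise ValueError(
            f"threshold for {threshold.organ}/{threshold.protocol} is excluded "
            f"({threshold.excluded_reason})"
        )
    if not delta.available:
        raise ValueError("delta unavailable (failed segmentation)")
    return abs(delta.delta_cGy) > threshold.threshold_cGy


@dataclass
class SignificanceReport:
    """Flagged cases for one organ x protocol x model."""

    organ: str
    protocol: str
    model: str
    threshold: SignificanceThreshold
    flagged_case_ids: List[str] = field(default_factory=list)
    n_evaluated: int = 0

    mean_abs_flagged_delta_cGy: Optional[float] = None
    mean_signed_flagged_delta_cGy: Optional[float] = None

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_case_ids)


def build_report(
    organ: str,
    protocol: str,
    model: str,
    threshold: SignificanceThreshold,
    case_ids: Sequence[str],
    deltas: Sequence[DoseDelta],
) -> SignificanceReport:
    """Classify every available delta against one threshold.

    Failed-segmentation deltas are skipped (they are tallied as failures in
    the cohort table, not as significant cases).  The mean deltas are over
    flagged cases only; the signed mean distinguishes systematic dose
    reductions from increases.
    """
    report = SignificanceReport(organ, protocol, model, threshold)
    if threshold.excluded:
        return report
    flagged_deltas = []
    for cid, delta in zip(case_ids, deltas):
        if not delta.available:
            continue
        report.n_evaluated += 1
        if classify_case(delta, threshold):
            report.flagged_case_ids.append(cid)
            flagged_deltas.append(delta.delta_cGy)
    if flagged_deltas:
        report.mean_abs_flagged_delta_cGy = float(np.mean(np.abs(flagged_deltas)))
        report.mean_signed_flagged_delta_cGy = float(np.mean(flagged_deltas))
    return report
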