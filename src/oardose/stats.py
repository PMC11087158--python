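"""Cohort-level aggregation and inference.

Three consumers of the per-case tables:

* absolute-average percent dose-change tables with successful-segmentation
  counts (N*),
* paired two-tailed t-tests between models with Bonferroni-corrected
  alpha,
* Pearson correlations between geometric agreement and absolute percent
  dose change, pooled across organs and cases within one model.

Pairwise-complete deletion throughout: a failed segmentation drops that
(case, organ) pair from the statistic in question, never the whole case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortTableRow",
    "PairedTestResult",
    "CorrelationResult",
    "aggregate",
    "paired_model_test",
    "correlate",
]


@dataclass(frozen=True)
class CohortTableRow:
    model: str
    organ: str
    mean_abs_percent: Optional[float]
    n_successful: int          # N*: cases with a usable auto segmentation
    n_failed: int
    n_undefined_percent: int   # successful but percent undefined (gold dose 0)


def aggregate(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per model x organ: mean |percent| change, N* and failure tally.

    ``deltas`` needs columns ``model, organ, case_id, status, percent``.
    Rows with status ``failed`` or ``eroded-away`` count as failures;
    ``undefined-percent`` rows are successful segmentations excluded from
    the percent mean and tallied separately.
    """
    required = {"model", "organ", "case_id", "status", "percent"}
    missing = required - set(deltas.columns)
    if missing:
        raise ValueError(f"delta table missing columns: {sorted(missing)}")
    rows = []
    for (model, organ), grp in deltas.groupby(["model", "organ"], sort=True):
        failed = grp["status"].isin(["failed", "eroded-away"])
        undefined = grp["status"] == "undefined-percent"
        ok = grp["status"] == "ok"
        pct = grp.loc[ok, "percent"].astype(float).abs()
        rows.append(
            {
                "model": model,
                "organ": organ,
                "mean_abs_percent": float(pct.mean()) if len(pct) else np.nan,
                "n_successful": int((~failed).sum()),
                "n_failed": int(failed.sum()),
                "n_undefined_percent": int(undefined.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    model_a: str
    model_b: str
    organ: str
    t: Optional[float]
    p: Optional[float]
    n_pairs: int
    corrected_alpha: float
    significant: Optional[bool]
    effect_size_median_percent: Optional[float]
    status: str = "ok"  # ok | too-few-pairs | zero-variance


def paired_model_test(
    a: Sequence[float],
    b: Sequence[float],
    family_size: int,
    alpha: float = 0.05,
    model_a: str = "a",
    model_b: str = "b",
    organ: str = "",
    percent_a: Optional[Sequence[float]] = None,
    percent_b: Optional[Sequence[float]] = None,
) -> PairedTestResult:
    """Classical paired two-tailed t-test on per-case metric doses.

    ``a`` and ``b`` must already be restricted to cases where both models
    succeeded.  Significance uses ``alpha / family_size`` exactly.  The
    effect size, when percent changes are supplied, is the difference of
    median percent dosimetric change between the two models.  Degenerate
    inputs (n < 2, zero-variance differences) yield an unavailable test,
    never a fabricated p-value.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    corrected = alpha / family_size
    effect = None
    if percent_a is not None and percent_b is not None:
        effect = float(np.median(percent_a) - np.median(percent_b))
    n = a.size
    if n < 2:
        return PairedTestResult(
            model_a, model_b, organ, None, None, n, corrected, None, effect,
            status="too-few-pairs",
        )
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTestResult(
            model_a, model_b, organ, None, None, n, corrected, None, effect,
            status="zero-variance",
        )
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult(
        model_a, model_b, organ, float(t), float(p), n, corrected,
        significant=bool(p <= corrected), effect_size_median_percent=effect,
    )


@dataclass(frozen=True)
class CorrelationResult:
    model: str
    geometric_metric: str
    r: Optional[float]
    n: int
    p: Optional[float]
    status: str = "ok"  # ok | too-few-points | zero-variance


def correlate(
    geometric: Sequence[float],
    abs_percent: Sequence[float],
    model: str = "",
    metric_name: str = "",
) -> CorrelationResult:
    """Pearson r between a geometric metric and |percent| dose change.

    Points are (geometric value, absolute percent change) pairs pooled over
    organs and cases within one model; callers drop failed pairs first.
    With n < 3 the coefficient is reported but p is unavailable; zero
    variance in either coordinate makes r undefined.
    """
    x = np.asarray(geometric, dtype=float)
    y = np.asarray(abs_percent, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate sequences must have equal length")
    n = x.size
    if n < 2:
        return CorrelationResult(model, metric_name, None, n, None, status="too-few-points")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        return CorrelationResult(model, metric_name, None, n, None, status="zero-variance")
    if n < 3:
        # r defined, p needs >= 3 points for the t transform
        r = float(np.corrcoef(x, y)[0, 1])
        return CorrelationResult(model, metric_name, r, n, None, status="too-few-points")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(model, metric_name, float(r), n, float(p))
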