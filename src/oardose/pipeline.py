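"""End-to-end evaluation pipeline: per-case metrics through cohort stats.

Everything is deterministic given (cohort, config); report writers sort
rows and emit stable formatting so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core_grid import DoseGrid, ProtocolSpec, StructureMask
from .dvh import DoseDelta, dose_delta, dose_metric
from .geometry import evaluate_geometry
from .manifest import LoadedCohort
from .significance import (
    MODE_WORST_CASE,
    SignificanceReport,
    SignificanceThreshold,
    build_report,
    compute_threshold,
    tier_route,
)
from .stats import aggregate, correlate, paired_model_test
from .synthetic import Cohort

__all__ = ["ReportBundle", "run_pipeline", "write_reports"]

GEOMETRIC_METRICS = ("dsc", "sensitivity", "mean_dta_mm")


@dataclass
class ReportBundle:
    metrics: pd.DataFrame        # case_id, model, organ, metric, gold/auto/delta/percent/status
    geometry: pd.DataFrame       # case_id, model, organ, dsc, sensitivity, mean_dta_mm, status
    cohort_table: pd.DataFrame   # model, organ, mean_abs_percent, N*, failures
    thresholds: pd.DataFrame     # organ, protocol, mode, threshold_cGy, excluded
    significance: pd.DataFrame   # organ, protocol, model, n_flagged, flagged ids, mean deltas
    paired_tests: pd.DataFrame
    correlations: pd.DataFrame
    run_log: dict
    deltas_by_key: Dict[Tuple[str, str, str], DoseDelta] = field(default_factory=dict)


def _iter_cases(cohort: Union[Cohort, LoadedCohort]):
    """Yield (case_id, protocol, dose, gold, auto) for either cohort kind."""
    if isinstance(cohort, Cohort):
        for case in cohort.cases:
            yield case.case_id, case.protocol, case.dose, case.gold, case.auto
    else:
        for rec in cohort.cases:
            dose = rec.load_dose()
            gold = rec.load_gold()
            auto = {model: rec.load_auto(model) for model in rec.auto_status}
            yield rec.case_id, rec.protocol, dose, gold, auto


def run_pipeline(cohort: Union[Cohort, LoadedCohort], config: RunConfig) -> ReportBundle:
    oar_specs = config.oar_by_name()
    warnings: List[dict] = []

    metric_rows: List[dict] = []
    geom_rows: List[dict] = []
    gold_doses: Dict[Tuple[str, str], List[Tuple[str, float]]] = {}  # (organ, proto) -> [(case, dose)]
    deltas_by_key: Dict[Tuple[str, str, str], DoseDelta] = {}
    case_protocol: Dict[str, str] = {}
    models_seen: set = set()

    for case_id, protocol, dose, gold, auto in _iter_cases(cohort):
        case_protocol[case_id] = protocol.name
        for organ, gmask in sorted(gold.items()):
            spec = oar_specs.get(organ)
            if spec is None:
                warnings.append({"code": "unknown-organ", "case": case_id, "organ": organ})
                continue
            gval = dose_metric(dose, gmask, spec.metric)
            gold_doses.setdefault((organ, protocol.name), []).append((case_id, gval))
            for model in sorted(auto):
                models_seen.add(model)
                amask = auto[model].get(organ)
                if amask is None:
                    warnings.append(
                        {"code": "missing-auto", "case": case_id, "organ": organ, "model": model}
                    )
                    continue
                dd = dose_delta(
                    dose, gmask, amask, spec.metric,
                    normalization=config.percent_normalization,
                    prescription_cGy=protocol.prescription_cGy,
                )
                deltas_by_key[(case_id, model, organ)] = dd
                if dd.status == "undefined-percent":
                    warnings.append(
                        {"code": "undefined-percent", "case": case_id,
                         "organ": organ, "model": model}
                    )
                metric_rows.append(
                    {
                        "case_id": case_id, "model": model, "organ": organ,
                        "metric": spec.metric.value,
                        "gold_cGy": dd.gold_cGy, "auto_cGy": dd.auto_cGy,
                        "delta_cGy": dd.delta_cGy, "percent": dd.percent,
                        "status": dd.status,
                    }
                )
                gm = evaluate_geometry(gmask, amask)
                geom_rows.append(
                    {
                        "case_id": case_id, "model": model, "organ": organ,
                        "dsc": gm.dsc, "sensitivity": gm.sensitivity,
                        "mean_dta_mm": gm.mean_dta_mm, "status": gm.status,
                    }
                )

    metrics = pd.DataFrame(metric_rows).sort_values(
        ["case_id", "model", "organ"], ignore_index=True
    )
    geometry = pd.DataFrame(geom_rows).sort_values(
        ["case_id", "model", "organ"], ignore_index=True
    )
    models = sorted(models_seen)

    cohort_table = aggregate(metrics) if len(metrics) else pd.DataFrame()

    # --- thresholds and per-case flagging -----------------------------------
    thr_rows: List[dict] = []
    sig_rows: List[dict] = []
    for (organ, proto), case_dose_pairs in sorted(gold_doses.items()):
        spec = oar_specs[organ]
        mode = tier_route(spec)
        if mode is None:
            thr_rows.append(
                {"organ": organ, "protocol": proto, "mode": "", "threshold_cGy": np.nan,
                 "n_cases_used": len(case_dose_pairs), "excluded": True,
                 "excluded_reason": "tier-excluded"}
            )
            continue
        thr = compute_threshold(
            [d for _, d in case_dose_pairs], spec.tolerance_cGy, mode,
            organ=organ, protocol=proto,
        )
        if (not thr.excluded and config.second_order_half_threshold
                and mode == MODE_WORST_CASE):
            thr = dataclasses.replace(thr, threshold_cGy=thr.threshold_cGy / 2.0)
        if thr.excluded:
            warnings.append({"code": "negative-headroom", "organ": organ, "protocol": proto})
        thr_rows.append(
            {"organ": organ, "protocol": proto, "mode": mode,
             "threshold_cGy": thr.threshold_cGy if not thr.excluded else np.nan,
             "n_cases_used": thr.n_cases_used, "excluded": thr.excluded,
             "excluded_reason": thr.excluded_reason or ""}
        )
        for model in models:
            case_ids = [cid for cid, _ in case_dose_pairs]
            deltas = [
                deltas_by_key.get((cid, model, organ),
                                  DoseDelta(0.0, None, None, None, "failed"))
                for cid in case_ids
            ]
            rep = build_report(organ, proto, model, thr, case_ids, deltas)
            sig_rows.append(
                {
                    "organ": organ, "protocol": proto, "model": model,
                    "mode": mode,
                    "threshold_cGy": thr.threshold_cGy if not thr.excluded else np.nan,
                    "excluded": thr.excluded,
                    "excluded_reason": thr.excluded_reason or "",
                    "n_evaluated": rep.n_evaluated,
                    "n_flagged": rep.n_flagged,
                    "flagged_case_ids": ";".join(rep.flagged_case_ids),
                    "mean_abs_flagged_delta_cGy": rep.mean_abs_flagged_delta_cGy,
                    "mean_signed_flagged_delta_cGy": rep.mean_signed_flagged_delta_cGy,
                }
            )

    thresholds = pd.DataFrame(thr_rows)
    significance = pd.DataFrame(sig_rows)

    # --- paired model comparisons -------------------------------------------
    families: Dict[str, List[str]] = {}
    fam_of = config.model_families or {m: "all" for m in models}
    for m in models:
        families.setdefault(fam_of.get(m, "all"), []).append(m)
    test_rows: List[dict] = []
    organs = sorted({organ for (_, _, organ) in deltas_by_key})
    for fam_label, fam_models in sorted(families.items()):
        pairs = list(itertools.combinations(sorted(fam_models), 2))
        family_size = max(1, len(pairs))
        for ma, mb in pairs:
            for organ in organs:
                common = []
                for cid in sorted(case_protocol):
                    da = deltas_by_key.get((cid, ma, organ))
                    db = deltas_by_key.get((cid, mb, organ))
                    if da is not None and db is not None and da.available and db.available:
                        common.append((da, db))
                res = paired_model_test(
                    [d.auto_cGy for d, _ in common],
                    [d.auto_cGy for _, d in common],
                    family_size=family_size,
                    alpha=config.alpha,
                    model_a=ma, model_b=mb, organ=organ,
                    percent_a=[d.percent for d, _ in common
                               if d.percent is not None] or None,
                    percent_b=[d.percent for _, d in common
                               if d.percent is not None] or None,
                )
                if res.status != "ok":
                    warnings.append(
                        {"code": f"test-{res.status}", "organ": organ,
                         "models": f"{ma}|{mb}"}
                    )
                test_rows.append(
                    {
                        "family": fam_label, "model_a": ma, "model_b": mb,
                        "organ": organ, "t": res.t, "p": res.p,
                        "n_pairs": res.n_pairs,
                        "corrected_alpha": res.corrected_alpha,
                        "significant": res.significant,
                        "effect_size_median_percent": res.effect_size_median_percent,
                        "status": res.status,
                    }
                )
    paired_tests = pd.DataFrame(test_rows)

    # --- geometric-dosimetric correlations ----------------------------------
    corr_rows: List[dict] = []
    merged = metrics.merge(geometry, on=["case_id", "model", "organ"], suffixes=("", "_geom"))
    for model in models:
        sub = merged[(merged["model"] == model) & (merged["status"] == "ok")]
        for gname in GEOMETRIC_METRICS:
            ok = sub.dropna(subset=[gname, "percent"])
            res = correlate(
                ok[gname].to_numpy(float),
                ok["percent"].abs().to_numpy(float),
                model=model, metric_name=gname,
            )
            if res.status != "ok":
                warnings.append(
                    {"code": f"correlation-{res.status}", "model": model, "metric": gname}
                )
            corr_rows.append(
                {
                    "model": model, "geometric_metric": gname,
                    "r": res.r, "n": res.n, "p": res.p, "status": res.status,
                }
            )
    correlations = pd.DataFrame(corr_rows)

    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_fingerprint": config.fingerprint(),
        "n_cases": len(case_protocol),
        "models": models,
        "warnings": warnings,
    }
    return ReportBundle(
        metrics=metrics, geometry=geometry, cohort_table=cohort_table,
        thresholds=thresholds, significance=significance,
        paired_tests=paired_tests, correlations=correlations,
        run_log=run_log, deltas_by_key=deltas_by_key,
    )


def _stable_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> Dict[str, Path]:
    """Write every table as CSV plus the machine-readable run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("metrics", "geometry", "cohort_table", "thresholds",
                 "significance", "paired_tests", "correlations"):
        p = out_dir / f"{name}.csv"
        _stable_csv(getattr(bundle, name), p)
        paths[name] = p
    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(bundle.run_log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["run_log"] = log_path
    return paths
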