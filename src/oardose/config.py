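"""Run configuration: OAR tolerance table, protocols and analysis options.

The default tolerance table is the glioma radical-primary VMAT constraint
set (tolerances in cGy): brainstem 5400 D5%, lenses 600 D1%, optic chiasm
5400 D1%, optic nerves 5400 D1%, orbits 4500 D1%, lacrimal glands 3000
D1%, pituitary 4500 Dmax, cochlea 4500 D50%; bilateral organs are listed
per side.  Tier assignment drives the clinical-significance routing:
brainstem, orbits, optic chiasm and optic nerves are first-order; cochlea
is second-order mean-like; lenses, lacrimal glands and pituitary are
second-order other (descriptive comparison only).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import yaml

from .core_grid import ProtocolSpec
from .dvh import MetricKind, OARSpec, OARTier

__all__ = ["RunConfig", "default_oar_table", "default_protocols", "load_config"]


def default_oar_table() -> Tuple[OARSpec, ...]:
    first = OARTier.FIRST_ORDER
    mean_like = OARTier.SECOND_ORDER_MEAN_LIKE
    other = OARTier.SECOND_ORDER_OTHER
    return (
        OARSpec("brainstem", 5400.0, MetricKind.D5, first),
        OARSpec("optic_chiasm", 5400.0, MetricKind.D1, first),
        OARSpec("optic_nerve_l", 5400.0, MetricKind.D1, first),
        OARSpec("optic_nerve_r", 5400.0, MetricKind.D1, first),
        OARSpec("orbit_l", 4500.0, MetricKind.D1, first),
        OARSpec("orbit_r", 4500.0, MetricKind.D1, first),
        OARSpec("cochlea_l", 4500.0, MetricKind.D50, mean_like),
        OARSpec("cochlea_r", 4500.0, MetricKind.D50, mean_like),
        OARSpec("lens_l", 600.0, MetricKind.D1, other),
        OARSpec("lens_r", 600.0, MetricKind.D1, other),
        OARSpec("lacrimal_l", 3000.0, MetricKind.D1, other),
        OARSpec("lacrimal_r", 3000.0, MetricKind.D1, other),
        OARSpec("pituitary", 4500.0, MetricKind.DMAX, other),
    )


def default_protocols() -> Tuple[ProtocolSpec, ...]:
    return (ProtocolSpec("A", 6000.0, 30), ProtocolSpec("B", 5400.0, 30))


@dataclass
class RunConfig:
    """All threshold-relevant analysis settings in one fingerprintable place."""

    oars: Tuple[OARSpec, ...] = field(default_factory=default_oar_table)
    protocols: Tuple[ProtocolSpec, ...] = field(default_factory=default_protocols)
    percent_normalization: str = "gold"  # gold | prescription
    alpha: float = 0.05
    # model name -> family label; pairwise tests run within a family and
    # family_size = number of pairs in it.  None = all models one family.
    model_families: Optional[Dict[str, str]] = None
    # resolve the ambiguous second-order rule as |delta| > T (False) or
    # |delta| > T/2 (True)
    second_order_half_threshold: bool = False
    seed: int = 0

    def oar_by_name(self) -> Dict[str, OARSpec]:
        return {o.name: o for o in self.oars}

    def protocol_by_name(self) -> Dict[str, ProtocolSpec]:
        return {p.name: p for p in self.protocols}

    def to_dict(self) -> dict:
        return {
            "oars": [
                {
                    "name": o.name,
                    "tolerance_cGy": o.tolerance_cGy,
                    "metric": o.metric.value,
                    "tier": o.tier.value,
                }
                for o in self.oars
            ],
            "protocols": [
                {"name": p.name, "prescription_cGy": p.prescription_cGy, "fractions": p.fractions}
                for p in self.protocols
            ],
            "percent_normalization": self.percent_normalization,
            "alpha": self.alpha,
            "model_families": self.model_families,
            "second_order_half_threshold": self.second_order_half_threshold,
            "seed": self.seed,
        }

    def fingerprint(self) -> str:
        """Stable digest of every setting that can change a result."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from YAML; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "oars" in raw:
        cfg.oars = tuple(
            OARSpec(
                name=o["name"],
                tolerance_cGy=float(o["tolerance_cGy"]),
                metric=MetricKind(o["metric"]),
                tier=OARTier(o["tier"]),
            )
            for o in raw["oars"]
        )
    if "protocols" in raw:
        cfg.protocols = tuple(
            ProtocolSpec(p["name"], float(p["prescription_cGy"]), int(p["fractions"]))
            for p in raw["protocols"]
        )
    for key in ("percent_normalization", "alpha", "model_families",
                "second_order_half_threshold", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg
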