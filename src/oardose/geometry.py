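"""Geometric agreement between gold and auto segmentations.

Dice and sensitivity are voxel-count overlap ratios.  Mean
distance-to-agreement (MDA) is a symmetric mean surface distance: surface
voxels are occupied voxels with at least one face-adjacent unoccupied
neighbour (the grid boundary counts as unoccupied), distances are between
voxel centres with anisotropic mm spacing applied, and the mean runs over
both directed surface-voxel sets.  A directed variant is available for
diagnostics but the symmetric form is the default everywhere downstream.

A failed segmentation carries *no* geometry metrics — it is a different
category from a mislocated structure that scores DSC = 0, and both are
preserved separately downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_grid import StructureMask, require_compatible

__all__ = ["GeometryMetrics", "dsc", "sensitivity", "mean_dta", "surface_voxels", "evaluate_geometry"]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class GeometryMetrics:
    """DSC, sensitivity and mean DTA for one case/organ/model."""

    dsc: Optional[float]
    sensitivity: Optional[float]
    mean_dta_mm: Optional[float]
    failed: bool
    status: str = "ok"


def _check(gold: StructureMask, auto: StructureMask) -> None:
    require_compatible(gold, auto, "gold and auto masks")
    if not gold.present or gold.voxel_count() == 0:
        raise ValueError("gold mask must be present and non-empty")


def dsc(gold: StructureMask, auto: StructureMask) -> float:
    """Dice similarity coefficient 2|G∩A| / (|G| + |A|)."""
    _check(gold, auto)
    if not auto.present:
        raise ValueError("auto mask is absent; failed segmentations carry no DSC")
    g, a = gold.values, auto.values
    inter = np.count_nonzero(g & a)
    return 2.0 * inter / (np.count_nonzero(g) + np.count_nonzero(a))


def sensitivity(gold: StructureMask, auto: StructureMask) -> float:
    """Fraction of gold voxels recovered: |G∩A| / |G|."""
    _check(gold, auto)
    if not auto.present:
        raise ValueError("auto mask is absent; failed segmentations carry no sensitivity")
    g, a = gold.values, auto.values
    return np.count_nonzero(g & a) / np.count_nonzero(g)


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """(n, 3) integer indices of occupied voxels with a face-adjacent
    unoccupied neighbour; voxels on the grid edge are surface."""
    occ = mask.values
    interior = ndimage.binary_erosion(occ, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(occ & ~interior)


def mean_dta(gold: StructureMask, auto: StructureMask, directed: bool = False) -> float:
    """Mean distance-to-agreement in mm.

    Symmetric by default: mean over the pooled directed distances
    auto-surface→gold-surface and gold-surface→auto-surface.  With
    ``directed=True`` only the auto→gold direction is averaged.
    """
    _check(gold, auto)
    if not auto.present:
        raise ValueError("auto mask is absent; failed segmentations carry no MDA")
    gs = surface_voxels(gold)
    as_ = surface_voxels(auto)
    if gs.size == 0 or as_.size == 0:
        raise ValueError("cannot compute MDA on an empty surface")
    spacing = np.asarray(gold.header.spacing)
    gs_mm = gs * spacing
    as_mm = as_ * spacing
    d_auto_to_gold, _ = cKDTree(gs_mm).query(as_mm, k=1)
    if directed:
        return float(np.mean(d_auto_to_gold))
    d_gold_to_auto, _ = cKDTree(as_mm).query(gs_mm, k=1)
    return float(np.mean(np.concatenate([d_auto_to_gold, d_gold_to_auto])))


def evaluate_geometry(gold: StructureMask, auto: StructureMask) -> GeometryMetrics:
    """All three metrics at once, mapping failed autos to a failed record."""
    require_compatible(gold, auto, "gold and auto masks")
    if not auto.present:
        status = auto.status if auto.status != "ok" else "failed"
        return GeometryMetrics(None, None, None, failed=True, status=status)
    return GeometryMetrics(
        dsc=dsc(gold, auto),
        sensitivity=sensitivity(gold, auto),
        mean_dta_mm=mean_dta(gold, auto),
        failed=False,
    )
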