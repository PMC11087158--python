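"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: full sorts and linear
scans for DVH metrics, explicit pairwise distance matrices for surface
distances, and plain voxel counting for overlap metrics.
"""

from __future__ import annotations

import numpy as np


def brute_dose_metric(doses, metric: str) -> float:
    """Descending full sort + linear cumulative scan."""
    ds = sorted((float(v) for v in np.asarray(doses).ravel()), reverse=True)
    n = len(ds)
    assert n > 0
    if metric == "Dmax":
        return ds[0]
    x = {"D1%": 1.0, "D5%": 5.0, "D50%": 50.0}[metric]
    need = n * x / 100.0
    count = 0
    for v in ds:
        count += 1
        if count >= need:
            return v
    return ds[-1]


def brute_surface(occ: np.ndarray) -> np.ndarray:
    """Occupied voxels with >= 1 face-adjacent unoccupied neighbour
    (outside the grid counts as unoccupied).  Explicit neighbour loop."""
    occ = np.asarray(occ, dtype=bool)
    out = []
    nz = np.argwhere(occ)
    shape = occ.shape
    for z, y, x in nz:
        boundary = False
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nzz, nyy, nxx = z + dz, y + dy, x + dx
            if not (0 <= nzz < shape[0] and 0 <= nyy < shape[1] and 0 <= nxx < shape[2]):
                boundary = True
                break
            if not occ[nzz, nyy, nxx]:
                boundary = True
                break
        if boundary:
            out.append((z, y, x))
    return np.asarray(out, dtype=float).reshape(-1, 3)


def brute_mean_dta(gold_occ: np.ndarray, auto_occ: np.ndarray, spacing) -> float:
    """Symmetric mean surface distance via the full O(n^2) distance matrix."""
    spacing = np.asarray(spacing, dtype=float)
    gs = brute_surface(gold_occ) * spacing
    as_ = brute_surface(auto_occ) * spacing
    assert len(gs) and len(as_)
    dmat = np.sqrt(((as_[:, None, :] - gs[None, :, :]) ** 2).sum(axis=2))
    d_a2g = dmat.min(axis=1)
    d_g2a = dmat.min(axis=0)
    return float(np.concatenate([d_a2g, d_g2a]).mean())


def brute_dsc(gold_occ: np.ndarray, auto_occ: np.ndarray) -> float:
    g = np.asarray(gold_occ, bool)
    a = np.asarray(auto_occ, bool)
    inter = int((g & a).sum())
    return 2.0 * inter / (int(g.sum()) + int(a.sum()))


def brute_sensitivity(gold_occ: np.ndarray, auto_occ: np.ndarray) -> float:
    g = np.asarray(gold_occ, bool)
    a = np.asarray(auto_occ, bool)
    return int((g & a).sum()) / int(g.sum())


def brute_nearest_value(values: np.ndarray, spacing, origin, point_mm) -> float:
    """Nearest-voxel-centre lookup by exhaustive scan over all voxels."""
    values = np.asarray(values)
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    best = None
    best_d = np.inf
    for idx in np.ndindex(values.shape):
        center = origin + np.asarray(idx) * spacing
        d = float(((center - np.asarray(point_mm)) ** 2).sum())
        if d < best_d:
            best_d = d
            best = values[idx]
    return float(best)
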