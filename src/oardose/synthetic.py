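"""Synthetic head-phantom cohorts: dose fields, gold organ masks and
parameterized autosegmentation errors.

The dose model is a radially symmetric logistic falloff around a spherical
high-dose target: ``dose(x) = P * (b + (1-b) * sigma((R - d(x)) / w))``
with ``P`` the prescription, ``R`` the target radius, ``w`` the gradient
width, ``b`` the background fraction, ``d`` the Euclidean distance from the
target centre and ``sigma`` the logistic function.  Optional multiplicative
Gaussian noise is seed-reproducible.  This is the simplest field with a
controllable gradient location; organs placed far from ``d = R`` sit in
near-uniform dose, organs straddling it sit on a steep gradient.

Organ phantoms are geometric primitives (sphere / ellipsoid / tube /
tapered cylinder) rasterized at voxel centres; every downstream computation
consumes only masks and doses, so anatomical realism is not required.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .core_grid import DoseGrid, GridHeader, ProtocolSpec, StructureMask

__all__ = [
    "Sphere",
    "Ellipsoid",
    "Tube",
    "TaperedCylinder",
    "PhantomSpec",
    "PerturbationSpec",
    "ErrorProfile",
    "CaseData",
    "Cohort",
    "PROTOCOL_A",
    "PROTOCOL_B",
    "default_phantom",
    "generate_dose",
    "generate_structures",
    "perturb",
    "simulate_cohort",
]

PROTOCOL_A = ProtocolSpec("A", 6000.0, 30)
PROTOCOL_B = ProtocolSpec("B", 5400.0, 30)


# ---------------------------------------------------------------------------
# Shape primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center_mm: Tuple[float, float, float]
    radius_mm: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = ((pts - np.asarray(self.center_mm)) ** 2).sum(axis=-1)
        return d2 <= self.radius_mm ** 2

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        return c - self.radius_mm, c + self.radius_mm


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = (pts - np.asarray(self.center_mm)) / np.asarray(self.semiaxes_mm)
        return (rel ** 2).sum(axis=-1) <= 1.0

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        s = np.asarray(self.semiaxes_mm)
        return c - s, c + s


@dataclass(frozen=True)
class Tube:
    """Cylinder with spherical cross-section perpendicular to ``axis``."""

    center_mm: Tuple[float, float, float]
    radius_mm: float
    half_length_mm: float
    axis: int = 0  # 0=z, 1=y, 2=x

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - np.asarray(self.center_mm)
        along = np.abs(rel[..., self.axis]) <= self.half_length_mm
        perp_axes = [k for k in range(3) if k != self.axis]
        r2 = rel[..., perp_axes[0]] ** 2 + rel[..., perp_axes[1]] ** 2
        return along & (r2 <= self.radius_mm ** 2)

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        ext = np.full(3, self.radius_mm)
        ext[self.axis] = self.half_length_mm
        return c - ext, c + ext


@dataclass(frozen=True)
class TaperedCylinder:
    """Cylinder whose radius varies linearly from one end to the other."""

    center_mm: Tuple[float, float, float]
    radius_start_mm: float
    radius_end_mm: float
    half_length_mm: float
    axis: int = 0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - np.asarray(self.center_mm)
        t = rel[..., self.axis]
        along = np.abs(t) <= self.half_length_mm
        # t = -L -> radius_start, t = +L -> radius_end
        frac = (t + self.half_length_mm) / (2.0 * self.half_length_mm)
        radius = self.radius_start_mm + frac * (self.radius_end_mm - self.radius_start_mm)
        perp_axes = [k for k in range(3) if k != self.axis]
        r2 = rel[..., perp_axes[0]] ** 2 + rel[..., perp_axes[1]] ** 2
        return along & (r2 <= np.maximum(radius, 0.0) ** 2)

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        rmax = max(self.radius_start_mm, self.radius_end_mm)
        ext = np.full(3, rmax)
        ext[self.axis] = self.half_length_mm
        return c - ext, c + ext


Primitive = Union[Sphere, Ellipsoid, Tube, TaperedCylinder]


def _shift_primitive(prim: Primitive, offset_mm: np.ndarray) -> Primitive:
    new_center = tuple(np.asarray(prim.center_mm) + offset_mm)
    return dataclasses.replace(prim, center_mm=new_center)


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build one synthetic case."""

    grid: GridHeader
    ptv_center_mm: Tuple[float, float, float]
    ptv_radius_mm: float          # R: gradient sits at d = R from the centre
    gradient_width_mm: float      # w: logistic falloff scale
    background_fraction: float    # b: far-field dose as a fraction of prescription
    oars: Mapping[str, Primitive] = field(default_factory=dict)
    noise_sd: float = 0.0         # fractional s.d. of multiplicative dose noise
    case_jitter_mm: float = 0.0   # per-case random shift of every organ centre

    def __post_init__(self) -> None:
        if self.ptv_radius_mm <= 0:
            raise ValueError("PTV radius must be positive")
        if self.gradient_width_mm <= 0:
            raise ValueError("gradient width must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background fraction must be in [0, 1)")
        for name, prim in self.oars.items():
            _check_inside(self.grid, prim, name)


def _check_inside(grid: GridHeader, prim: Primitive, name: str) -> None:
    lo, hi = prim.bounds()
    grid_lo = np.asarray(grid.origin)
    grid_hi = grid_lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    if np.any(lo < grid_lo) or np.any(hi > grid_hi):
        raise ValueError(
            f"primitive for {name!r} extends outside the grid: "
            f"bounds [{lo}, {hi}] vs grid [{grid_lo}, {grid_hi}]"
        )


def _voxel_centers(grid: GridHeader) -> np.ndarray:
    axes = [grid.voxel_centers_mm(k) for k in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def default_phantom(
    spacing_mm: float = 2.0,
    noise_sd: float = 0.01,
    case_jitter_mm: float = 0.0,
) -> PhantomSpec:
    """A 13-organ head phantom on a 100 x 140 x 140 mm grid.

    The roster mirrors a bilateral brain OAR set: brainstem, optic chiasm,
    paired optic nerves / orbits / lenses / lacrimal glands / cochleae, and
    pituitary.  Positions are schematic; the brainstem and chiasm sit near
    the high-dose gradient, peripheral organs sit in low, flat dose.
    """
    shape = tuple(int(round(e / spacing_mm)) + 1 for e in (100.0, 140.0, 140.0))
    grid = GridHeader(shape=shape, spacing=(spacing_mm,) * 3)
    oars: Dict[str, Primitive] = {
        # superior brainstem reaches into the gradient (positive but tight
        # headroom); chiasm straddles the gradient; everything else sits in
        # flat low dose
        "brainstem": TaperedCylinder((40.0, 86.0, 70.0), 8.0, 5.0, 16.0, axis=0),
        "optic_chiasm": Ellipsoid((50.0, 80.0, 70.0), (3.0, 5.0, 9.0)),
        "optic_nerve_l": Tube((48.0, 62.0, 58.0), 2.5, 11.0, axis=1),
        "optic_nerve_r": Tube((48.0, 62.0, 82.0), 2.5, 11.0, axis=1),
        "orbit_l": Sphere((46.0, 36.0, 48.0), 11.0),
        "orbit_r": Sphere((46.0, 36.0, 92.0), 11.0),
        "lens_l": Sphere((46.0, 24.0, 48.0), 4.0),
        "lens_r": Sphere((46.0, 24.0, 92.0), 4.0),
        "lacrimal_l": Ellipsoid((52.0, 30.0, 34.0), (5.0, 4.0, 4.0)),
        "lacrimal_r": Ellipsoid((52.0, 30.0, 106.0), (5.0, 4.0, 4.0)),
        "pituitary": Sphere((42.0, 74.0, 70.0), 4.5),
        "cochlea_l": Sphere((34.0, 90.0, 40.0), 3.0),
        "cochlea_r": Sphere((34.0, 90.0, 100.0), 3.0),
    }
    return PhantomSpec(
        grid=grid,
        ptv_center_mm=(60.0, 100.0, 70.0),
        ptv_radius_mm=20.0,
        gradient_width_mm=4.0,
        background_fraction=0.05,
        oars=oars,
        noise_sd=noise_sd,
        case_jitter_mm=case_jitter_mm,
    )


# ---------------------------------------------------------------------------
# Dose and structure generation
# ---------------------------------------------------------------------------

def generate_dose(
    phantom: PhantomSpec, protocol: ProtocolSpec, seed: Optional[int] = None
) -> DoseGrid:
    """Logistic-falloff dose field; noise is multiplicative Gaussian."""
    pts = _voxel_centers(phantom.grid)
    d = np.sqrt(((pts - np.asarray(phantom.ptv_center_mm)) ** 2).sum(axis=-1))
    b = phantom.background_fraction
    sig = 1.0 / (1.0 + np.exp(-(phantom.ptv_radius_mm - d) / phantom.gradient_width_mm))
    dose = protocol.prescription_cGy * (b + (1.0 - b) * sig)
    if phantom.noise_sd > 0:
        rng = np.random.default_rng(seed)
        dose = dose * (1.0 + phantom.noise_sd * rng.standard_normal(dose.shape))
    return DoseGrid(np.clip(dose, 0.0, None), phantom.grid)


def generate_structures(
    phantom: PhantomSpec,
    center_offsets_mm: Optional[Mapping[str, np.ndarray]] = None,
) -> Dict[str, StructureMask]:
    """Rasterize every configured organ primitive to a present mask.

    ``center_offsets_mm`` optionally shifts individual organs (used for
    per-case anatomical jitter); shifted primitives are re-checked against
    the grid bounds.
    """
    if not phantom.oars:
        raise ValueError("phantom defines no organs")
    pts = _voxel_centers(phantom.grid)
    out: Dict[str, StructureMask] = {}
    for name, prim in phantom.oars.items():
        if center_offsets_mm and name in center_offsets_mm:
            prim = _shift_primitive(prim, np.asarray(center_offsets_mm[name]))
            _check_inside(phantom.grid, prim, name)
        occ = prim.contains(pts)
        if not occ.any():
            raise ValueError(f"primitive for {name!r} rasterizes to zero voxels")
        out[name] = StructureMask(occ, phantom.grid, present=True)
    return out


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

PERTURBATION_KINDS = ("none", "dilate", "erode", "translate", "truncate", "mislocate", "fail")


@dataclass(frozen=True)
class PerturbationSpec:
    """One autosegmentation error to inflict on a gold mask.

    kind        one of ``none | dilate | erode | translate | truncate |
                mislocate | fail``
    magnitude   mm (dilate/erode) or occupied-slice count (truncate);
                ignored for translate (see ``vector_mm``), mislocate and fail
    vector_mm   displacement for translate; rounded to the nearest whole
                voxel per axis
    axis        truncation axis (occupied slices removed from the high end)
    seed        tie-breaking seed for mislocation direction search
    """

    kind: str
    magnitude: float = 0.0
    vector_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("perturbation magnitude must be >= 0")


def _ball_dilate(occ: np.ndarray, radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Ball-structuring-element dilation via the exact Euclidean distance
    transform (equivalent to morphology with a voxel-centre ball, but memory
    use is independent of the radius)."""
    dist = ndimage.distance_transform_edt(~occ, sampling=spacing)
    return occ | (dist <= radius_mm)


def _ball_erode(occ: np.ndarray, radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    dist = ndimage.distance_transform_edt(occ, sampling=spacing)
    return dist > radius_mm


def _translate_voxels(values: np.ndarray, shift: Sequence[int]) -> np.ndarray:
    """Integer-voxel shift with zero fill (voxels leaving the grid drop)."""
    out = values
    for ax, s in enumerate(shift):
        s = int(s)
        if s == 0:
            continue
        shifted = np.zeros_like(out)
        if s > 0:
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            src[ax] = slice(0, out.shape[ax] - s)
            dst[ax] = slice(s, out.shape[ax])
        else:
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            src[ax] = slice(-s, out.shape[ax])
            dst[ax] = slice(0, out.shape[ax] + s)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def _mislocate(gold: StructureMask, seed: int) -> np.ndarray:
    """Find an integer-voxel translation making the output disjoint from
    gold while keeping every voxel inside the grid (count preserved)."""
    occ = gold.values
    idx = np.argwhere(occ)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    extent = hi - lo + 1
    shape = np.asarray(gold.header.shape)
    rng = np.random.default_rng(seed)
    axis_order = rng.permutation(3)
    for gap_scale in (1, 2):
        for ax in axis_order:
            for sign in (1, -1):
                shift = np.zeros(3, dtype=int)
                shift[ax] = sign * (extent[ax] + gap_scale)
                new_lo = lo + shift
                new_hi = hi + shift
                if np.any(new_lo < 0) or np.any(new_hi >= shape):
                    continue
                moved = _translate_voxels(occ, shift)
                if not (moved & occ).any():
                    return moved
    raise ValueError("no in-grid disjoint translation exists for mislocation")


def perturb(gold: StructureMask, spec: PerturbationSpec) -> StructureMask:
    """Apply one autosegmentation-error mode to a gold mask.

    Erosion/truncation that removes every voxel returns an absent mask with
    status ``eroded-away`` — distinct from the ``failed`` status of a model
    that produced nothing at all.
    """
    if not gold.present:
        raise ValueError("cannot perturb an absent gold mask")
    header = gold.header
    if spec.kind == "fail":
        return StructureMask.absent(header, status="failed")
    if spec.kind == "none" or (
        spec.kind in ("dilate", "erode", "truncate") and spec.magnitude == 0
    ):
        return StructureMask(gold.values.copy(), header, present=True)
    if spec.kind in ("dilate", "erode"):
        if spec.kind == "dilate":
            out = _ball_dilate(gold.values, spec.magnitude, header.spacing)
        else:
            out = _ball_erode(gold.values, spec.magnitude, header.spacing)
            if not out.any():
                return StructureMask.absent(header, status="eroded-away")
        return StructureMask(out, header, present=True)
    if spec.kind == "translate":
        shift = np.rint(np.asarray(spec.vector_mm) / np.asarray(header.spacing)).astype(int)
        if not shift.any():
            return StructureMask(gold.values.copy(), header, present=True)
        out = _translate_voxels(gold.values, shift)
        if not out.any():
            return StructureMask.absent(header, status="eroded-away")
        return StructureMask(out, header, present=True)
    if spec.kind == "truncate":
        occupied = np.unique(np.argwhere(gold.values)[:, spec.axis])
        k = int(round(spec.magnitude))
        if k >= occupied.size:
            return StructureMask.absent(header, status="eroded-away")
        out = gold.values.copy()
        cut = occupied[occupied.size - k:]
        sl = [slice(None)] * 3
        for c in cut:
            sl[spec.axis] = int(c)
            out[tuple(sl)] = False
        return StructureMask(out, header, present=True)
    if spec.kind == "mislocate":
        return StructureMask(_mislocate(gold, spec.seed), header, present=True)
    raise AssertionError(f"unhandled kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorProfile:
    """Distribution over perturbations for one autosegmentation model.

    ``kind_weights`` are relative sampling weights over perturbation kinds
    (``none`` included).  Magnitudes are drawn uniformly from
    ``magnitude_range_mm`` (dilate/erode and translate displacement);
    truncation removes between one and ``truncate_max_slices`` occupied
    slices along a random axis.
    """

    kind_weights: Mapping[str, float]
    magnitude_range_mm: Tuple[float, float] = (1.0, 5.0)
    truncate_max_slices: int = 3

    def __post_init__(self) -> None:
        if not self.kind_weights:
            raise ValueError("empty kind_weights")
        for k in self.kind_weights:
            if k not in PERTURBATION_KINDS:
                raise ValueError(f"unknown perturbation kind {k!r}")
        if any(w < 0 for w in self.kind_weights.values()):
            raise ValueError("weights must be non-negative")
        if sum(self.kind_weights.values()) <= 0:
            raise ValueError("weights must not all be zero")

    def failure_probability(self) -> float:
        total = sum(self.kind_weights.values())
        return self.kind_weights.get("fail", 0.0) / total

    def sample(self, rng: np.random.Generator) -> PerturbationSpec:
        kinds = sorted(self.kind_weights)
        weights = np.array([self.kind_weights[k] for k in kinds], dtype=float)
        kind = str(rng.choice(kinds, p=weights / weights.sum()))
        lo, hi = self.magnitude_range_mm
        if kind in ("dilate", "erode"):
            return PerturbationSpec(kind, magnitude=float(rng.uniform(lo, hi)))
        if kind == "translate":
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            mag = float(rng.uniform(lo, hi))
            return PerturbationSpec(kind, magnitude=mag, vector_mm=tuple(mag * direction))
        if kind == "truncate":
            return PerturbationSpec(
                kind,
                magnitude=float(rng.integers(1, self.truncate_max_slices + 1)),
                axis=int(rng.integers(0, 3)),
            )
        if kind == "mislocate":
            return PerturbationSpec(kind, seed=int(rng.integers(0, 2 ** 31)))
        return PerturbationSpec(kind)  # none / fail


@dataclass
class CaseData:
    """One simulated case: dose, gold masks and per-model auto masks."""

    case_id: str
    protocol: ProtocolSpec
    dose: DoseGrid
    gold: Dict[str, StructureMask]
    auto: Dict[str, Dict[str, StructureMask]]  # model -> organ -> mask
    perturbations: Dict[str, Dict[str, PerturbationSpec]]


@dataclass
class Cohort:
    cases: Tuple[CaseData, ...]
    phantom: PhantomSpec
    models: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.cases)


def simulate_cohort(
    n_cases: int,
    phantom: PhantomSpec,
    model_error_profiles: Mapping[str, ErrorProfile],
    seed: int,
    protocol_a_fraction: float = 0.6,
    protocols: Tuple[ProtocolSpec, ProtocolSpec] = (PROTOCOL_A, PROTOCOL_B),
) -> Cohort:
    """Simulate a reproducible test cohort.

    Protocol labels are assigned by rounding ``protocol_a_fraction`` of the
    cohort to the first protocol (deterministic split, shuffled by seed).
    Everything downstream of (spec, seed) is pure.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    if not model_error_profiles:
        raise ValueError("model_error_profiles must not be empty")
    rng = np.random.default_rng(seed)
    n_a = int(round(protocol_a_fraction * n_cases))
    labels = np.array([0] * n_a + [1] * (n_cases - n_a))
    rng.shuffle(labels)
    models = tuple(sorted(model_error_profiles))
    cases = []
    for i in range(n_cases):
        protocol = protocols[labels[i]]
        case_seed = int(rng.integers(0, 2 ** 31))
        case_rng = np.random.default_rng(case_seed)
        offsets = None
        if phantom.case_jitter_mm > 0:
            offsets = {
                name: case_rng.uniform(-phantom.case_jitter_mm, phantom.case_jitter_mm, 3)
                for name in phantom.oars
            }
        dose = generate_dose(phantom, protocol, seed=int(case_rng.integers(0, 2 ** 31)))
        gold = generate_structures(phantom, center_offsets_mm=offsets)
        auto: Dict[str, Dict[str, StructureMask]] = {}
        perts: Dict[str, Dict[str, PerturbationSpec]] = {}
        for model in models:
            profile = model_error_profiles[model]
            auto[model] = {}
            perts[model] = {}
            for organ, gmask in gold.items():
                pspec = profile.sample(case_rng)
                perts[model][organ] = pspec
                auto[model][organ] = perturb(gmask, pspec)
        cases.append(
            CaseData(
                case_id=f"case_{i:03d}",
                protocol=protocol,
                dose=dose,
                gold=gold,
                auto=auto,
                perturbations=perts,
            )
        )
    return Cohort(cases=tuple(cases), phantom=phantom, models=models)
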