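"""Synthetic paired CTU / unenhanced-CT phantoms with ground-truth labels.

The phantom emulates the anatomy and failure modes the pipeline must
handle: two ellipsoidal kidneys, two tubular ureters descending to an
ellipsoidal bladder, optional *unopacified gaps* along the ureters (the
segments an opacity-driven segmenter cannot see), extra-tract incidental
lesions, additive Gaussian noise, and a known rigid/affine misalignment
between the contrast-enhanced and unenhanced volumes.

Everything is analytic: a voxel is labeled iff its center lies inside the
shape, ureters are unions of spheres along a 1 mm-resampled centerline
(so gap arithmetic is exact arc length), and the applied misalignment is
stored with the output, giving registration a parameter-recovery ground
truth. Intensities are fixture constants chosen for plausible contrast,
not claims about real tissue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .register import AffineTransform
from .volio import BLADDER, KIDNEY, URETER, ImageVolume, LabelVolume

__all__ = [
    "Ellipsoid",
    "UreterSpec",
    "Gap",
    "Lesion",
    "PhantomSpec",
    "PhantomOutput",
    "default_spec",
    "random_spec",
    "generate_phantom",
]

CENTERLINE_STEP_MM = 1.0


@dataclass(frozen=True)
class Ellipsoid:
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center, dtype=pts.dtype)) / np.asarray(
            self.semi_axes, dtype=pts.dtype
        )
        return (d * d).sum(axis=-1) <= 1.0

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class UreterSpec:
    """Tube: union of spheres of ``radius_mm`` along a smoothed polyline."""

    control_points: Tuple[Tuple[float, float, float], ...]
    radius_mm: float = 4.0

    def centerline(self, step_mm: float = CENTERLINE_STEP_MM) -> np.ndarray:
        """Arc-length resampling of the control polyline at ``step_mm``."""
        pts = np.asarray(self.control_points, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(int(np.round(total / step_mm)) + 1, 2)
        si = np.linspace(0.0, total, n)
        out = np.empty((n, 3))
        for ax in range(3):
            out[:, ax] = np.interp(si, s, pts[:, ax])
        return out


@dataclass(frozen=True)
class Cylinder:
    """z-aligned rod (vertebral-column surrogate for registration anchoring)."""

    center_xy: Tuple[float, float]
    radius_mm: float
    z_range: Tuple[float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        dx = pts[..., 0] - self.center_xy[0]
        dy = pts[..., 1] - self.center_xy[1]
        return (dx * dx + dy * dy <= self.radius_mm ** 2) & (
            (pts[..., 2] >= self.z_range[0]) & (pts[..., 2] <= self.z_range[1])
        )


@dataclass(frozen=True)
class Gap:
    """Unopacified ureter segment: invisible to an opacity-based segmenter."""

    side: str  # "left" | "right"
    start_fraction: float  # of total arc length, in [0, 1)
    length_mm: float


@dataclass(frozen=True)
class Lesion:
    """Extra-tract incidental finding (sphere)."""

    center: Tuple[float, float, float]
    radius_mm: float = 8.0
    hu: float = 80.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    body: Ellipsoid
    kidneys: Dict[str, Ellipsoid]
    ureters: Dict[str, UreterSpec]
    bladder: Ellipsoid
    gaps: Tuple[Gap, ...] = ()
    lesions: Tuple[Lesion, ...] = ()
    contrast_hu: float = 300.0
    kidney_hu: float = 140.0  # nephrographic-phase parenchyma
    soft_tissue_hu: float = 40.0
    unopacified_hu: float = 35.0
    air_hu: float = -1024.0
    fat_hu: float = -90.0  # perirenal fat capsule, visible on both phases
    perirenal_fat_scale: float = 1.35  # fat shell = kidney ellipsoid scaled by this
    bone_hu: float = 500.0
    spine: Optional["Cylinder"] = None  # vertebral-column surrogate
    noise_sd: float = 10.0
    misalignment: AffineTransform = field(default_factory=AffineTransform.identity)
    lesion_clearance_mm: float = 30.0  # boundary (10) + bridge (20) radii
    seed: int = 0

    @property
    def origin(self) -> Tuple[float, float, float]:
        return (0.0, 0.0, 0.0)


@dataclass
class PhantomOutput:
    """Paired volumes plus every piece of ground truth downstream stages need.

    ``truth`` is the gap-free anatomy; ``observed`` has gap voxels removed
    from the ureter labels (what a segmenter of opacified tract could see),
    so ``observed`` ⊆ ``truth`` voxel-wise. ``misalignment`` maps CTU-frame
    physical points to unenhanced-frame points (patient motion between the
    acquisitions); registration of unenhanced→CTU should recover its inverse.
    ``ureter_arclength`` holds, for every truth ureter voxel, its fractional
    arc-length position along its ureter (NaN elsewhere); ``ureter_side`` is
    1 for left, 2 for right, 0 elsewhere.
    """

    ctu: ImageVolume
    unenhanced: ImageVolume
    truth: LabelVolume
    observed: LabelVolume
    incidental_mask: np.ndarray
    misalignment: AffineTransform
    ureter_side: np.ndarray
    ureter_arclength: np.ndarray
    spec: PhantomSpec


def default_spec(scale: str = "small") -> PhantomSpec:
    """Deterministic reference phantom at ``small`` or ``standard`` scale.

    Both scales share one anatomy in a 192 × 160 × 256 mm field of view;
    ``standard`` grids it at 1 × 1 × 2 mm (192 × 160 × 128 voxels) and
    ``small`` at 2 × 2 × 4 mm (96 × 80 × 64 voxels) for fast tests.
    """
    if scale == "small":
        shape, spacing = (96, 80, 64), (2.0, 2.0, 4.0)
    elif scale == "standard":
        shape, spacing = (192, 160, 128), (1.0, 1.0, 2.0)
    else:
        raise ValueError(f"scale must be 'small' or 'standard', got {scale!r}")

    center_mm = tuple(n * s / 2.0 for n, s in zip(shape, spacing))
    misalignment = AffineTransform.from_rigid(
        rotation_deg=(0.0, 0.0, 2.0), translation=(3.0, -2.0, 4.0), center=center_mm
    )
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        body=Ellipsoid((96.0, 80.0, 128.0), (88.0, 72.0, 126.0)),
        kidneys={
            "left": Ellipsoid((52.0, 78.0, 72.0), (22.0, 18.0, 38.0)),
            "right": Ellipsoid((140.0, 82.0, 70.0), (22.0, 18.0, 38.0)),
        },
        ureters={
            "left": UreterSpec(
                ((52.0, 78.0, 95.0), (62.0, 84.0, 120.0), (66.0, 88.0, 150.0),
                 (72.0, 90.0, 175.0), (88.0, 88.0, 195.0))
            ),
            "right": UreterSpec(
                ((140.0, 82.0, 95.0), (130.0, 86.0, 120.0), (126.0, 90.0, 150.0),
                 (120.0, 92.0, 175.0), (104.0, 90.0, 195.0))
            ),
        },
        bladder=Ellipsoid((96.0, 88.0, 204.0), (34.0, 30.0, 26.0)),
        lesions=(
            Lesion((96.0, 30.0, 120.0), 8.0, 80.0),
            Lesion((150.0, 40.0, 160.0), 10.0, 80.0),
        ),
        spine=Cylinder((96.0, 120.0), 11.0, (0.0, 256.0)),
        misalignment=misalignment,
        seed=0,
    )


def random_spec(
    seed: int,
    scale: str = "small",
    n_gaps: int = 0,
    gap_length_range: Tuple[float, float] = (5.0, 25.0),
    with_lesions: bool = True,
    max_translation_mm: float = 4.0,
    max_rotation_deg: float = 2.0,
) -> PhantomSpec:
    """Jittered variant of :func:`default_spec` for randomized property tests.

    Organ centers move by up to ±5 mm, semi-axes scale by ±10%, interior
    ureter control points shift by up to ±4 mm, and ``n_gaps`` unopacified
    gaps with lengths drawn from ``gap_length_range`` are placed on
    alternating ureters. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    base = default_spec(scale)

    def jit_ellipsoid(e: Ellipsoid, c_mm=5.0, a_frac=0.10) -> Ellipsoid:
        c = tuple(np.asarray(e.center) + rng.uniform(-c_mm, c_mm, 3))
        a = tuple(np.asarray(e.semi_axes) * rng.uniform(1 - a_frac, 1 + a_frac, 3))
        return Ellipsoid(c, a)

    kidneys = {s: jit_ellipsoid(base.kidneys[s]) for s in ("left", "right")}
    bladder = jit_ellipsoid(base.bladder)

    ureters = {}
    for s in ("left", "right"):
        pts = np.asarray(base.ureters[s].control_points, dtype=float)
        pts[1:-1] += rng.uniform(-4.0, 4.0, (len(pts) - 2, 3))
        # keep the endpoints anchored inside the jittered kidney / bladder
        pts[0] = np.asarray(kidneys[s].center) + (0.0, 0.0, 0.55 * kidneys[s].semi_axes[2])
        pts[-1] = np.asarray(bladder.center) - (
            (-1 if s == "right" else 1) * 0.25 * bladder.semi_axes[0], 0.0,
            0.55 * bladder.semi_axes[2],
        )
        ureters[s] = UreterSpec(tuple(map(tuple, pts)), base.ureters[s].radius_mm)

    gaps = []
    for i in range(n_gaps):
        side = ("left", "right")[i % 2]
        length = float(rng.uniform(*gap_length_range))
        start = float(rng.uniform(0.25, 0.65))
        gaps.append(Gap(side, start, length))

    center_mm = tuple(n * s / 2.0 for n, s in zip(base.shape, base.spacing))
    misalignment = AffineTransform.from_rigid(
        rotation_deg=tuple(rng.uniform(-max_rotation_deg, max_rotation_deg, 3)),
        translation=tuple(rng.uniform(-max_translation_mm, max_translation_mm, 3)),
        center=center_mm,
    )
    return replace(
        base,
        kidneys=kidneys,
        ureters=ureters,
        bladder=bladder,
        gaps=tuple(gaps),
        lesions=base.lesions if with_lesions else (),
        misalignment=misalignment,
        seed=int(seed),
    )


class PhantomValidationError(ValueError):
    pass


def _evaluate_anatomy(spec: PhantomSpec, pts: np.ndarray, trees: dict):
    """Label geometry at physical points ``pts`` (N, 3).

    Returns (labels, ureter_side, ureter_frac, body_mask) as flat arrays.
    Label precedence on overlap: kidney > bladder > ureter.
    """
    n = pts.shape[0]
    labels = np.zeros(n, dtype=np.uint8)
    side_arr = np.zeros(n, dtype=np.uint8)
    frac = np.full(n, np.nan, dtype=np.float32)

    body = spec.body.contains(pts)

    for code, s in ((1, "left"), (2, "right")):
        tree, npts = trees[s]
        dist, idx = tree.query(pts, workers=-1)
        inside = dist <= spec.ureters[s].radius_mm
        labels[inside] = URETER
        side_arr[inside] = code
        frac[inside] = idx[inside].astype(np.float32) / max(npts - 1, 1)

    bl = spec.bladder.contains(pts)
    labels[bl] = BLADDER
    side_arr[bl] = 0
    frac[bl] = np.nan
    for s in ("left", "right"):
        k = spec.kidneys[s].contains(pts)
        labels[k] = KIDNEY
        side_arr[k] = 0
        frac[k] = np.nan
    return labels, side_arr, frac, body


def _render_hu(
    spec: PhantomSpec,
    labels: np.ndarray,
    side: np.ndarray,
    frac: np.ndarray,
    body: np.ndarray,
    pts: np.ndarray,
    contrast: bool,
    gap_mask: np.ndarray,
) -> np.ndarray:
    hu = np.full(labels.shape, spec.air_hu, dtype=np.float32)
    hu[body] = spec.soft_tissue_hu
    # phase-independent anatomy: perirenal fat capsules and the spine rod
    # give the unenhanced volume the structure real registration relies on
    for s in ("left", "right"):
        k = spec.kidneys[s]
        shell = Ellipsoid(k.center, tuple(a * spec.perirenal_fat_scale for a in k.semi_axes))
        hu[shell.contains(pts) & body] = spec.fat_hu
    if spec.spine is not None:
        hu[spec.spine.contains(pts) & body] = spec.bone_hu
    if contrast:
        hu[labels == KIDNEY] = spec.kidney_hu
        hu[labels == BLADDER] = spec.contrast_hu
        hu[labels == URETER] = spec.contrast_hu
        hu[gap_mask] = spec.unopacified_hu
    else:
        hu[labels > 0] = spec.unopacified_hu
    for les in spec.lesions:
        d = np.linalg.norm(pts - np.asarray(les.center, dtype=pts.dtype), axis=-1)
        hu[d <= les.radius_mm] = les.hu
    return hu


def _gap_mask(spec: PhantomSpec, side: np.ndarray, frac: np.ndarray, trees: dict) -> np.ndarray:
    """Ureter voxels whose arc-length position falls inside a gap interval."""
    mask = np.zeros(side.shape, dtype=bool)
    for gap in spec.gaps:
        code = {"left": 1, "right": 2}[gap.side]
        _, npts = trees[gap.side]
        total = (npts - 1) * CENTERLINE_STEP_MM
        s0 = gap.start_fraction * total
        s1 = s0 + gap.length_mm
        arc = frac * total
        mask |= (side == code) & (arc >= s0) & (arc < s1)
    return mask


def generate_phantom(spec: PhantomSpec, validate: bool = True) -> PhantomOutput:
    """Render a phantom pair from its analytic specification.

    Deterministic given ``spec`` (including ``spec.seed``). With
    ``validate=True`` the organ-disjointness, lesion-clearance and (for a
    gap-free spec) tract-connectivity invariants are checked and violations
    raise :class:`PhantomValidationError` naming the offending parts.
    """
    shape, spacing = spec.shape, spec.spacing
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float32) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1).reshape(-1, 3)

    trees = {}
    for s in ("left", "right"):
        cl = spec.ureters[s].centerline()
        trees[s] = (cKDTree(cl), len(cl))

    labels, side, frac, body = _evaluate_anatomy(spec, pts, trees)
    gap_mask = _gap_mask(spec, side, frac, trees)

    if validate:
        _validate(spec, pts, labels, shape)

    rng = np.random.default_rng(spec.seed)

    ctu_hu = _render_hu(spec, labels, side, frac, body, pts, contrast=True, gap_mask=gap_mask)
    if spec.noise_sd > 0:
        ctu_hu = ctu_hu + rng.normal(0.0, spec.noise_sd, ctu_hu.shape).astype(np.float32)

    # unenhanced volume: anatomy seen through the misalignment (patient moved),
    # rendered without contrast, with its own independent noise draw
    inv = spec.misalignment.inverse()
    pts_m = inv.apply(pts).astype(np.float32)
    labels_m, side_m, frac_m, body_m = _evaluate_anatomy(spec, pts_m, trees)
    unenh_hu = _render_hu(
        spec, labels_m, side_m, frac_m, body_m, pts_m, contrast=False,
        gap_mask=np.zeros(labels_m.shape, dtype=bool),
    )
    if spec.noise_sd > 0:
        unenh_hu = unenh_hu + rng.normal(0.0, spec.noise_sd, unenh_hu.shape).astype(np.float32)

    incidental = np.zeros(pts.shape[0], dtype=bool)
    for les in spec.lesions:
        d = np.linalg.norm(pts - np.asarray(les.center, dtype=pts.dtype), axis=-1)
        incidental |= d <= les.radius_mm

    observed_labels = labels.copy()
    observed_labels[gap_mask] = 0

    def vol(a, cls=ImageVolume):
        return cls(a.reshape(shape), spacing=spacing, origin=spec.origin)

    return PhantomOutput(
        ctu=vol(ctu_hu),
        unenhanced=vol(unenh_hu),
        truth=vol(labels, LabelVolume),
        observed=vol(observed_labels, LabelVolume),
        incidental_mask=incidental.reshape(shape),
        misalignment=spec.misalignment,
        ureter_side=side.reshape(shape),
        ureter_arclength=frac.reshape(shape),
        spec=spec,
    )


def _validate(spec: PhantomSpec, pts: np.ndarray, labels: np.ndarray, shape) -> None:
    # organ ellipsoids must be pairwise disjoint (ureters may dip into
    # kidney/bladder by construction; precedence resolves those overlaps)
    organs = {
        "left kidney": spec.kidneys["left"],
        "right kidney": spec.kidneys["right"],
        "bladder": spec.bladder,
    }
    names = list(organs)
    masks = {n: organs[n].contains(pts) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise PhantomValidationError(f"overlapping organs: {a} and {b}")

    tract = labels > 0
    if spec.lesions and tract.any():
        tract_pts = pts[tract]
        tree = cKDTree(tract_pts)
        for les in spec.lesions:
            d, _ = tree.query(np.asarray(les.center, dtype=np.float32))
            required = spec.lesion_clearance_mm + les.radius_mm
            if d < required:
                raise PhantomValidationError(
                    f"lesion at {les.center} is {d:.1f} mm from the urinary tract; "
                    f"needs >= {required:.1f} mm for well-posed concealment"
                )

    if not spec.gaps:
        lab_img, n = ndimage.label(tract.reshape(shape), structure=np.ones((3, 3, 3), dtype=bool))
        if n != 1:
            raise PhantomValidationError(
                f"gap-free tract must be a single connected component, found {n}"
            )
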