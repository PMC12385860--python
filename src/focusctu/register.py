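"""Affine/rigid alignment of the unenhanced CT to the CTU frame.

The metric is the Pearson cross-correlation of voxel intensities; the
optimizer is (regular-step) gradient descent over a 3-level image pyramid,
run through SimpleITK's registration framework with full (non-random)
metric sampling so results are deterministic.

Transform convention
--------------------
:class:`AffineTransform` represents the physical-space map
``y = matrix @ x + translation`` (millimetres). :func:`register` returns the
map from *moving*-frame physical points into the *fixed* frame, i.e. the
transform that, applied to the moving volume via :func:`apply_transform`,
aligns it with the fixed volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .volio import ImageVolume, LabelVolume, Volume

__all__ = [
    "AffineTransform",
    "RegistrationOptions",
    "RegistrationResult",
    "RegistrationError",
    "cross_correlation",
    "register",
    "apply_transform",
]


class RegistrationError(RuntimeError):
    """Raised when the similarity metric is undefined or optimization fails."""


@dataclass(frozen=True, eq=False)
class AffineTransform:
    """Physical-space affine map ``y = matrix @ x + translation`` (mm).

    ``rigid=True`` asserts (to 1e-6) that ``matrix`` is a proper rotation.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rigid: bool = False

    def __eq__(self, other) -> bool:
        if not isinstance(other, AffineTransform):
            return NotImplemented
        return (
            bool(np.array_equal(self.matrix, other.matrix))
            and bool(np.array_equal(self.translation, other.translation))
            and self.rigid == other.rigid
        )

    def __hash__(self):
        return hash((self.matrix.tobytes(), self.translation.tobytes(), self.rigid))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)
        det = np.linalg.det(m)
        if abs(det) < 1e-8:
            raise ValueError(f"affine matrix is singular (det={det:g})")
        if self.rigid:
            if not np.allclose(m @ m.T, np.eye(3), atol=1e-6) or det < 0:
                raise ValueError("rigid transform requires an orthonormal matrix with det +1")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_rigid(
        cls,
        rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation (degrees, about x/y/z through ``center``) then translation."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - R @ c
        return cls(R, t, rigid=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape ``(..., 3)``."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, rigid=self.rigid)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``x -> self(other(x))``."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
            rigid=self.rigid and other.rigid,
        )

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the orthogonal (polar) factor of ``matrix``."""
        from scipy.linalg import polar

        u, _ = polar(self.matrix)
        cosang = np.clip((np.trace(u) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))

    def displacement_at(self, point: Sequence[float]) -> np.ndarray:
        """``self(point) - point``; useful as a local misalignment magnitude."""
        p = np.asarray(point, dtype=float)
        return self.apply(p) - p

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "rigid": bool(self.rigid),
            "convention": "y = matrix @ x + translation, physical mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["matrix"]), np.array(d["translation"]), bool(d.get("rigid", False)))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def cross_correlation(
    a: ImageVolume, b: ImageVolume, overlap_mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation of intensities over the overlap region, in [-1, 1].

    Raises :class:`RegistrationError` if either image is constant inside the
    overlap (the correlation is then undefined — never silently zero).
    """
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(f"grids differ: {a.voxels.shape} vs {b.voxels.shape}")
    x = a.voxels.astype(np.float64)
    y = b.voxels.astype(np.float64)
    if overlap_mask is not None:
        overlap_mask = np.asarray(overlap_mask, dtype=bool)
        if overlap_mask.shape != x.shape:
            raise ValueError("overlap mask grid mismatch")
        if not overlap_mask.any():
            raise ValueError("overlap mask is empty")
        x, y = x[overlap_mask], y[overlap_mask]
    else:
        x, y = x.ravel(), y.ravel()
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if sx == 0.0 or sy == 0.0:
        raise RegistrationError("correlation undefined: constant image within overlap")
    return float(np.clip((x * y).sum() / (sx * sy), -1.0, 1.0))


@dataclass
class RegistrationOptions:
    """Optimizer and model choices for :func:`register`.

    ``model`` selects the full 12-parameter affine (default, the general
    path) or its rigid restriction. The pyramid shrink factors and smoothing
    sigmas define a standard 3-level coarse-to-fine schedule.
    """

    model: str = "affine"  # "affine" | "rigid"
    shrink_factors: Tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas_mm: Tuple[float, ...] = (4.0, 2.0, 0.0)
    learning_rate: float = 2.0
    min_step: float = 1e-4
    iterations_per_level: int = 200
    convergence_tolerance: float = 1e-6

    def __post_init__(self):
        if self.model not in ("affine", "rigid"):
            raise ValueError(f"model must be 'affine' or 'rigid', got {self.model!r}")
        if len(self.shrink_factors) != len(self.smoothing_sigmas_mm):
            raise ValueError("shrink_factors and smoothing_sigmas_mm must have equal length")


@dataclass
class RegistrationResult:
    """Outcome of :func:`register`: the moving→fixed map plus diagnostics."""

    transform: AffineTransform
    metric_value: float  # cross-correlation-based metric at the optimum (higher = better)
    metric_at_identity: float
    iterations: int


def _to_sitk(vol: ImageVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)).astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def register(
    fixed: ImageVolume, moving: ImageVolume, options: Optional[RegistrationOptions] = None
) -> RegistrationResult:
    """Find the affine (or rigid) map aligning ``moving`` to ``fixed``.

    Maximizes the cross-correlation between the fixed volume and the
    transformed moving volume by gradient descent, seeded from the identity,
    over a multi-resolution pyramid. Deterministic given ``options``.

    Returns the transform mapping moving-frame physical points into the
    fixed frame, so ``apply_transform(moving, result.transform, fixed)``
    yields the aligned moving volume on the fixed grid.
    """
    import SimpleITK as sitk

    options = options or RegistrationOptions()
    for vol, name in ((fixed, "fixed"), (moving, "moving")):
        if np.ptp(vol.voxels) == 0:
            raise RegistrationError(f"{name} volume is constant; metric undefined")

    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    if options.model == "rigid":
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
    else:
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=options.learning_rate,
        minStep=options.min_step,
        numberOfIterations=options.iterations_per_level,
        gradientMagnitudeTolerance=options.convergence_tolerance,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(options.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(options.smoothing_sigmas_mm))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)

    metric_at_identity = -reg.MetricEvaluate(f_img, m_img)
    final_tx = reg.Execute(f_img, m_img)
    metric_value = -float(reg.GetMetricValue())
    iterations = int(reg.GetOptimizerIteration())

    # SimpleITK's resampling transform maps fixed-frame points to moving-frame
    # points; invert to obtain the moving->fixed map we expose.
    try:
        flat = final_tx
        if options.model == "rigid":
            sitk.Euler3DTransform(flat)
        else:
            sitk.AffineTransform(flat)
    except Exception:
        flat = sitk.CompositeTransform(final_tx).GetBackTransform()
    if options.model == "rigid":
        euler = sitk.Euler3DTransform(flat)
        A = np.array(euler.GetMatrix()).reshape(3, 3)
        c = np.array(euler.GetCenter())
        t = np.array(euler.GetTranslation())
    else:
        aff = sitk.AffineTransform(flat)
        A = np.array(aff.GetMatrix()).reshape(3, 3)
        c = np.array(aff.GetCenter())
        t = np.array(aff.GetTranslation())
    fixed_to_moving = AffineTransform(A, t + c - A @ c, rigid=False)
    moving_to_fixed = fixed_to_moving.inverse()
    if options.model == "rigid":
        # re-orthonormalize against accumulated float error before flagging rigid
        u, _, vt = np.linalg.svd(moving_to_fixed.matrix)
        moving_to_fixed = AffineTransform(u @ vt, moving_to_fixed.translation, rigid=True)
    return RegistrationResult(
        transform=moving_to_fixed,
        metric_value=metric_value,
        metric_at_identity=metric_at_identity,
        iterations=iterations,
    )


def apply_transform(
    volume: Volume,
    transform: AffineTransform,
    reference: Volume,
    fill_value: Optional[float] = None,
) -> Volume:
    """Resample ``volume`` onto the grid of ``reference``.

    ``transform`` maps volume-frame physical points into the reference frame;
    the output satisfies ``out(x) = volume(transform^{-1}(x))`` for reference
    voxel centers ``x``. Scalar volumes are linearly interpolated, label/mask
    volumes use nearest-neighbour. Out-of-field voxels take ``fill_value``
    (default −1024 HU for images, 0 for labels).
    """
    is_label = isinstance(volume, LabelVolume)
    if fill_value is None:
        fill_value = 0 if is_label else -1024.0

    inv = transform.inverse()
    sp_in = np.asarray(volume.spacing)
    or_in = np.asarray(volume.origin)
    sp_ref = np.asarray(reference.spacing)
    or_ref = np.asarray(reference.origin)

    # index_out -> physical_ref -> (inv) physical_in -> index_in
    M = (inv.matrix * sp_ref[None, :]) / sp_in[:, None]
    offset = (inv.matrix @ or_ref + inv.translation - or_in) / sp_in

    data = volume.voxels.astype(np.uint8 if is_label else np.float32)
    out = ndimage.affine_transform(
        data,
        M,
        offset=offset,
        output_shape=reference.voxels.shape,
        order=0 if is_label else 1,
        mode="constant",
        cval=fill_value,
    )
    if is_label:
        return LabelVolume(out.astype(np.uint8), tuple(sp_ref), tuple(or_ref))
    return ImageVolume(out.astype(np.float32), tuple(sp_ref), tuple(or_ref))
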