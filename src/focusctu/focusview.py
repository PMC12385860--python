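"""Focused-view mask generation and application.

Three masking methods, in increasing order of permissiveness:

* **method 1** — the raw segmentation itself (kidney ∪ ureter ∪ bladder);
* **method 2** — method 1 dilated by a spherical structuring element with a
  physical radius (default 10 mm), giving a safety boundary so organ edges
  remain assessable; on anisotropic grids the element is ellipsoidal in
  index space because the radius is specified in millimetres;
* **method 3** — method 2 plus *gap bridging*: while the urinary-tract
  segmentation has more than one connected component, a straight voxel path
  is rasterized between the closest voxel-center pair of a disconnected
  ureter-bearing component and its nearest other component; each added path
  is dilated by a second radius (default 20 mm) and unioned in, so
  unopacified ureter segments stay viewable and both kidneys end up
  connected to the bladder.

Masks are applied by copying in-mask voxels exactly and replacing
everything else with a fill value (default −1024 HU, air). By
construction ``method1 ⊆ method2 ⊆ method3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .register import AffineTransform, RegistrationOptions, RegistrationResult, apply_transform, register
from .volio import KIDNEY, URETER, BLADDER, ImageVolume, LabelVolume

__all__ = [
    "FocusedViewConfig",
    "BridgeSegment",
    "FocusedViewResult",
    "method1_mask",
    "method2_mask",
    "method3_mask",
    "bridge_components",
    "apply_mask",
    "focused_view",
]


@dataclass(frozen=True)
class FocusedViewConfig:
    """Method selector and radii for focused-view mask construction."""

    method: int = 3
    boundary_mm: float = 10.0
    bridge_radius_mm: float = 20.0
    fill_hu: float = -1024.0
    connectivity: int = 26  # 6, 18 or 26-neighbour components

    def __post_init__(self):
        if self.method not in (1, 2, 3):
            raise ValueError(f"method must be 1, 2 or 3, got {self.method}")
        if self.boundary_mm < 0 or self.bridge_radius_mm < 0:
            raise ValueError("radii must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class BridgeSegment:
    """Endpoints (physical mm) of one added straight connection."""

    start_mm: Tuple[float, float, float]
    end_mm: Tuple[float, float, float]

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end_mm) - np.asarray(self.start_mm)))


@dataclass
class FocusedViewResult:
    mask: np.ndarray
    masked_ctu: ImageVolume
    masked_unenhanced: ImageVolume
    bridges: List[BridgeSegment]
    config: FocusedViewConfig
    registration: Optional[RegistrationResult] = None


def method1_mask(labels: LabelVolume) -> np.ndarray:
    """Baseline mask: exactly the segmented voxels (any nonzero class)."""
    return labels.labels > 0


def dilate_mm(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Dilate by a sphere of physical radius: a voxel is set iff its center
    lies within ``radius_mm`` (Euclidean, mm) of a foreground voxel center."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def method2_mask(labels: LabelVolume, boundary_mm: float = 10.0) -> np.ndarray:
    """Expanded-boundary mask: method 1 dilated by ``boundary_mm``."""
    return dilate_mm(method1_mask(labels), boundary_mm, labels.spacing)


def _rasterize_line(p_idx: np.ndarray, q_idx: np.ndarray) -> np.ndarray:
    """Voxel indices of a straight 3-D path; consecutive voxels 26-adjacent."""
    p = np.asarray(p_idx, dtype=float)
    q = np.asarray(q_idx, dtype=float)
    n = int(np.ceil(np.abs(q - p).max())) * 2 + 1
    t = np.linspace(0.0, 1.0, n)
    pts = np.round(p[None, :] + t[:, None] * (q - p)[None, :]).astype(int)
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return pts[keep]


def bridge_components(
    labels: LabelVolume, config: Optional[FocusedViewConfig] = None
) -> Tuple[np.ndarray, List[BridgeSegment]]:
    """Connect a fragmented urinary-tract segmentation with straight paths.

    Connected components of the union of all tract labels are merged
    iteratively: pick a still-disconnected component containing ureter
    voxels (tie-break: smallest voxel count, then lowest lexicographic
    centroid), find the closest voxel-center pair (Euclidean, physical mm)
    between it and the nearest other component, rasterize the straight path
    between them, and merge. Returns the tract mask with the (undilated)
    path voxels added, plus the list of added segments. A connected input
    comes back unchanged with an empty list.

    If the labels contain no kidney or no bladder voxels a warning is
    emitted and remaining components are still connected best-effort.
    """
    config = config or FocusedViewConfig()
    tract = labels.labels > 0
    if not tract.any():
        raise ValueError("labels contain no urinary-tract voxels")
    if not (labels.labels == KIDNEY).any() or not (labels.labels == BLADDER).any():
        warnings.warn(
            "labels lack kidney or bladder voxels; bridging remaining components best-effort",
            stacklevel=2,
        )

    comp, n = ndimage.label(tract, structure=config.structure)
    out = tract.copy()
    segments: List[BridgeSegment] = []
    if n <= 1:
        return out, segments

    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)

    # per-component bookkeeping in physical coordinates
    group_of = {c: c for c in range(1, n + 1)}

    def find(c):
        while group_of[c] != c:
            group_of[c] = group_of[group_of[c]]
            c = group_of[c]
        return c

    idx_by_comp = {}
    has_ureter = {}
    for c in range(1, n + 1):
        ii = np.argwhere(comp == c)
        idx_by_comp[c] = ii
        has_ureter[c] = bool((labels.labels[tuple(ii.T)] == URETER).any())

    def group_members(g):
        return [c for c in range(1, n + 1) if find(c) == g]

    merges = 0
    while merges < n - 1:
        groups = sorted({find(c) for c in range(1, n + 1)})
        if len(groups) <= 1:
            break
        # candidate group: contains ureter voxels if any group does
        stats = []
        for g in groups:
            members = group_members(g)
            pts = np.vstack([idx_by_comp[c] for c in members])
            size = len(pts)
            centroid = tuple(pts.mean(axis=0))
            ureter = any(has_ureter[c] for c in members)
            stats.append((g, size, centroid, ureter, pts))
        ureter_groups = [s for s in stats if s[3]]
        pool = ureter_groups if ureter_groups else stats
        pool.sort(key=lambda s: (s[1], s[2]))
        g_sel, _, _, _, pts_sel = pool[0]

        phys_sel = pts_sel * spacing + origin
        # nearest other group by closest voxel-center pair
        best = None
        for g, _, _, _, pts_o in stats:
            if g == g_sel:
                continue
            phys_o = pts_o * spacing + origin
            tree = cKDTree(phys_o)
            d, j = tree.query(phys_sel, workers=-1)
            k = int(np.argmin(d))
            if best is None or d[k] < best[0]:
                best = (float(d[k]), pts_sel[k], pts_o[j[k]], g)
        _, p_idx, q_idx, g_other = best

        path = _rasterize_line(p_idx, q_idx)
        out[tuple(path.T)] = True
        p_mm = tuple((p_idx * spacing + origin).astype(float))
        q_mm = tuple((q_idx * spacing + origin).astype(float))
        segments.append(BridgeSegment(p_mm, q_mm))
        group_of[find(g_other)] = find(g_sel)
        merges += 1

    return out, segments


def method3_mask(labels: LabelVolume, config: Optional[FocusedViewConfig] = None) -> np.ndarray:
    """Expanded boundary plus bridging: ``method2 ∪ dilate(bridge paths)``.

    Bridge paths are dilated by ``bridge_radius_mm`` independently of the
    method-2 boundary (no double dilation) and unioned in, so the result is
    always a superset of the method-2 mask.
    """
    config = config or FocusedViewConfig()
    m2 = method2_mask(labels, config.boundary_mm)
    bridged, segments = bridge_components(labels, config)
    if not segments:
        return m2
    paths = bridged & ~(labels.labels > 0)
    bridge_dil = dilate_mm(paths, config.bridge_radius_mm, labels.spacing)
    return m2 | bridge_dil


def compute_mask(labels: LabelVolume, config: FocusedViewConfig) -> Tuple[np.ndarray, List[BridgeSegment]]:
    """Dispatch on ``config.method``; returns (mask, bridge segments)."""
    if config.method == 1:
        return method1_mask(labels), []
    if config.method == 2:
        return method2_mask(labels, config.boundary_mm), []
    m2 = method2_mask(labels, config.boundary_mm)
    bridged, segments = bridge_components(labels, config)
    if segments:
        paths = bridged & ~(labels.labels > 0)
        m2 = m2 | dilate_mm(paths, config.bridge_radius_mm, labels.spacing)
    return m2, segments


def apply_mask(volume: ImageVolume, mask: np.ndarray, fill_hu: float = -1024.0) -> ImageVolume:
    """Copy in-mask voxels exactly; set everything outside to ``fill_hu``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.voxels.shape:
        raise ValueError(f"mask grid {mask.shape} does not match volume grid {volume.voxels.shape}")
    out = np.full_like(volume.voxels, fill_hu)
    out[mask] = volume.voxels[mask]
    return ImageVolume(out, volume.spacing, volume.origin)


def focused_view(
    ctu: ImageVolume,
    unenhanced: ImageVolume,
    labels: LabelVolume,
    config: Optional[FocusedViewConfig] = None,
    registration_options: Optional[RegistrationOptions] = None,
    register_unenhanced: bool = True,
) -> FocusedViewResult:
    """Produce the focused-view pair for one case, fully automatically.

    The mask is computed from ``labels`` on the CTU grid; the unenhanced
    volume is registered to the CTU (affine by default, rigid via
    ``registration_options``) and resampled onto the CTU grid before the
    same mask is applied to both volumes.
    """
    config = config or FocusedViewConfig()
    if not labels.same_grid(ctu):
        raise ValueError("labels must share the CTU grid")

    mask, segments = compute_mask(labels, config)

    reg_result = None
    if register_unenhanced:
        reg_result = register(ctu, unenhanced, registration_options)
        unenh_on_ctu = apply_transform(unenhanced, reg_result.transform, ctu, fill_value=config.fill_hu)
    else:
        unenh_on_ctu = apply_transform(
            unenhanced, AffineTransform.identity(), ctu, fill_value=config.fill_hu
        )

    return FocusedViewResult(
        mask=mask,
        masked_ctu=apply_mask(ctu, mask, config.fill_hu),
        masked_unenhanced=apply_mask(unenh_on_ctu, mask, config.fill_hu),
        bridges=segments,
        config=config,
        registration=reg_result,
    )
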