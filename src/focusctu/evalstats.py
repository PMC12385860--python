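"""Coverage-based visibility scoring, diagnostic ratios, agreement, and
concealment checks.

These are automated stand-ins for a human reader assessment: per-organ
*coverage* is the fraction of ground-truth organ voxels that survive the
focused-view mask, mapped onto the ordinal scales readers use —

* 4-point visualization scale: 1 (≤ 75%), 2 (75–95%), 3 (96–99%), 4 (100%);
  implemented as the disjoint bins (−, .75], (.75, .95], (.95, 1), {1}.
* 3-point scale: 1 (substantial parts not visible), 2 (miniscule parts not
  visible), 3 (completely visible); "miniscule" is operationalized as a
  configurable coverage threshold (default 0.95) — a stand-in for human
  judgment, not a claim about it.

Diagnostic accuracy (sensitivity/specificity/PPV/NPV) comes from 2×2
confusion counts with every undefined denominator reported as such, never
silently zero. Cohen's κ measures chance-corrected agreement between two
raters over the same cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volio import BLADDER, KIDNEY, URETER, LabelVolume

__all__ = [
    "OrganVisibility",
    "VisibilityReport",
    "DiagnosticTable",
    "ConcealmentResult",
    "organ_coverage",
    "score_4point",
    "score_3point",
    "diagnostic_metrics",
    "proportion_percent",
    "cohen_kappa",
    "concealment_check",
]

URETER_SEGMENTS = ("proximal", "mid", "distal")


def score_4point(coverage: float, tolerance: float = 0.0) -> int:
    """Map a coverage fraction to the 4-point visualization scale.

    ``tolerance`` widens the "complete" bin to ``coverage >= 1 - tolerance``
    (e.g. half a voxel's worth on tiny organs); the default 0 demands exact
    completeness.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    if coverage >= 1.0 - tolerance:
        return 4
    if coverage > 0.95:
        return 3
    if coverage > 0.75:
        return 2
    return 1


def score_3point(coverage: float, miniscule_threshold: float = 0.95) -> int:
    """Map a coverage fraction to the 3-point scale (3 = completely visible)."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    if not 0.0 < miniscule_threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {miniscule_threshold}")
    if coverage >= 1.0:
        return 3
    if coverage >= miniscule_threshold:
        return 2
    return 1


@dataclass(frozen=True)
class OrganVisibility:
    coverage: float
    score4: int
    score3: int
    n_truth_voxels: int


@dataclass
class VisibilityReport:
    """Per-organ-instance coverage and ordinal scores for one case."""

    instances: Dict[str, OrganVisibility]
    missing: List[str] = field(default_factory=list)

    def complete(self, names: Optional[Sequence[str]] = None) -> bool:
        """True iff every (requested) instance is fully covered."""
        names = names if names is not None else list(self.instances)
        return all(self.instances[n].coverage >= 1.0 for n in names)

    def to_dict(self) -> dict:
        return {
            "instances": {
                k: {
                    "coverage": v.coverage,
                    "score4": v.score4,
                    "score3": v.score3,
                    "n_truth_voxels": v.n_truth_voxels,
                }
                for k, v in self.instances.items()
            },
            "missing": list(self.missing),
        }


def _split_side(mask: np.ndarray, side_grid: Optional[np.ndarray]) -> Dict[str, np.ndarray]:
    """Split an organ-class mask into left/right instances.

    Uses a phantom-provided side grid when available; otherwise connected
    components whose centroids are ordered along x (left = smaller x).
    """
    if side_grid is not None:
        return {"left": mask & (side_grid == 1), "right": mask & (side_grid == 2)}
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return {"left": np.zeros_like(mask), "right": np.zeros_like(mask)}
    if n == 1:
        return {"left": mask, "right": np.zeros_like(mask)}
    cents = ndimage.center_of_mass(mask, lab, range(1, n + 1))
    order = np.argsort([c[0] for c in cents])
    left_ids = {order[i] + 1 for i in range(len(order) // 2)}
    left = np.isin(lab, list(left_ids))
    return {"left": left, "right": mask & ~left}


def organ_coverage(
    truth: LabelVolume,
    mask: np.ndarray,
    ureter_side: Optional[np.ndarray] = None,
    ureter_arclength: Optional[np.ndarray] = None,
    segment_bounds: Tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    score4_tolerance: float = 0.0,
    miniscule_threshold: float = 0.95,
) -> VisibilityReport:
    """Per-instance visible fraction of ground-truth organs under a mask.

    Coverage of an instance is ``|truth voxels ∩ mask| / |truth voxels|``.
    Kidneys and ureters are split into left/right; when a fractional
    arc-length grid is supplied (as the phantom provides) each ureter is
    additionally split into proximal/mid/distal segments at
    ``segment_bounds``, standing in for the anatomical landmarks a reader
    would use. Instances with zero truth voxels are reported as missing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.labels.shape:
        raise ValueError("mask grid does not match truth grid")

    parts: Dict[str, np.ndarray] = {}
    # kidneys: side split by component/centroid (the side grid describes ureters)
    kid = _split_side(truth.labels == KIDNEY, None)
    parts["kidney_left"] = kid["left"]
    parts["kidney_right"] = kid["right"]
    parts["bladder"] = truth.labels == BLADDER

    ur = _split_side(truth.labels == URETER, ureter_side)
    for side in ("left", "right"):
        parts[f"ureter_{side}"] = ur[side]
        if ureter_arclength is not None:
            frac = ureter_arclength
            lo, hi = segment_bounds
            with np.errstate(invalid="ignore"):
                seg_masks = (
                    frac < lo,
                    (frac >= lo) & (frac < hi),
                    frac >= hi,
                )
            for name, seg in zip(URETER_SEGMENTS, seg_masks):
                parts[f"ureter_{side}_{name}"] = ur[side] & seg

    instances: Dict[str, OrganVisibility] = {}
    missing: List[str] = []
    for name, organ in parts.items():
        n_truth = int(organ.sum())
        if n_truth == 0:
            missing.append(name)
            continue
        cov = float((organ & mask).sum() / n_truth)
        instances[name] = OrganVisibility(
            coverage=cov,
            score4=score_4point(cov, score4_tolerance),
            score3=score_3point(cov, miniscule_threshold),
            n_truth_voxels=n_truth,
        )
    return VisibilityReport(instances=instances, missing=missing)


@dataclass(frozen=True)
class DiagnosticTable:
    """2×2 confusion counts with derived diagnostic-accuracy ratios.

    Each ratio is ``None`` when its denominator is zero — an explicit
    undefined state, never a silent 0/0 → 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else 100.0 * num / den

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)


def diagnostic_metrics(table: DiagnosticTable) -> Dict[str, Optional[float]]:
    """The four diagnostic ratios in percent, rounded to one decimal.

    Undefined ratios (zero denominator) are returned as ``None``.
    """
    out = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        v = getattr(table, name)
        out[name] = None if v is None else round(v, 1)
    return out


def proportion_percent(numerator: int, denominator: int) -> float:
    """Exact percentage ``100 * k / n`` (reporting rounds separately)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> Optional[float]:
    """Cohen's κ = (pₒ − pₑ)/(1 − pₑ) between two aligned rating vectors.

    Chance agreement pₑ comes from the marginal category proportions.
    Returns ``None`` when pₑ = 1 (both raters constant on the same single
    category), where κ is undefined.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1-D and of equal length")
    if len(a) < 1:
        raise ValueError("rater vectors must be non-empty")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    po = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(np.dot(pa, pb))
    if pe >= 1.0 - 1e-12:
        return None
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class ConcealmentResult:
    hidden_fraction: Optional[float]
    all_hidden: bool


def concealment_check(incidental_mask: np.ndarray, focused_mask: np.ndarray) -> ConcealmentResult:
    """Fraction of incidental-finding voxels hidden by the focused mask.

    ``all_hidden`` is True iff no incidental voxel survives. An empty
    incidental mask gives an undefined fraction (``None``) and a vacuously
    true flag, with a warning.
    """
    inc = np.asarray(incidental_mask, dtype=bool)
    foc = np.asarray(focused_mask, dtype=bool)
    if inc.shape != foc.shape:
        raise ValueError("grids do not match")
    total = int(inc.sum())
    if total == 0:
        warnings.warn("incidental mask is empty; concealment vacuously true", stacklevel=2)
        return ConcealmentResult(hidden_fraction=None, all_hidden=True)
    hidden = int((inc & ~foc).sum())
    return ConcealmentResult(hidden_fraction=hidden / total, all_hidden=hidden == total)
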