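"""Static-expression symmetry metrics about the facial midsagittal plane.

The midsagittal plane is the perpendicular bisector of the segment joining
the two iris landmarks: it passes through their midpoint and its unit normal
points from the left iris toward the right one. Two per-pair metrics are
computed against it:

* **distance symmetry** d_i — the left landmark is reflected across the
  plane and its distance to the right partner taken; 0 means perfect
  mirror symmetry.
* **angle symmetry** cos θ_i — cosine similarity between the plane normal
  and the right-minus-left pair vector; 1 means perfect symmetry, 0 a pair
  vector perpendicular to the normal.

Both are intrinsic to a single capture (no registration involved); when
values from different sessions are compared, the captures should first be
registered into a common frame so distances share one scale. Per-muscle
summaries average the per-pair values over the pairs lying fully inside a
muscle group, scaled by 100 and rounded for reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .landmarks import FaceTopology, LandmarkSet

__all__ = [
    "MidsagittalPlane",
    "SymmetryReport",
    "midsagittal_plane",
    "reflect_across_plane",
    "distance_symmetry",
    "angle_symmetry",
    "angle_symmetry_flattened",
    "aggregate_by_muscle",
    "compute_symmetry_report",
]

logger = logging.getLogger(__name__)

PairKey = tuple[int, int]


@dataclass(frozen=True)
class MidsagittalPlane:
    """Point + unit normal of the facial symmetry plane."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-12:
            raise ValidationError("plane normal must be unit length (tol 1e-12)")
        p.setflags(write=False)
        n.setflags(write=False)
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class SymmetryReport:
    """Per-pair and per-muscle symmetry values for one capture.

    Per-muscle entries are means over the group's internal pairs scaled by
    ``scale`` and rounded to ``decimals``; groups without any internal pair
    carry ``None``.
    """

    per_pair_distance: dict[PairKey, float]
    per_pair_cosine: dict[PairKey, float]
    per_muscle_distance: dict[int, float | None]
    per_muscle_angle: dict[int, float | None]
    scale: float = 100.0
    decimals: int = 6


def midsagittal_plane(ls: LandmarkSet, topo: FaceTopology) -> MidsagittalPlane:
    """Plane through the iris midpoint, normal along the inter-iris vector."""
    left = ls.points[topo.left_iris_index]
    right = ls.points[topo.right_iris_index]
    diff = right - left
    norm = float(np.linalg.norm(diff))
    if norm < 1e-300:
        raise DegenerateGeometryError("iris landmarks coincide; midsagittal plane undefined")
    return MidsagittalPlane(point=(left + right) / 2.0, normal=diff / norm)


def reflect_across_plane(p: np.ndarray, plane: MidsagittalPlane) -> np.ndarray:
    """Mirror point(s) across the plane: ``p − 2[(p − q)·n]n``."""
    pts = np.asarray(p, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    offset = (pts - plane.point) @ plane.normal
    out = pts - 2.0 * offset[:, None] * plane.normal
    return out[0] if single else out


def distance_symmetry(
    ls: LandmarkSet, topo: FaceTopology, plane: MidsagittalPlane | None = None
) -> dict[PairKey, float]:
    """Per-pair distance ``‖p_R − reflect(p_L)‖``; midline landmarks excluded."""
    plane = plane or midsagittal_plane(ls, topo)
    left = topo.left_indices
    right = topo.right_indices
    reflected = reflect_across_plane(ls.points[left], plane)
    d = np.linalg.norm(ls.points[right] - reflected, axis=1)
    return {pair: float(v) for pair, v in zip(topo.pairs, d)}


def angle_symmetry(
    ls: LandmarkSet, topo: FaceTopology, plane: MidsagittalPlane | None = None
) -> dict[PairKey, float]:
    """Per-pair cosine between the plane normal and the pair vector.

    The pair vector is right-minus-left, and the normal points left→right,
    so perfect symmetry gives +1. Zero-length pair vectors are flagged,
    logged and excluded.
    """
    plane = plane or midsagittal_plane(ls, topo)
    a = ls.points[topo.right_indices] - ls.points[topo.left_indices]
    norms = np.linalg.norm(a, axis=1)
    out: dict[PairKey, float] = {}
    skipped = []
    for pair, vec, nrm in zip(topo.pairs, a, norms):
        if nrm < 1e-300:
            skipped.append(pair)
            continue
        out[pair] = float(np.dot(plane.normal, vec) / nrm)
    if skipped:
        logger.warning("angle symmetry: %d zero-length pair vectors excluded: %s", len(skipped), skipped[:5])
    return out


def angle_symmetry_flattened(
    ls: LandmarkSet, topo: FaceTopology, plane: MidsagittalPlane | None = None
) -> dict[int, float | None]:
    """Per-muscle angle symmetry as one flattened cosine per group.

    Alternative aggregation: the pair vectors of a group's internal pairs
    are stacked against equally many copies of the plane normal and a single
    cosine taken (``Σ n·a_i / (‖n‖√k · √Σ‖a_i‖²)``), instead of averaging
    per-pair cosines. Kept for comparison; the averaged form is the default
    reporting path.
    """
    plane = plane or midsagittal_plane(ls, topo)
    out: dict[int, float | None] = {}
    for group in topo.muscle_groups:
        pairs = topo.group_pairs(group.group_id)
        if not pairs:
            out[group.group_id] = None
            continue
        a = np.array([ls.points[r] - ls.points[l] for l, r in pairs])
        num = float(np.sum(a @ plane.normal))
        den = math.sqrt(len(pairs)) * float(np.linalg.norm(a))
        out[group.group_id] = num / den if den > 0 else None
    return out


def aggregate_by_muscle(
    values: dict[PairKey, float],
    topo: FaceTopology,
    scale: float = 100.0,
    decimals: int = 6,
) -> dict[int, float | None]:
    """Mean per-pair value per muscle group, scaled and rounded.

    Only pairs whose *both* members belong to the group contribute; pairs
    straddling two groups are counted to neither (their number is logged).
    Groups with no eligible pairs map to ``None``.
    """
    out: dict[int, float | None] = {}
    used: set[PairKey] = set()
    for group in topo.muscle_groups:
        pairs = [p for p in topo.group_pairs(group.group_id) if p in values]
        if not pairs:
            out[group.group_id] = None
            continue
        used.update(pairs)
        mean = float(np.mean([values[p] for p in pairs]))
        out[group.group_id] = round(mean * scale, decimals)
    grouped_members = {
        i for g in topo.muscle_groups for i in g.indices
    }
    cross = [
        p for p in values
        if p not in used and (p[0] in grouped_members or p[1] in grouped_members)
    ]
    if cross:
        logger.debug("aggregate_by_muscle: %d pairs not fully inside any group", len(cross))
    return out


def compute_symmetry_report(
    ls: LandmarkSet,
    topo: FaceTopology,
    plane: MidsagittalPlane | None = None,
    scale: float = 100.0,
    decimals: int = 6,
) -> SymmetryReport:
    """Distance and angle symmetry for one capture, aggregated per muscle."""
    plane = plane or midsagittal_plane(ls, topo)
    dist = distance_symmetry(ls, topo, plane)
    cos = angle_symmetry(ls, topo, plane)
    return SymmetryReport(
        per_pair_distance=dist,
        per_pair_cosine=cos,
        per_muscle_distance=aggregate_by_muscle(dist, topo, scale, decimals),
        per_muscle_angle=aggregate_by_muscle(cos, topo, scale, decimals),
        scale=scale,
        decimals=decimals,
    )
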