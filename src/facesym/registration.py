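"""Scale-sweep landmark registration.

Landmark sets captured at different times differ in scale, rotation and
position, and rigid registration alone cannot absorb the scale difference.
The pipeline implemented here therefore: (1) equalises scale by the norm
ratio of the i-th landmark about the coordinate origin, (2) runs a coarse,
correspondence-free global registration (FPFH-style local feature matching +
RANSAC over 3-point samples), (3) refines with point-to-plane ICP. Steps
1-3 are repeated for every swept landmark index i, and the transform with
the smallest inlier RMSE — the root-mean-square of per-index L2 residuals
over all n landmarks — is selected.

Baseline registrations used for method comparison (point-to-point ICP and
point-to-plane ICP from a centroid-difference initial transform, and global
registration alone) run inside the same scale sweep with the same min-RMSE
selection, so the comparison isolates the registration core.

All operations accept either a :class:`~facesym.landmarks.LandmarkSet` or a
plain ``(n, 3)`` array.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    NoConsensusError,
    NoOverlapError,
    RegistrationError,
    ValidationError,
)
from .landmarks import HomogeneousTransform, LandmarkSet

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "scale_factor",
    "apply_scale",
    "estimate_normals",
    "global_registration",
    "icp_point_to_plane",
    "icp_point_to_point",
    "centroid_init_transform",
    "inlier_rmse",
    "umeyama_similarity",
    "register",
    "benchmark_methods",
    "REGISTRATION_METHODS",
]

logger = logging.getLogger(__name__)

REGISTRATION_METHODS = ("proposed", "p2p", "p2plane", "global")


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LandmarkSet):
        return obj.points
    pts = np.asarray(obj, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


def _bbox_diagonal(points: np.ndarray) -> float:
    return float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))


# ---------------------------------------------------------------------------
# Configuration / result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationConfig:
    """Tunable parameters of the registration pipeline.

    ``origin`` is the fixed point of scale matching (the landmark-coordinate
    origin, (0,0,0) by convention). ``sweep_indices`` is an explicit index
    list, or ``"all"`` for every index with step ``sweep_stride``.
    ``icp_max_correspondence_distance`` and the two ``global_*_scale``
    fractions are resolved against the target bounding-box diagonal;
    ``None`` for the ICP gate means 10% of the diagonal.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sweep_indices: str | tuple[int, ...] = "all"
    sweep_stride: int = 1
    normals_k: int = 12
    icp_max_iterations: int = 100
    icp_convergence_tol: float = 1e-8
    icp_max_correspondence_distance: float | None = None
    global_ransac_iterations: int = 100_000
    global_ransac_confidence: float = 0.999
    global_feature_radius_scale: float = 0.25
    global_feature_min_radius_scale: float = 0.06
    global_correspondence_distance_scale: float = 0.05
    feature_normals_k: int = 24
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_stride < 1 or self.normals_k < 3 or self.icp_max_iterations < 1:
            raise ValidationError("counts must be positive (stride ≥ 1, normals_k ≥ 3)")
        if self.icp_convergence_tol <= 0:
            raise ValidationError("icp_convergence_tol must be > 0")
        if not (0 < self.global_feature_radius_scale <= 1) or not (
            0 < self.global_correspondence_distance_scale <= 1
        ):
            raise ValidationError("global_*_scale fractions must lie in (0, 1]")
        if not (0 <= self.global_feature_min_radius_scale < self.global_feature_radius_scale):
            raise ValidationError("feature annulus requires 0 <= min radius < radius")
        if self.global_ransac_iterations < 1:
            raise ValidationError("global_ransac_iterations must be positive")

    def resolve_sweep(self, n: int) -> tuple[int, ...]:
        if self.sweep_indices == "all":
            return tuple(range(0, n, self.sweep_stride))
        idx = tuple(int(i) for i in self.sweep_indices)
        if any(i < 0 or i >= n for i in idx):
            raise ValidationError(f"sweep indices out of range for n={n}")
        if not idx:
            raise ValidationError("sweep_indices must not be empty")
        return idx


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a scale-sweep registration.

    ``transform`` maps source landmarks into the *original* target frame
    (the rigid sweep winner composed with the inverse of its scale
    matching), so it can be applied to any capture of the source session.
    ``inlier_rmse`` and ``per_landmark_residuals`` are reported in the
    scale-matched frame in which the sweep selection happened.
    """

    transform: HomogeneousTransform
    chosen_scale_index: int
    scale_factor: float
    inlier_rmse: float
    per_landmark_residuals: np.ndarray
    method_label: str = "proposed"
    sweep_trace: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        res = np.asarray(self.per_landmark_residuals, dtype=np.float64)
        res.setflags(write=False)
        object.__setattr__(self, "per_landmark_residuals", res)
        combined = math.sqrt(float(np.mean(res**2))) if res.size else 0.0
        if abs(combined - self.inlier_rmse) > 1e-10:
            raise ValidationError(
                f"inlier_rmse {self.inlier_rmse} inconsistent with residuals (expected {combined})"
            )
        if self.sweep_trace and self.inlier_rmse > min(r for _, r in self.sweep_trace) + 1e-12:
            raise ValidationError("inlier_rmse must be the minimum over the sweep trace")

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.matrix.tolist(),
            "scale_factor": self.scale_factor,
            "chosen_scale_index": self.chosen_scale_index,
            "inlier_rmse": self.inlier_rmse,
            "method": self.method_label,
        }


# ---------------------------------------------------------------------------
# Scale matching
# ---------------------------------------------------------------------------

def scale_factor(source, target, i: int, origin: Iterable[float] = (0.0, 0.0, 0.0)) -> float:
    """Norm ratio ``‖s_i − O‖ / ‖t_i − O‖`` of the i-th landmark pair."""
    s = _as_points(source)
    t = _as_points(target)
    if not (0 <= i < s.shape[0] and i < t.shape[0]):
        raise ValidationError(f"landmark index {i} out of range")
    o = np.asarray(list(origin), dtype=np.float64)
    denom = float(np.linalg.norm(t[i] - o))
    if denom < 1e-300:
        raise DegenerateGeometryError(f"target landmark {i} coincides with the origin")
    return float(np.linalg.norm(s[i] - o)) / denom


def apply_scale(ls, factor: float, origin: Iterable[float] = (0.0, 0.0, 0.0)):
    """Scale every landmark by ``factor`` about ``origin``.

    Returns the same type as the input (LandmarkSet or array).
    """
    if factor <= 0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    o = np.asarray(list(origin), dtype=np.float64)
    pts = _as_points(ls)
    scaled = o + factor * (pts - o)
    if isinstance(ls, LandmarkSet):
        return ls.with_points(scaled)
    return scaled


# ---------------------------------------------------------------------------
# Normal estimation
# ---------------------------------------------------------------------------

def estimate_normals(ls, k: int = 12) -> np.ndarray:
    """Per-landmark unit normals from k-nearest-neighbour PCA.

    The normal is the smallest-eigenvalue eigenvector of the neighbourhood
    covariance (self included). Orientation is made camera-facing: flipped
    so the z component is non-negative (ties broken toward +x then +y).
    Degenerate neighbourhoods (rank < 2) fall back to +z with a warning.
    """
    pts = _as_points(ls)
    n = pts.shape[0]
    if k < 3:
        raise ValidationError("normal estimation requires k >= 3")
    if n <= k:
        raise ValidationError(f"normal estimation requires more points ({n}) than neighbours ({k})")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)  # includes the point itself
    neigh = pts[idx]  # (n, k+1, 3)
    centred = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / (k + 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0].copy()  # smallest-eigenvalue direction

    degenerate = eigvals[:, 1] < 1e-12 * np.maximum(eigvals[:, 2], 1e-300)
    if np.any(degenerate):
        logger.warning(
            "normal estimation: %d degenerate neighbourhoods, falling back to +z",
            int(degenerate.sum()),
        )
        normals[degenerate] = (0.0, 0.0, 1.0)

    flip = (normals[:, 2] < 0) | (
        (normals[:, 2] == 0) & ((normals[:, 0] < 0) | ((normals[:, 0] == 0) & (normals[:, 1] < 0)))
    )
    normals[flip] *= -1.0
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# FPFH-style features + RANSAC global registration
# ---------------------------------------------------------------------------

_FPFH_BINS = 11
_FPFH_RADIAL_WEIGHT = 0.3


def _fpfh_features(
    points: np.ndarray, normals: np.ndarray, radius: float, min_radius: float = 0.0
) -> np.ndarray:
    """Simplified FPFH descriptors per point, plus a radial-context channel.

    For each point, pair features (alpha, phi, theta) of the Darboux frame
    are histogrammed over the neighbours in the annulus
    ``min_radius <= d <= radius``, then neighbour histograms are blended
    with inverse-distance weights. Excluding the nearest neighbours matters
    on sparse landmark clouds: at realistic noise levels the direction to a
    very close neighbour is dominated by noise, while mid-range geometry is
    stable. A scale-normalised distance-from-centroid coordinate is appended
    as extra context (rotation-invariant, and strongly discriminative on
    head-shaped clouds). All channels are angle- or ratio-based, so
    descriptors are scale-invariant when the radii scale with the cloud.
    """
    n = points.shape[0]
    k = min(60, n - 1)
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    within = (dist <= radius) & (dist >= min_radius)
    starved = within.sum(axis=1) < 3
    if np.any(starved):  # tiny clouds: fall back to the nearest neighbours
        within[starved, : min(8, k)] = True

    d = points[idx] - points[:, None, :]  # (n, k, 3)
    dn = np.linalg.norm(d, axis=2)
    dn_safe = np.maximum(dn, 1e-300)
    dhat = d / dn_safe[..., None]
    u = np.broadcast_to(normals[:, None, :], d.shape)
    nq = normals[idx]

    v = np.cross(dhat, u)
    vnorm = np.linalg.norm(v, axis=2)
    valid = within & (vnorm > 1e-12) & (dn > 1e-12)
    v = v / np.maximum(vnorm, 1e-300)[..., None]
    w = np.cross(u, v)

    alpha = np.einsum("nkj,nkj->nk", v, nq)  # [-1, 1]
    phi = np.einsum("nkj,nkj->nk", u, dhat)  # [-1, 1]
    theta = np.arctan2(np.einsum("nkj,nkj->nk", w, nq), np.einsum("nkj,nkj->nk", u, nq))

    def _bins(val, lo, hi):
        b = ((val - lo) / (hi - lo) * _FPFH_BINS).astype(np.intp)
        return np.clip(b, 0, _FPFH_BINS - 1)

    spfh = np.zeros((n, 3 * _FPFH_BINS))
    rows = np.broadcast_to(np.arange(n)[:, None], alpha.shape)
    weights = valid.astype(np.float64)
    for f, (val, lo, hi) in enumerate(
        ((alpha, -1.0, 1.0), (phi, -1.0, 1.0), (theta, -math.pi, math.pi))
    ):
        cols = f * _FPFH_BINS + _bins(val, lo, hi)
        np.add.at(spfh, (rows.ravel(), cols.ravel()), weights.ravel())

    # blend neighbour SPFHs with inverse-distance weights
    wgt = np.where(valid, 1.0 / dn_safe, 0.0)
    wsum = np.maximum(wgt.sum(axis=1, keepdims=True), 1e-300)
    fpfh = spfh + np.einsum("nk,nkf->nf", wgt / wsum, spfh[idx])
    norm = np.maximum(fpfh.sum(axis=1, keepdims=True), 1e-300)
    fpfh = fpfh / norm

    centroid = points.mean(axis=0)
    r = np.linalg.norm(points - centroid, axis=1)
    r = r / math.sqrt(max(float(np.mean(r**2)), 1e-300))
    return np.hstack([fpfh, _FPFH_RADIAL_WEIGHT * r[:, None]])


def _feature_correspondences(
    src_feat: np.ndarray, tgt_feat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-way nearest-neighbour matches in descriptor space."""
    tree = cKDTree(tgt_feat)
    _, j = tree.query(src_feat)
    return np.arange(src_feat.shape[0], dtype=np.intp), j.astype(np.intp)


def _kabsch_batch(src3: np.ndarray, tgt3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid fits for batches of 3-point correspondences: (B,3,3) -> R, t."""
    ms = src3.mean(axis=1, keepdims=True)
    mt = tgt3.mean(axis=1, keepdims=True)
    H = np.einsum("bki,bkj->bij", src3 - ms, tgt3 - mt)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("bij,bjk->bik", np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1))))
    D = np.tile(np.eye(3), (src3.shape[0], 1, 1))
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("bji,bjk,blk->bil", Vt, D, U)  # V D U^T
    t = mt[:, 0, :] - np.einsum("bij,bj->bi", R, ms[:, 0, :])
    return R, t


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> HomogeneousTransform:
    R, t = _kabsch_batch(src[None], tgt[None])
    return HomogeneousTransform.from_rotation_translation(R[0], t[0])


def _check_nondegenerate(points: np.ndarray, what: str) -> None:
    if points.shape[0] < 4:
        raise DegenerateGeometryError(f"{what}: need at least 4 points")
    centred = points - points.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise DegenerateGeometryError(f"{what}: points are (near-)collinear")


def global_registration(source, target, cfg: RegistrationConfig | None = None) -> HomogeneousTransform:
    """Coarse rigid alignment without an initial transform.

    FPFH-style descriptors are matched between the clouds and RANSAC over
    3-point correspondence samples maximises the number of matches within
    the correspondence-distance threshold; the winning hypothesis is refit
    on its inlier set. Deterministic for a fixed ``cfg.random_seed``.
    """
    cfg = cfg or RegistrationConfig()
    src = _as_points(source)
    tgt = _as_points(target)
    _check_nondegenerate(src, "global registration source")
    _check_nondegenerate(tgt, "global registration target")

    diag = _bbox_diagonal(tgt)
    ci, cj = _feature_correspondences(*_descriptor_pair(src, tgt, cfg))
    rng = np.random.default_rng(cfg.random_seed)
    return _ransac_alignment(src, tgt, ci, cj, cfg, rng, diag)


def _descriptor_pair(
    src: np.ndarray, tgt: np.ndarray, cfg: RegistrationConfig
) -> tuple[np.ndarray, np.ndarray]:
    feats = []
    for pts in (src, tgt):
        k = min(cfg.feature_normals_k, pts.shape[0] - 1)
        diag = _bbox_diagonal(pts)
        feats.append(
            _fpfh_features(
                pts,
                estimate_normals(pts, max(k, 3)),
                cfg.global_feature_radius_scale * diag,
                cfg.global_feature_min_radius_scale * diag,
            )
        )
    return feats[0], feats[1]


def _ransac_alignment(
    src: np.ndarray,
    tgt: np.ndarray,
    corr_i: np.ndarray,
    corr_j: np.ndarray,
    cfg: RegistrationConfig,
    rng: np.random.Generator,
    diag: float,
) -> HomogeneousTransform:
    threshold = cfg.global_correspondence_distance_scale * diag
    sp = src[corr_i]
    tp = tgt[corr_j]
    m = sp.shape[0]

    best_count = 0
    best_R = None
    best_t = None
    done = 0
    batch = 256
    while done < cfg.global_ransac_iterations:
        b = min(batch, cfg.global_ransac_iterations - done)
        samples = rng.integers(0, m, size=(b, 3))
        done += b
        ok = (
            (samples[:, 0] != samples[:, 1])
            & (samples[:, 0] != samples[:, 2])
            & (samples[:, 1] != samples[:, 2])
        )
        s3 = sp[samples]
        t3 = tp[samples]
        # edge-length consistency prefilter (rigid ⇒ distances preserved)
        for a, b_ in ((0, 1), (0, 2), (1, 2)):
            es = np.linalg.norm(s3[:, a] - s3[:, b_], axis=1)
            et = np.linalg.norm(t3[:, a] - t3[:, b_], axis=1)
            ok &= np.abs(es - et) <= np.maximum(2.0 * threshold, 0.1 * np.maximum(es, et))
            ok &= es > 1e-12
        if not np.any(ok):
            continue
        R, t = _kabsch_batch(s3[ok], t3[ok])
        moved = np.einsum("bij,mj->bmi", R, sp) + t[:, None, :]
        dist2 = np.sum((moved - tp[None]) ** 2, axis=2)
        counts = np.sum(dist2 <= threshold**2, axis=1)
        k = int(np.argmax(counts))
        if counts[k] > best_count:
            best_count = int(counts[k])
            best_R, best_t = R[k], t[k]
        if best_count > 0:
            w = best_count / m
            denom = math.log(max(1.0 - w**3, 1e-12))
            needed = math.log(max(1.0 - cfg.global_ransac_confidence, 1e-12)) / denom
            if done >= needed:
                break

    if best_count < 3 or best_R is None:
        raise NoConsensusError("RANSAC found no consensus set of at least 3 correspondences")

    # refit on the inlier set of the best hypothesis
    moved = sp @ best_R.T + best_t
    inl = np.linalg.norm(moved - tp, axis=1) <= threshold
    if inl.sum() >= 3:
        return _kabsch(sp[inl], tp[inl])
    return HomogeneousTransform.from_rotation_translation(best_R, best_t)


# ---------------------------------------------------------------------------
# ICP refinements
# ---------------------------------------------------------------------------

def _rotvec_matrix(w: np.ndarray) -> np.ndarray:
    """Exact rotation matrix for a rotation vector (Rodrigues)."""
    th = float(np.linalg.norm(w))
    if th < 1e-300:
        return np.eye(3)
    k = w / th
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)


def _resolve_icp_gate(cfg: RegistrationConfig, tgt: np.ndarray) -> float:
    if cfg.icp_max_correspondence_distance is not None:
        return cfg.icp_max_correspondence_distance
    return 0.1 * _bbox_diagonal(tgt)


def _icp_common(source, target, init):
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape[0] != tgt.shape[0]:
        raise ValidationError("ICP here operates on equal-sized landmark sets")
    T = np.array(init.matrix, dtype=np.float64)
    return src, tgt, T


def icp_point_to_plane(
    source,
    target,
    target_normals: np.ndarray,
    init: HomogeneousTransform,
    cfg: RegistrationConfig | None = None,
) -> tuple[HomogeneousTransform, float]:
    """Point-to-plane ICP: minimise distances along target surface normals.

    Each iteration gates nearest-neighbour correspondences at the maximum
    correspondence distance, solves the linearised least-squares problem
    ``Σ [(R·s + t − t_c)·n_c]²`` for a small rotation/translation update
    (applied as an exact rotation via Rodrigues, so R stays orthonormal),
    and stops when the relative change of the correspondence RMSE falls
    below ``icp_convergence_tol``. The returned RMSE is the index-based
    inlier RMSE of the final transform.
    """
    cfg = cfg or RegistrationConfig()
    src, tgt, T = _icp_common(source, target, init)
    normals = np.asarray(target_normals, dtype=np.float64)
    tree = cKDTree(tgt)
    gate = _resolve_icp_gate(cfg, tgt)

    prev = None
    for _ in range(cfg.icp_max_iterations):
        moved = src @ T[:3, :3].T + T[:3, 3]
        dist, j = tree.query(moved, distance_upper_bound=gate)
        mask = np.isfinite(dist)
        if not np.any(mask):
            raise NoOverlapError("no ICP correspondences within the distance threshold")
        p = moved[mask]
        q = tgt[j[mask]]
        nq = normals[j[mask]]
        r = np.einsum("mi,mi->m", p - q, nq)
        rmse = math.sqrt(float(np.mean(dist[mask] ** 2)))

        A = np.hstack([np.cross(p, nq), nq])
        x, *_ = np.linalg.lstsq(A, -r, rcond=None)
        dT = np.eye(4)
        dT[:3, :3] = _rotvec_matrix(x[:3])
        dT[:3, 3] = x[3:]
        T = dT @ T

        if prev is not None and abs(prev - rmse) <= cfg.icp_convergence_tol * max(prev, 1e-30):
            break
        prev = rmse

    transform = HomogeneousTransform(T, kind="rigid")
    rmse_final, _ = inlier_rmse(src, tgt, transform)
    return transform, rmse_final


def icp_point_to_point(
    source,
    target,
    init: HomogeneousTransform,
    cfg: RegistrationConfig | None = None,
) -> tuple[HomogeneousTransform, float]:
    """Point-to-point ICP with the closed-form SVD (Kabsch) update."""
    cfg = cfg or RegistrationConfig()
    src, tgt, T = _icp_common(source, target, init)
    tree = cKDTree(tgt)
    gate = _resolve_icp_gate(cfg, tgt)

    prev = None
    for _ in range(cfg.icp_max_iterations):
        moved = src @ T[:3, :3].T + T[:3, 3]
        dist, j = tree.query(moved, distance_upper_bound=gate)
        mask = np.isfinite(dist)
        if not np.any(mask):
            raise NoOverlapError("no ICP correspondences within the distance threshold")
        rmse = math.sqrt(float(np.mean(dist[mask] ** 2)))
        if mask.sum() >= 3:
            T = _kabsch(src[mask], tgt[j[mask]]).matrix
        if prev is not None and abs(prev - rmse) <= cfg.icp_convergence_tol * max(prev, 1e-30):
            break
        prev = rmse

    transform = HomogeneousTransform(T, kind="rigid")
    rmse_final, _ = inlier_rmse(src, tgt, transform)
    return transform, rmse_final


def centroid_init_transform(source, target) -> HomogeneousTransform:
    """Identity rotation with translation ``Σ(s_j − t_j)/N`` per coordinate.

    This is the frontal-face initial transform convention used for the ICP
    baselines; the sign convention (source minus target) is kept exactly as
    printed in the method it reproduces.
    """
    s = _as_points(source)
    t = _as_points(target)
    if s.shape != t.shape:
        raise ValidationError("centroid init requires equal-sized landmark sets")
    if s.shape[0] == 0:
        raise ValidationError("centroid init requires non-empty landmark sets")
    translation = (s - t).mean(axis=0)
    return HomogeneousTransform.from_rotation_translation(np.eye(3), translation)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def inlier_rmse(source, target, transform: HomogeneousTransform) -> tuple[float, np.ndarray]:
    """Index-based inlier RMSE: ``√(Σ‖T·s_i − t_i‖² / n)`` and the residuals.

    Landmark indices carry anatomical identity, so the i-th source landmark
    is compared with the i-th target landmark; no residual cutoff is applied.
    """
    s = _as_points(source)
    t = _as_points(target)
    if s.shape != t.shape:
        raise ValidationError("inlier RMSE requires equal-sized landmark sets")
    residuals = np.linalg.norm(transform.apply(s) - t, axis=1)
    return math.sqrt(float(np.mean(residuals**2))), residuals


def umeyama_similarity(source, target) -> tuple[HomogeneousTransform, float]:
    """Closed-form least-squares similarity fit (independent of the sweep).

    Uses the SVD of the cross-covariance of the index-corresponding point
    sets; serves as the lower-bound oracle for registration quality.
    """
    s = _as_points(source)
    t = _as_points(target)
    if s.shape != t.shape or s.shape[0] < 3:
        raise ValidationError("Umeyama fit requires equal-sized sets of at least 3 points")
    n = s.shape[0]
    ms, mt = s.mean(axis=0), t.mean(axis=0)
    sc, tc = s - ms, t - mt
    var_s = float(np.mean(np.sum(sc**2, axis=1)))
    if var_s < 1e-300:
        raise DegenerateGeometryError("source points are coincident")
    cov = tc.T @ sc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    c = float(np.trace(np.diag(D) @ S)) / var_s
    if c <= 0:
        raise DegenerateGeometryError("degenerate configuration: non-positive similarity scale")
    m = np.eye(4)
    m[:3, :3] = c * R
    m[:3, 3] = mt - c * R @ ms
    transform = HomogeneousTransform(m, kind="similarity")
    rmse, _ = inlier_rmse(s, t, transform)
    return transform, rmse


# ---------------------------------------------------------------------------
# The scale sweep
# ---------------------------------------------------------------------------

def _sweep(
    source,
    target,
    cfg: RegistrationConfig,
    methods: Sequence[str],
) -> dict[str, RegistrationResult]:
    src_ls = source if isinstance(source, LandmarkSet) else None
    tgt_ls = target if isinstance(target, LandmarkSet) else None
    if src_ls is not None and tgt_ls is not None and src_ls.mode != tgt_ls.mode:
        raise ValidationError("source and target landmark sets must share a topology mode")
    for mth in methods:
        if mth not in REGISTRATION_METHODS:
            raise ValidationError(f"unknown registration method {mth!r}")

    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise ValidationError("registration requires equal-sized landmark sets")
    _check_nondegenerate(src, "registration source")
    _check_nondegenerate(tgt, "registration target")

    origin = np.asarray(cfg.origin, dtype=np.float64)
    sweep = cfg.resolve_sweep(src.shape[0])
    needs_global = any(m in ("proposed", "global") for m in methods)
    needs_normals = any(m in ("proposed", "p2plane") for m in methods)

    # scale-invariant precomputations (descriptors and normals do not change
    # under a positive isotropic rescale of the target)
    tgt_normals = estimate_normals(tgt, cfg.normals_k) if needs_normals else None
    corr = None
    if needs_global:
        corr = _feature_correspondences(*_descriptor_pair(src, tgt, cfg))

    traces: dict[str, list[tuple[int, float]]] = {m: [] for m in methods}
    best: dict[str, tuple[float, int, float, np.ndarray]] = {}
    failures: dict[int, str] = {}

    for i in sweep:
        try:
            c = scale_factor(src, tgt, i, origin)
            tgt_scaled = origin + c * (tgt - origin)
        except (DegenerateGeometryError, ValidationError) as exc:
            failures[i] = str(exc)
            continue
        diag_scaled = _bbox_diagonal(tgt_scaled)

        T_global = None
        if needs_global:
            rng = np.random.default_rng(np.random.SeedSequence([max(cfg.random_seed, 0), i]))
            try:
                T_global = _ransac_alignment(src, tgt_scaled, corr[0], corr[1], cfg, rng, diag_scaled)
            except RegistrationError as exc:
                failures[i] = str(exc)
                T_global = None

        for mth in methods:
            try:
                if mth == "proposed":
                    if T_global is None:
                        continue
                    T, rmse = icp_point_to_plane(src, tgt_scaled, tgt_normals, T_global, cfg)
                elif mth == "global":
                    if T_global is None:
                        continue
                    T = T_global
                    rmse, _ = inlier_rmse(src, tgt_scaled, T)
                elif mth == "p2plane":
                    T0 = centroid_init_transform(src, tgt_scaled)
                    T, rmse = icp_point_to_plane(src, tgt_scaled, tgt_normals, T0, cfg)
                else:  # p2p
                    T0 = centroid_init_transform(src, tgt_scaled)
                    T, rmse = icp_point_to_point(src, tgt_scaled, T0, cfg)
            except RegistrationError as exc:
                failures[i] = str(exc)
                continue
            traces[mth].append((i, rmse))
            cur = best.get(mth)
            if cur is None or rmse < cur[0]:
                _, residuals = inlier_rmse(src, tgt_scaled, T)
                best[mth] = (rmse, i, c, T.matrix, residuals)

    results: dict[str, RegistrationResult] = {}
    for mth in methods:
        if mth not in best:
            detail = "; ".join(f"index {i}: {msg}" for i, msg in sorted(failures.items())[:5])
            raise RegistrationError(
                f"every sweep iteration failed for method {mth!r} ({len(failures)} failures: {detail})"
            )
        rmse, i, c, T, residuals = best[mth]
        # compose the rigid winner with the inverse scale matching so the
        # stored transform maps source landmarks into the original target frame
        unscale = HomogeneousTransform.from_scale(1.0 / c, origin)
        composite = unscale.compose(HomogeneousTransform(T, kind="rigid"))
        results[mth] = RegistrationResult(
            transform=composite,
            chosen_scale_index=i,
            scale_factor=c,
            inlier_rmse=rmse,
            per_landmark_residuals=residuals,
            method_label=mth,
            sweep_trace=tuple(traces[mth]),
        )
    return results


def register(
    source,
    target,
    cfg: RegistrationConfig | None = None,
    method: str = "proposed",
) -> RegistrationResult:
    """Scale-sweep registration of ``source`` onto ``target``.

    For every swept landmark index i the target is rescaled by the i-th
    norm ratio, the selected registration core is run, and the index-based
    inlier RMSE recorded; the minimum-RMSE transform wins. ``method``
    selects the core: ``"proposed"`` (global registration + point-to-plane
    ICP), ``"p2plane"`` / ``"p2p"`` (ICP from the centroid init), or
    ``"global"`` (coarse registration alone).
    """
    cfg = cfg or RegistrationConfig()
    return _sweep(source, target, cfg, (method,))[method]


def benchmark_methods(
    source,
    target,
    cfg: RegistrationConfig | None = None,
    methods: Sequence[str] = REGISTRATION_METHODS,
) -> dict[str, RegistrationResult]:
    """Run several registration cores over one shared scale sweep.

    Used for method-comparison tables; per-index work (scale matching,
    normals, descriptors, the coarse transform) is shared across methods.
    """
    cfg = cfg or RegistrationConfig()
    return _sweep(source, target, cfg, tuple(methods))
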