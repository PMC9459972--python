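"""Procedural synthetic faces: the test bed for registration and metrics.

Patient captures are not distributable, so the package carries a procedural
stand-in: a mirror-symmetric "neutral" face template laid out on a smooth
parametric head surface, plus a deformation model that produces smile
captures, one-sided palsy (multiplicative attenuation of the smile
displacement field), static structural asymmetry, isotropic landmark noise,
and an optional similarity transform emulating a different camera pose.

The template is built for the half-face and mirrored across ``x = 0``, so it
is *exactly* mirror-symmetric in floating point: paired landmarks differ only
in the sign of x, midline landmarks lie exactly on ``x = 0``. Coordinates are
dimensionless model units emulating the unit-normalised output of a face-mesh
detector; the face spans roughly 0.85 x 1.0 units centred near the origin.

Everything here is a deterministic function of its configuration and seed,
and every generated capture comes with its ground truth (displacement field,
similarity transform) so registration and metric tests can compare against
values known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .landmarks import (
    MODE_COUNTS,
    MUSCLE_GROUP_NAMES,
    FaceTopology,
    HomogeneousTransform,
    LandmarkSet,
    topology_from_dict,
)

__all__ = [
    "FACE_SCALE",
    "SimilarityParams",
    "SyntheticFaceConfig",
    "SyntheticCapture",
    "SyntheticSession",
    "RegistrationCase",
    "build_layout",
    "generate_template",
    "apply_expression",
    "generate_session",
    "similarity_transform",
    "registration_benchmark_cases",
]

#: conversion from the internal "face units" of the layout tables below
#: (face ~17 wide, ~21 tall) to model units (face ~0.85 wide).
FACE_SCALE = 0.05

# mouth-corner centre of the smile displacement field, in face units
_MOUTH_CORNER = (2.6, -3.0)
_SMILE_WIDTH = 2.2  # Gaussian falloff s.d. of the smile field, face units
_SMILE_DIR = (0.8, 0.55, 0.2)  # (outward, upward, forward) direction weights


def _depth(x: float, y: float) -> float:
    """Camera-facing depth of the head surface at (x, y), face units.

    An elliptical dome plus a nose bump; depends on x only through x**2 so
    mirrored points get bit-identical depths.
    """
    r2 = 1.0 - (x / 9.0) ** 2 - (y / 11.0) ** 2
    base = 6.0 * math.sqrt(max(0.0, r2))
    nose = 2.2 * math.exp(-((x / 1.6) ** 2 + ((y + 1.5) / 2.8) ** 2))
    return base + nose


class _LayoutBuilder:
    """Accumulates template points together with their topology roles."""

    def __init__(self) -> None:
        self.points: list[tuple[float, float, float]] = []
        self.pairs: list[tuple[int, int]] = []
        self.midline: list[int] = []
        self.groups: dict[str, list[int]] = {name: [] for name in MUSCLE_GROUP_NAMES}
        self.iris: dict[str, int] = {}

    def add_pair(
        self,
        x: float,
        y: float,
        group: str | None = None,
        stray: bool = False,
        z: float | None = None,
    ) -> tuple[int, int]:
        """Add a mirrored landmark pair; ``x`` is the right-side abscissa (> 0).

        With ``stray=True`` only the left member joins ``group`` (the paper's
        per-group landmark counts are left/right-asymmetric for some lateral
        muscles, so the authored topology reproduces that)."""
        if x <= 0:
            raise ValueError("pair abscissa must be positive")
        zz = _depth(x, y) if z is None else z
        il = len(self.points)
        self.points.append((-x, y, zz))
        ir = il + 1
        self.points.append((x, y, zz))
        self.pairs.append((il, ir))
        if group is not None:
            self.groups[group].append(il)
            if not stray:
                self.groups[group].append(ir)
        return il, ir

    def add_mid(self, y: float, group: str | None = None, z: float | None = None) -> int:
        zz = _depth(0.0, y) if z is None else z
        i = len(self.points)
        self.points.append((0.0, y, zz))
        self.midline.append(i)
        if group is not None:
            self.groups[group].append(i)
        return i

    def to_dict(self, mode: str) -> dict:
        return {
            "mode": mode,
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
            "iris": {"left": self.iris["left"], "right": self.iris["right"]},
            "muscle_groups": [
                {"id": k + 1, "name": name, "indices": sorted(self.groups[name])}
                for k, name in enumerate(MUSCLE_GROUP_NAMES)
            ],
        }


def _ellipse_points(a: float, b: float, cy: float, n: int) -> list[tuple[float, float]]:
    """n points on an axis-aligned ellipse centred at (0, cy)."""
    return [
        (a * math.cos(2.0 * math.pi * k / n), cy + b * math.sin(2.0 * math.pi * k / n))
        for k in range(n)
    ]


def _scatter_fill(builder: _LayoutBuilder, n_pairs: int, min_dist: float = 0.32) -> None:
    """Fill the half-face with quasi-uniform generic landmark pairs.

    Uses the 2D low-discrepancy R2 sequence, rejecting candidates outside the
    face ellipse or closer than ``min_dist`` (face units) to any existing
    point. Deterministic.
    """
    existing = [(abs(px), py) for px, py, _ in builder.points]
    accepted: list[tuple[float, float]] = []
    g = 1.32471795724474602596  # plastic constant; R2 sequence generator
    a1, a2 = 1.0 / g, 1.0 / g**2
    j = 0
    while len(accepted) < n_pairs:
        j += 1
        u = (0.5 + a1 * j) % 1.0
        v = (0.5 + a2 * j) % 1.0
        x = 0.35 + u * (8.3 - 0.35)
        y = -9.8 + v * 19.5
        if (x / 9.0) ** 2 + (y / 11.0) ** 2 > 0.93:
            continue
        ok = True
        for ex, ey in existing + accepted:
            if (x - ex) ** 2 + (y - ey) ** 2 < min_dist**2:
                ok = False
                break
        if ok:
            accepted.append((x, y))
    for x, y in accepted:
        builder.add_pair(x, y)


def _build_layout_478() -> dict:
    b = _LayoutBuilder()

    # 1. Frontalis — forehead band, 3 pairs
    for x in (1.5, 3.0, 4.5):
        b.add_pair(x, 6.5, group="Frontalis")
    # 2./3. Corrugator and Procerus — single midline landmarks at the glabella
    b.add_mid(3.4, group="Corrugator")
    b.add_mid(2.6, group="Procerus")
    # 4. Orbicularis Oculi — two rings around each eye + inner/outer canthus
    ex, ey = 3.0, 2.5
    for k in range(16):
        th = 2.0 * math.pi * k / 16
        b.add_pair(ex + 1.3 * math.cos(th), ey + 1.3 * math.sin(th), group="Orbicularis Oculi")
    for k in range(12):
        th = 2.0 * math.pi * (k + 0.5) / 12
        b.add_pair(ex + 1.9 * math.cos(th), ey + 1.9 * math.sin(th), group="Orbicularis Oculi")
    b.add_pair(0.8, ey, group="Orbicularis Oculi")          # inner canthus
    b.add_pair(5.6, ey, group="Orbicularis Oculi", stray=True)  # outer canthus (59 = 29 pairs + 1)
    # 5. Levator Labii Superioris (+ Alaeque Nasi) — 5 pairs beside the nose
    for k, x in enumerate((1.0, 1.5, 2.0, 2.5, 3.0)):
        b.add_pair(x, -0.9 - 0.15 * k, group="Levator Labii Superioris")
    # 6. Nasalis — 3 pairs on the nose sides
    for x in (0.9, 1.2, 1.5):
        b.add_pair(x, 0.6, group="Nasalis")
    # 7. Nose Tip — ridge midline + alae/tip ring (32 = 14 pairs + 4 midline)
    for y in (1.6, 0.6, -0.4, -1.2):
        b.add_mid(y, group="Nose Tip")
    for x in (0.45, 0.75):
        for y in (1.4, 0.6, -0.2):
            b.add_pair(x, y, group="Nose Tip")
    for x in (0.5, 1.0, 1.4, 1.7):
        b.add_pair(x, -1.0, group="Nose Tip")
    for x in (0.6, 1.1, 1.5):
        b.add_pair(x, -1.6, group="Nose Tip")
    b.add_pair(0.4, -2.0, group="Nose Tip")
    # 8. Orbicularis Oris — outer and inner lip contours (44 = 20 pairs + 4 midline)
    for a_, b_, n in ((2.6, 1.1, 24), (1.9, 0.55, 20)):
        for x, y in _ellipse_points(a_, b_, -3.0, n):
            if abs(x) < 1e-12:
                b.add_mid(y, group="Orbicularis Oris")
            elif x > 0:
                b.add_pair(x, y, group="Orbicularis Oris")
    # 9. Mentalis — chin (6 = 2 pairs + 2 midline)
    b.add_mid(-6.2, group="Mentalis")
    b.add_mid(-7.0, group="Mentalis")
    b.add_pair(0.9, -6.4, group="Mentalis")
    b.add_pair(0.9, -7.1, group="Mentalis")
    # 10. Depressor Anguli Oris — 4 pairs below the mouth corners
    for x, y in ((2.3, -4.4), (2.9, -4.7), (2.0, -5.1), (2.6, -5.4)):
        b.add_pair(x, y, group="Depressor Anguli Oris")
    # 11./12. Zygomaticus Minor / Major — cheek diagonals
    for x, y in ((2.2, -1.6), (2.7, -1.1), (3.2, -0.6)):
        b.add_pair(x, y, group="Zygomaticus Minor")
    b.add_pair(3.8, -1.9, group="Zygomaticus Major")
    b.add_pair(4.3, -2.4, group="Zygomaticus Major", stray=True)
    # 13. Buccinator — 2 pairs lateral to the mouth
    for x, y in ((3.5, -3.1), (4.1, -3.4)):
        b.add_pair(x, y, group="Buccinator")
    # 14. Risorius — near the mouth corner (3 = 1 pair + 1 stray)
    b.add_pair(3.0, -3.3, group="Risorius")
    b.add_pair(3.6, -3.6, group="Risorius", stray=True)
    # 15. Platysma — below the jaw (5 = 2 pairs + 1 stray)
    b.add_pair(1.4, -8.3, group="Platysma")
    b.add_pair(2.4, -8.0, group="Platysma")
    b.add_pair(3.2, -7.7, group="Platysma", stray=True)
    # 16. Masseter — jaw angle (9 = 4 pairs + 1 stray)
    for x, y in ((5.1, -3.6), (5.6, -4.3), (4.9, -4.9), (5.4, -5.5)):
        b.add_pair(x, y, group="Masseter")
    b.add_pair(5.9, -3.9, group="Masseter", stray=True)
    # 17. Temporalis — temple grid, 8 pairs
    for x in (5.6, 6.4):
        for y in (1.6, 2.6, 3.6, 4.6):
            b.add_pair(x, y, group="Temporalis")

    # generic (ungrouped) face-surface landmarks: 8 midline + filler pairs
    for y in (9.3, 8.1, 7.2, 5.4, 4.3, -5.3, -8.6, -9.5):
        b.add_mid(y)
    # fill to 468 facial landmarks, leaving 10 indices for the iris block
    n_fill = (MODE_COUNTS["full_478"] - 10 - len(b.points)) // 2
    _scatter_fill(b, n_fill)

    # iris landmarks last (indices 468..477): centre + 4-point ring per eye
    il, ir = b.add_pair(ex, ey, z=_depth(ex, ey) - 0.15)
    b.iris = {"left": il, "right": ir}
    for th in (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi):
        b.add_pair(
            ex + 0.45 * math.cos(th),
            ey + 0.45 * math.sin(th),
            z=_depth(ex, ey) - 0.15,
        )
    return b


def _build_layout_68() -> dict:
    b = _LayoutBuilder()
    ex, ey = 3.0, 2.5
    # groups (Table-2-style cardinalities; most groups are empty in 68 mode)
    b.add_pair(0.5, 2.8, group="Procerus")
    b.add_pair(ex - 1.4, ey, group="Orbicularis Oculi")
    b.add_pair(ex + 1.4, ey, group="Orbicularis Oculi")
    b.add_pair(ex, ey + 0.9, group="Orbicularis Oculi")
    b.add_pair(1.0, 0.5, group="Nasalis")
    b.add_mid(-0.6, group="Nose Tip")
    b.add_pair(0.8, -0.9, group="Nose Tip")
    for a_, b_, n in ((2.6, 1.1, 8), (1.9, 0.55, 4)):
        for x, y in _ellipse_points(a_, b_, -3.0, n):
            if abs(x) < 1e-12:
                b.add_mid(y, group="Orbicularis Oris")
            elif x > 0:
                b.add_pair(x, y, group="Orbicularis Oris")
    b.add_pair(2.4, -4.8, group="Depressor Anguli Oris")
    b.add_pair(2.0, -8.2, group="Platysma")
    b.add_pair(5.4, -3.8, group="Masseter")
    b.add_pair(5.8, -4.6, group="Masseter")
    b.add_pair(6.2, 3.5, group="Temporalis", stray=True)
    # iris surrogate: one eye-centre pair
    il, ir = b.add_pair(ex, ey, z=_depth(ex, ey) - 0.15)
    b.iris = {"left": il, "right": ir}
    # generic structure: midline profile + jaw/brow scatter
    for y in (9.0, 6.5, 1.8, -1.8, -6.5):
        b.add_mid(y)
    for x, y in (
        (1.8, 6.3), (3.6, 6.1), (2.2, 4.2), (4.3, 4.0),
        (6.8, 0.5), (6.4, -1.8), (5.6, -5.8), (4.4, -7.2),
        (3.0, -8.6), (1.5, -9.3), (7.2, 2.4), (1.6, 1.4), (4.6, -0.8),
    ):
        b.add_pair(x, y)
    return b


_LAYOUT_BUILDERS = {"full_478": _build_layout_478, "compact_68": _build_layout_68}


def build_layout(mode: str) -> tuple[np.ndarray, dict]:
    """Template coordinates (model units) and topology dict for ``mode``.

    This is the single source of truth from which the bundled topology
    resource files are generated.
    """
    if mode not in _LAYOUT_BUILDERS:
        raise ValidationError(f"unknown topology mode {mode!r}")
    builder = _LAYOUT_BUILDERS[mode]()
    pts = np.asarray(builder.points, dtype=np.float64) * FACE_SCALE
    expected = MODE_COUNTS[mode]
    if pts.shape[0] != expected:  # layout bookkeeping guard
        raise AssertionError(f"layout for {mode} produced {pts.shape[0]} points, expected {expected}")
    return pts, builder.to_dict(mode)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityParams:
    """Ground-truth similarity pose: ``p -> scale * R(rotation) * p + translation``."""

    scale: float = 1.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # extrinsic x, y, z
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> HomogeneousTransform:
        return similarity_transform(self.scale, self.rotation_deg, self.translation)


def _euler_rotation(rotation_deg: Sequence[float]) -> np.ndarray:
    rx, ry, rz = (math.radians(a) for a in rotation_deg)
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def similarity_transform(
    scale: float = 1.0,
    rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
    translation: Sequence[float] = (0.0, 0.0, 0.0),
) -> HomogeneousTransform:
    """Similarity transform ``p -> scale·R·p + t`` as a HomogeneousTransform."""
    if scale <= 0:
        raise ValidationError("scale must be positive")
    m = np.eye(4)
    m[:3, :3] = scale * _euler_rotation(rotation_deg)
    m[:3, 3] = np.asarray(list(translation), dtype=np.float64)
    kind = "rigid" if abs(scale - 1.0) < 1e-15 else "similarity"
    return HomogeneousTransform(m, kind=kind)


@dataclass(frozen=True)
class SyntheticFaceConfig:
    """Conditions for one synthetic capture.

    ``expression_amplitude`` (g) is the peak smile displacement in model
    units (default 0.08 ≈ a 1.5 cm corner excursion on a real face);
    ``palsy_attenuation`` (α) multiplies the smile displacement on
    ``palsy_side`` (1 = healthy, 0 = complete palsy); ``asymmetry_jitter``
    is the s.d. of static structural asymmetry added to the palsy side;
    ``noise_sd`` (σ) is isotropic Gaussian landmark noise; ``transform`` is
    the capture pose, applied last.
    """

    mode: str = "full_478"
    expression_amplitude: float = 0.08
    palsy_side: str = "none"  # {"left", "right", "none"}
    palsy_attenuation: float = 1.0
    asymmetry_jitter: float = 0.0
    noise_sd: float = 0.0
    transform: SimilarityParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.palsy_attenuation <= 1.0:
            raise ValidationError("palsy_attenuation must lie in [0, 1]")
        if self.expression_amplitude < 0 or self.asymmetry_jitter < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes and standard deviations must be non-negative")
        if self.palsy_side not in ("left", "right", "none"):
            raise ValidationError("palsy_side must be 'left', 'right' or 'none'")
        if self.mode not in MODE_COUNTS:
            raise ValidationError(f"unknown topology mode {self.mode!r}")


@dataclass(frozen=True)
class SyntheticCapture:
    """A generated capture plus its ground truth (in template frame)."""

    landmarks: LandmarkSet
    displacement: np.ndarray  # (n, 3) smile displacement after palsy, pre-noise
    transform: HomogeneousTransform  # the applied pose (identity if none)


@dataclass(frozen=True)
class SyntheticSession:
    neutral: SyntheticCapture
    smile: SyntheticCapture
    template: LandmarkSet
    topology: FaceTopology


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_template(mode: str = "full_478", seed: int = 0) -> tuple[LandmarkSet, FaceTopology]:
    """The neutral, exactly mirror-symmetric face template for ``mode``.

    The template geometry is fixed (seed-independent); ``seed`` is accepted
    for interface symmetry with the stochastic generators and recorded in the
    subject id.
    """
    pts, layout = build_layout(mode)
    topo = topology_from_dict(layout)
    ls = LandmarkSet(
        points=pts,
        subject_id=f"synthetic-{seed}",
        session_label="template",
        expression="neutral",
        mode=mode,
    )
    return ls, topo


def _smile_field(points: np.ndarray, amplitude: float) -> np.ndarray:
    """Mirror-symmetric smile displacement field, evaluated per landmark.

    Gaussian falloff around the mouth corners; direction outward (away from
    the midline), upward and slightly forward. Exactly equivariant under
    x-mirroring: mirrored points receive mirrored displacements bit-for-bit.
    """
    cx, cy = _MOUTH_CORNER[0] * FACE_SCALE, _MOUTH_CORNER[1] * FACE_SCALE
    cz = _depth(*_MOUTH_CORNER) * FACE_SCALE
    width = _SMILE_WIDTH * FACE_SCALE
    dx = np.abs(points[:, 0]) - cx
    dy = points[:, 1] - cy
    dz = points[:, 2] - cz
    w = np.exp(-(dx**2 + dy**2 + dz**2) / (2.0 * width**2))
    disp = np.empty_like(points)
    disp[:, 0] = _SMILE_DIR[0] * np.sign(points[:, 0])
    disp[:, 1] = _SMILE_DIR[1]
    disp[:, 2] = _SMILE_DIR[2]
    return amplitude * w[:, None] * disp


def _side_indices(topo: FaceTopology, side: str) -> np.ndarray:
    return topo.left_indices if side == "left" else topo.right_indices


def apply_expression(
    template: LandmarkSet, topo: FaceTopology, cfg: SyntheticFaceConfig
) -> SyntheticCapture:
    """Deform the neutral template into a capture under ``cfg``.

    Order of operations: smile displacement (mirror-symmetric, peak
    ``expression_amplitude``) → palsy attenuation of the affected side →
    static asymmetry jitter on the affected side → isotropic noise →
    similarity pose. Jitter is drawn from a stream keyed by ``seed`` only
    (structural: identical across captures of one subject); noise is keyed
    by ``(seed, expression)`` so neutral and smile captures of one session
    get independent noise.
    """
    if template.mode != cfg.mode or topo.mode != cfg.mode:
        raise ValidationError("template, topology and config modes must agree")
    pts = np.array(template.points)

    disp = _smile_field(pts, cfg.expression_amplitude)
    if cfg.palsy_side != "none" and cfg.palsy_attenuation != 1.0:
        idx = _side_indices(topo, cfg.palsy_side)
        disp[idx] *= cfg.palsy_attenuation
    pts = pts + disp

    if cfg.asymmetry_jitter > 0 and cfg.palsy_side != "none":
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        idx = _side_indices(topo, cfg.palsy_side)
        pts[idx] += cfg.asymmetry_jitter * rng.standard_normal((idx.size, 3))

    expression = "smile" if cfg.expression_amplitude > 0 else "neutral"
    if cfg.noise_sd > 0:
        expr_code = 1 if expression == "smile" else 0
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202, expr_code]))
        pts = pts + cfg.noise_sd * rng.standard_normal(pts.shape)

    transform = cfg.transform.matrix() if cfg.transform is not None else HomogeneousTransform.identity()
    if cfg.transform is not None:
        pts = transform.apply(pts)

    ls = LandmarkSet(
        points=pts,
        subject_id=template.subject_id,
        session_label=template.session_label,
        expression=expression,
        mode=cfg.mode,
    )
    return SyntheticCapture(landmarks=ls, displacement=disp, transform=transform)


def generate_session(
    mode: str = "full_478",
    seed: int = 0,
    expression_amplitude: float = 0.08,
    palsy_side: str = "none",
    palsy_attenuation: float = 1.0,
    asymmetry_jitter: float = 0.0,
    noise_sd: float = 0.0,
    neutral_transform: SimilarityParams | None = None,
    smile_transform: SimilarityParams | None = None,
    subject_id: str | None = None,
    session_label: str = "session1",
) -> SyntheticSession:
    """A matched neutral + smile capture pair for one synthetic session."""
    template, topo = generate_template(mode, seed)
    if subject_id is not None:
        template = LandmarkSet(
            points=template.points,
            subject_id=subject_id,
            session_label=session_label,
            expression="neutral",
            mode=mode,
        )
    common = dict(
        mode=mode,
        palsy_side=palsy_side,
        palsy_attenuation=palsy_attenuation,
        asymmetry_jitter=asymmetry_jitter,
        noise_sd=noise_sd,
        seed=seed,
    )
    neutral = apply_expression(
        template, topo, SyntheticFaceConfig(expression_amplitude=0.0, transform=neutral_transform, **common)
    )
    smile = apply_expression(
        template, topo, SyntheticFaceConfig(expression_amplitude=expression_amplitude, transform=smile_transform, **common)
    )
    return SyntheticSession(neutral=neutral, smile=smile, template=template, topology=topo)


# ---------------------------------------------------------------------------
# Registration benchmark conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationCase:
    """One synthetic registration problem with its ground truth."""

    case_id: int
    source: LandmarkSet
    target: LandmarkSet
    true_transform: HomogeneousTransform  # maps source onto the noise-free target
    noise_sd: float


#: noise levels cycled through the benchmark cases (model units)
BENCHMARK_NOISE_LEVELS = (0.0, 0.005, 0.01)


def registration_benchmark_cases(
    n_cases: int = 20, base_seed: int = 0, mode: str = "full_478"
) -> list[RegistrationCase]:
    """The fixed conditions of the synthetic registration benchmark.

    Case k applies to the neutral template a similarity transform about the
    origin with scale ~ U[0.8, 1.25] and a rotation about a uniformly random
    axis with angle ~ U[5°, 25°], then adds isotropic Gaussian landmark
    noise with σ cycling over ``BENCHMARK_NOISE_LEVELS``. Transforms are
    origin-preserving because the scale-matching step equalises norms about
    the fixed coordinate origin; a translation would make the scale-matched
    pair only approximately rigid-related and exact noise-free recovery
    impossible for any method under test.
    """
    template, _ = generate_template(mode)
    src = template.points
    cases = []
    for k in range(n_cases):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, k]))
        scale = 0.8 + 0.45 * rng.random()
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(5.0 + 20.0 * rng.random())
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)
        m = np.eye(4)
        m[:3, :3] = scale * R
        truth = HomogeneousTransform(m, kind="similarity" if abs(scale - 1) > 1e-15 else "rigid")
        sigma = BENCHMARK_NOISE_LEVELS[k % len(BENCHMARK_NOISE_LEVELS)]
        tgt_pts = truth.apply(src)
        if sigma > 0:
            tgt_pts = tgt_pts + sigma * rng.standard_normal(src.shape)
        target = LandmarkSet(
            points=tgt_pts,
            subject_id=template.subject_id,
            session_label=f"bench-{k}",
            expression="neutral",
            mode=mode,
        )
        cases.append(
            RegistrationCase(
                case_id=k, source=template, target=target, true_transform=truth, noise_sd=sigma
            )
        )
    return cases
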