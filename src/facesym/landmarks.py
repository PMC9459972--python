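"""Data model and I/O for 3D facial landmark sets and the face topology.

A capture is an ordered set of *n* 3D landmarks indexed 0..n-1; index
semantics are fixed by the upstream face-mesh detector, so the i-th landmark
of two captures of the same subject refers to the same anatomical location.
Two topology modes are supported: the full 478-point face mesh (468 facial
landmarks + 10 iris landmarks) and a compact 68-point layout kept for
compatibility with older landmarkers.

The :class:`FaceTopology` carries everything the symmetry and movement
metrics need beyond raw coordinates: the left/right landmark pairing, the
midline landmarks, the iris landmarks that define the midsagittal plane, and
the 17 facial-muscle groups over which metrics are averaged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "MODE_COUNTS",
    "MUSCLE_GROUP_NAMES",
    "GROUP_SIZES_478",
    "GROUP_SIZES_68",
    "LandmarkSet",
    "MuscleGroup",
    "FaceTopology",
    "HomogeneousTransform",
    "load_landmarks",
    "save_landmarks",
    "load_topology",
]

#: landmark count per topology mode
MODE_COUNTS: Mapping[str, int] = {"full_478": 478, "compact_68": 68}

VALID_EXPRESSIONS = ("neutral", "smile", "other")

#: the 17 facial-muscle groups, in their canonical order (group ids 1..17).
#: Group 7 ("Nose Tip") is not a muscle but an anatomically useful region:
#: the nose bends under palsy of the surrounding muscles.
MUSCLE_GROUP_NAMES: Sequence[str] = (
    "Frontalis",
    "Corrugator",
    "Procerus",
    "Orbicularis Oculi",
    "Levator Labii Superioris",
    "Nasalis",
    "Nose Tip",
    "Orbicularis Oris",
    "Mentalis",
    "Depressor Anguli Oris",
    "Zygomaticus Minor",
    "Zygomaticus Major",
    "Buccinator",
    "Risorius",
    "Platysma",
    "Masseter",
    "Temporalis",
)

#: per-group landmark counts in full_478 mode
GROUP_SIZES_478: Sequence[int] = (6, 1, 1, 59, 10, 6, 32, 44, 6, 8, 6, 3, 4, 3, 5, 9, 16)
#: per-group landmark counts in compact_68 mode
GROUP_SIZES_68: Sequence[int] = (0, 0, 2, 6, 0, 2, 3, 12, 0, 2, 0, 0, 0, 0, 2, 4, 1)

_GROUP_SIZES = {"full_478": GROUP_SIZES_478, "compact_68": GROUP_SIZES_68}


def _check_mode(mode: str) -> None:
    if mode not in MODE_COUNTS:
        raise ValidationError(f"unknown topology mode {mode!r}; expected one of {sorted(MODE_COUNTS)}")


# ---------------------------------------------------------------------------
# LandmarkSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    """An indexed set of 3D facial landmarks plus capture metadata.

    Parameters
    ----------
    points
        Array of shape ``(n, 3)``, dimensionless model units. Stored as
        float64; every coordinate must be finite.
    subject_id, session_label
        Free-form identifiers (e.g. ``"patient1"``, ``"year1"``).
    expression
        One of ``"neutral"``, ``"smile"``, ``"other"``.
    mode
        ``"full_478"`` or ``"compact_68"``; fixes the expected landmark count.
    """

    points: np.ndarray
    subject_id: str = ""
    session_label: str = ""
    expression: str = "neutral"
    mode: str = "full_478"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must have shape (n, 3), got {pts.shape}")
        _check_mode(self.mode)
        expected = MODE_COUNTS[self.mode]
        if pts.shape[0] != expected:
            raise ValidationError(
                f"mode {self.mode!r} requires {expected} landmarks, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must all be finite")
        if self.expression not in VALID_EXPRESSIONS:
            raise ValidationError(
                f"expression must be one of {VALID_EXPRESSIONS}, got {self.expression!r}"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        """Same metadata, new coordinates."""
        return replace(self, points=np.array(points, dtype=np.float64))

    def __eq__(self, other: object) -> bool:  # value semantics incl. coordinates
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.session_label == other.session_label
            and self.expression == other.expression
            and self.mode == other.mode
            and np.array_equal(self.points, other.points)
        )


# ---------------------------------------------------------------------------
# FaceTopology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleGroup:
    group_id: int  # 1..17
    name: str
    indices: tuple[int, ...]


@dataclass(frozen=True)
class FaceTopology:
    """Left/right pairing, midline, iris landmarks and muscle groups.

    ``pairs`` lists ``(left_index, right_index)`` tuples; every landmark is
    either one member of exactly one pair or a midline landmark, and the two
    sets together cover the full index range of the mode.
    """

    mode: str
    pairs: tuple[tuple[int, int], ...]
    midline_indices: tuple[int, ...]
    left_iris_index: int
    right_iris_index: int
    muscle_groups: tuple[MuscleGroup, ...]

    # derived, filled in __post_init__
    _pair_of: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        n = MODE_COUNTS[self.mode]
        pairs = tuple((int(l), int(r)) for l, r in self.pairs)
        midline = tuple(int(i) for i in self.midline_indices)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline_indices", midline)

        seen: set[int] = set()
        for l, r in pairs:
            if l == r:
                raise ValidationError(f"degenerate pair ({l}, {r})")
            for i in (l, r):
                if i in seen:
                    raise ValidationError(f"index {i} appears in more than one pair")
                seen.add(i)
        left = {l for l, _ in pairs}
        right = {r for _, r in pairs}
        if left & right:
            raise ValidationError("left and right index sets are not disjoint")
        if seen & set(midline):
            raise ValidationError("midline indices overlap paired indices")
        covered = seen | set(midline)
        if covered != set(range(n)):
            missing = sorted(set(range(n)) - covered)[:5]
            extra = sorted(covered - set(range(n)))[:5]
            raise ValidationError(
                f"pairs ∪ midline must cover exactly 0..{n - 1}; "
                f"missing={missing}..., out-of-range={extra}..."
            )

        pair_of = {}
        for l, r in pairs:
            pair_of[l] = r
            pair_of[r] = l
        object.__setattr__(self, "_pair_of", pair_of)

        if len(self.muscle_groups) != 17:
            raise ValidationError(f"expected 17 muscle groups, got {len(self.muscle_groups)}")
        expected_sizes = _GROUP_SIZES[self.mode]
        for k, group in enumerate(self.muscle_groups):
            if group.group_id != k + 1:
                raise ValidationError(
                    f"muscle groups must be ordered by id 1..17; position {k} has id {group.group_id}"
                )
            if group.name != MUSCLE_GROUP_NAMES[k]:
                raise ValidationError(
                    f"group {k + 1} must be named {MUSCLE_GROUP_NAMES[k]!r}, got {group.name!r}"
                )
            if len(set(group.indices)) != len(group.indices):
                raise ValidationError(f"group {group.group_id} has duplicate indices")
            if any(i not in covered for i in group.indices):
                raise ValidationError(f"group {group.group_id} has out-of-range indices")
            if len(group.indices) != expected_sizes[k]:
                raise ValidationError(
                    f"group {group.group_id} ({group.name}) must have "
                    f"{expected_sizes[k]} landmarks in mode {self.mode}, got {len(group.indices)}"
                )

        if self._pair_of.get(self.left_iris_index) != self.right_iris_index:
            raise ValidationError("iris indices must form a left/right pair")
        if self.left_iris_index not in left:
            raise ValidationError("left_iris_index must be a left-side landmark")

    # -- convenience accessors -------------------------------------------

    @property
    def n_landmarks(self) -> int:
        return MODE_COUNTS[self.mode]

    @property
    def left_indices(self) -> np.ndarray:
        return np.array([l for l, _ in self.pairs], dtype=np.intp)

    @property
    def right_indices(self) -> np.ndarray:
        return np.array([r for _, r in self.pairs], dtype=np.intp)

    def partner_of(self, index: int) -> int | None:
        """The mirror partner of ``index``, or None for midline landmarks."""
        return self._pair_of.get(index)

    def group_by_id(self, group_id: int) -> MuscleGroup:
        return self.muscle_groups[group_id - 1]

    def group_pairs(self, group_id: int) -> list[tuple[int, int]]:
        """Pairs whose *both* members belong to the group."""
        members = set(self.group_by_id(group_id).indices)
        return [(l, r) for l, r in self.pairs if l in members and r in members]


# ---------------------------------------------------------------------------
# HomogeneousTransform
# ---------------------------------------------------------------------------

_RIGID_TOL = 1e-8


@dataclass(frozen=True)
class HomogeneousTransform:
    """A 4x4 rigid or similarity transform in homogeneous coordinates.

    ``kind="rigid"``: the upper-left 3x3 block R is a proper rotation.
    ``kind="similarity"``: the block is c·R with c > 0.
    """

    matrix: np.ndarray
    kind: str = "rigid"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValidationError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=1e-12):
            raise ValidationError("bottom row of a homogeneous transform must be (0,0,0,1)")
        block = m[:3, :3]
        det = np.linalg.det(block)
        if self.kind == "rigid":
            if not np.allclose(block.T @ block, np.eye(3), atol=_RIGID_TOL):
                raise ValidationError("rigid transform requires an orthonormal rotation block")
            if det <= 0:
                raise ValidationError("rigid transform requires det(R) = +1 (no reflection)")
        elif self.kind == "similarity":
            c = det ** (1.0 / 3.0) if det > 0 else float("nan")
            if not (det > 0 and np.allclose((block / c).T @ (block / c), np.eye(3), atol=1e-6)):
                raise ValidationError("similarity transform requires block c·R with c>0, R a proper rotation")
        else:
            raise ValidationError(f"kind must be 'rigid' or 'similarity', got {self.kind!r}")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "HomogeneousTransform":
        return cls(np.eye(4), kind="rigid")

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Iterable[float], kind: str = "rigid"
    ) -> "HomogeneousTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=np.float64)
        m[:3, 3] = np.asarray(list(translation), dtype=np.float64)
        return cls(m, kind=kind)

    @classmethod
    def from_scale(cls, factor: float, origin: Iterable[float] = (0.0, 0.0, 0.0)) -> "HomogeneousTransform":
        """Isotropic scaling by ``factor`` about ``origin``."""
        if factor <= 0:
            raise ValidationError(f"scale factor must be positive, got {factor}")
        o = np.asarray(list(origin), dtype=np.float64)
        m = np.eye(4)
        m[:3, :3] *= factor
        m[:3, 3] = o - factor * o
        return cls(m, kind="similarity")

    # -- algebra ----------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def scale(self) -> float:
        """Isotropic scale of the linear block (1.0 for rigid transforms)."""
        return float(np.linalg.det(self.matrix[:3, :3]) ** (1.0 / 3.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(n, 3)`` array (or a single 3-vector)."""
        p = np.asarray(points, dtype=np.float64)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def compose(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """``self ∘ other`` — apply ``other`` first, then ``self``."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "similarity"
        return HomogeneousTransform(self.matrix @ other.matrix, kind=kind)

    def inverse(self) -> "HomogeneousTransform":
        return HomogeneousTransform(np.linalg.inv(self.matrix), kind=self.kind)


# ---------------------------------------------------------------------------
# Landmark file I/O
# ---------------------------------------------------------------------------

def load_landmarks(path: str | Path, mode: str = "full_478", **metadata: str) -> LandmarkSet:
    """Read a landmark set from a CSV (``index,x,y,z``) or JSON file.

    The format is selected by file extension (``.json`` vs anything else).
    CSV carries no metadata; subject/session/expression may be supplied as
    keyword arguments. JSON files carry their own metadata, which keyword
    arguments override. Rows may appear in any order; indices must be dense
    0..n-1 with no duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        return _load_landmarks_json(path, mode, metadata)
    return _load_landmarks_csv(path, mode, metadata)


def _load_landmarks_csv(path: Path, mode: str, metadata: Mapping[str, str]) -> LandmarkSet:
    rows: dict[int, tuple[float, float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["index", "x", "y", "z"]:
            raise FormatError(f"{path}: expected header 'index,x,y,z', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                idx = int(row[0])
                xyz = (float(row[1]), float(row[2]), float(row[3]))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row {row}") from exc
            if idx in rows:
                raise FormatError(f"{path}: duplicate landmark index {idx}")
            rows[idx] = xyz
    n = len(rows)
    if sorted(rows) != list(range(n)):
        raise FormatError(f"{path}: landmark indices must be dense 0..{n - 1}")
    pts = np.array([rows[i] for i in range(n)], dtype=np.float64)
    return LandmarkSet(points=pts, mode=mode, **dict(metadata))


def _load_landmarks_json(path: Path, mode: str, metadata: Mapping[str, str]) -> LandmarkSet:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "points" not in payload:
        raise FormatError(f"{path}: JSON landmark file must be an object with a 'points' array")
    meta = {
        "subject_id": payload.get("subject_id", ""),
        "session_label": payload.get("session_label", ""),
        "expression": payload.get("expression", "neutral"),
    }
    meta.update(metadata)
    file_mode = payload.get("mode", mode)
    if file_mode != mode:
        raise ValidationError(f"{path}: file mode {file_mode!r} does not match requested mode {mode!r}")
    pts = np.asarray(payload["points"], dtype=np.float64)
    return LandmarkSet(points=pts, mode=mode, **meta)


def save_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as CSV or JSON (by extension), full precision.

    Coordinates are written with 17 significant digits (``repr`` round-trip
    precision for float64), so ``load_landmarks(save_landmarks(ls))``
    reproduces the coordinates bit-for-bit.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "subject_id": ls.subject_id,
            "session_label": ls.session_label,
            "expression": ls.expression,
            "mode": ls.mode,
            "points": [[float(f"{v:.17g}") for v in p] for p in ls.points],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "x", "y", "z"])
        for i, (x, y, z) in enumerate(ls.points):
            writer.writerow([i, f"{x:.17g}", f"{y:.17g}", f"{z:.17g}"])


# ---------------------------------------------------------------------------
# Topology resource I/O
# ---------------------------------------------------------------------------

_RESOURCE_FILES = {"full_478": "topology_478.json", "compact_68": "topology_68.json"}


def load_topology(mode: str = "full_478", path: str | Path | None = None) -> FaceTopology:
    """Load the bundled face topology for ``mode``, or a user-supplied file.

    The bundled resources assign the landmarks of the package's canonical
    face template to left/right pairs, midline, iris landmarks and the 17
    muscle groups; all :class:`FaceTopology` invariants (including the
    per-group cardinalities) are re-validated on load.
    """
    _check_mode(mode)
    if path is None:
        ref = _importlib_resources.files("facesym.resources").joinpath(_RESOURCE_FILES[mode])
        text = ref.read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FormatError(f"topology file not found: {p}")
        text = p.read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid topology JSON: {exc}") from exc
    return topology_from_dict(payload, mode=mode)


def topology_from_dict(payload: Mapping, mode: str | None = None) -> FaceTopology:
    """Build and validate a :class:`FaceTopology` from its JSON dict form."""
    try:
        file_mode = payload["mode"]
        pairs = tuple((int(l), int(r)) for l, r in payload["pairs"])
        midline = tuple(int(i) for i in payload["midline"])
        iris = payload["iris"]
        groups = tuple(
            MuscleGroup(int(g["id"]), str(g["name"]), tuple(int(i) for i in g["indices"]))
            for g in payload["muscle_groups"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed topology payload: {exc}") from exc
    if mode is not None and file_mode != mode:
        raise ValidationError(f"topology file is for mode {file_mode!r}, requested {mode!r}")
    return FaceTopology(
        mode=file_mode,
        pairs=pairs,
        midline_indices=midline,
        left_iris_index=int(iris["left"]),
        right_iris_index=int(iris["right"]),
        muscle_groups=groups,
    )


def topology_to_dict(topo: FaceTopology) -> dict:
    """Inverse of :func:`topology_from_dict`."""
    return {
        "mode": topo.mode,
        "pairs": [[l, r] for l, r in topo.pairs],
        "midline": list(topo.midline_indices),
        "iris": {"left": topo.left_iris_index, "right": topo.right_iris_index},
        "muscle_groups": [
            {"id": g.group_id, "name": g.name, "indices": list(g.indices)}
            for g in topo.muscle_groups
        ],
    }
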