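"""Longitudinal report assembly across capture sessions.

A manifest lists one neutral + smile capture pair per session for one
subject. The first session is the reference: every later session's neutral
capture is registered onto the reference neutral, the recovered similarity
is applied to both captures of that session, and the three per-muscle
metrics are computed in the shared reference frame — so distance and
movement magnitudes are comparable across sessions even when the captures
were taken at different camera distances. Results come back as tidy
long-format tables (one row per session x muscle group).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import FacesymError, FormatError, ValidationError
from .landmarks import FaceTopology, LandmarkSet, load_landmarks, load_topology
from .movement import compute_movement_report
from .registration import RegistrationConfig, RegistrationResult, register
from .symmetry import compute_symmetry_report

__all__ = [
    "SessionRecord",
    "SessionResult",
    "LongitudinalResult",
    "load_manifest",
    "run_longitudinal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SessionRecord:
    """One row of the longitudinal manifest."""

    subject_id: str
    session_label: str
    capture_date: str  # ISO-8601
    neutral_path: str
    smile_path: str

    def __post_init__(self) -> None:
        try:
            datetime.date.fromisoformat(self.capture_date)
        except ValueError as exc:
            raise ValidationError(
                f"session {self.session_label!r}: capture_date must be ISO-8601, got {self.capture_date!r}"
            ) from exc


@dataclass(frozen=True)
class SessionResult:
    record: SessionRecord
    symmetry: "object"  # SymmetryReport
    movement: "object | None"  # MovementReport (None for single-session runs)
    cross_session_registration: RegistrationResult | None  # None for the reference


@dataclass(frozen=True)
class LongitudinalResult:
    """Per-session results plus tidy per-metric tables.

    ``failed_sessions`` lists (session_label, reason) for sessions that
    could not be processed; a non-empty list signals partial failure.
    """

    sessions: tuple[SessionResult, ...]
    distance_table: pd.DataFrame
    angle_table: pd.DataFrame
    movement_table: pd.DataFrame
    failed_sessions: tuple[tuple[str, str], ...] = ()


def load_manifest(path: str | Path) -> list[SessionRecord]:
    """Read a session manifest from YAML.

    Schema: a list (or ``{sessions: [...]}``) of mappings with keys
    ``subject_id, session_label, date, neutral, smile``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    payload = yaml.safe_load(path.read_text())
    if isinstance(payload, dict):
        payload = payload.get("sessions")
    if not isinstance(payload, list):
        raise FormatError(f"{path}: manifest must be a list of session mappings")
    records = []
    for entry in payload:
        try:
            records.append(
                SessionRecord(
                    subject_id=str(entry["subject_id"]),
                    session_label=str(entry["session_label"]),
                    capture_date=str(entry["date"]),
                    neutral_path=str(entry["neutral"]),
                    smile_path=str(entry["smile"]),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: manifest entry missing key {exc}") from exc
    _check_manifest(records)
    return records


def _check_manifest(manifest: Sequence[SessionRecord]) -> None:
    if not manifest:
        raise ValidationError("manifest must contain at least one session")
    seen: dict[str, set[str]] = {}
    for rec in manifest:
        labels = seen.setdefault(rec.subject_id, set())
        if rec.session_label in labels:
            raise ValidationError(
                f"duplicate session label {rec.session_label!r} for subject {rec.subject_id!r}"
            )
        labels.add(rec.session_label)


def _metric_rows(label: str, per_muscle: dict, topo: FaceTopology, metric: str) -> list[dict]:
    rows = []
    for group in topo.muscle_groups:
        value = per_muscle.get(group.group_id)
        rows.append(
            {
                "session": label,
                "group_id": group.group_id,
                "group_name": group.name,
                metric: value,
                "n_pairs": len(topo.group_pairs(group.group_id)),
            }
        )
    return rows


def run_longitudinal(
    manifest: Sequence[SessionRecord],
    cfg: RegistrationConfig | None = None,
    mode: str = "full_478",
    topology: FaceTopology | None = None,
) -> LongitudinalResult:
    """Register every session to the first one and tabulate the metrics.

    Sessions whose capture files cannot be read or validated are skipped
    with a logged error and reported in ``failed_sessions``. With a single
    (usable) session only the symmetry tables are populated. Deterministic
    for fixed manifest + config.
    """
    cfg = cfg or RegistrationConfig()
    _check_manifest(manifest)
    topo = topology or load_topology(mode)

    loaded: list[tuple[SessionRecord, LandmarkSet, LandmarkSet]] = []
    failures: list[tuple[str, str]] = []
    for rec in manifest:
        try:
            neutral = load_landmarks(rec.neutral_path, mode=mode, expression="neutral")
            smile = load_landmarks(rec.smile_path, mode=mode, expression="smile")
        except FacesymError as exc:
            logger.error("session %s skipped: %s", rec.session_label, exc)
            failures.append((rec.session_label, str(exc)))
            continue
        loaded.append((rec, neutral, smile))

    if not loaded:
        raise ValidationError("no usable sessions in the manifest")

    single_session = len(loaded) == 1
    _, ref_neutral, _ = loaded[0]

    session_results: list[SessionResult] = []
    dist_rows: list[dict] = []
    angle_rows: list[dict] = []
    move_rows: list[dict] = []
    for rec, neutral, smile in loaded:
        try:
            if neutral is ref_neutral:
                cross = None
                neutral_aligned, smile_aligned = neutral, smile
            else:
                cross = register(neutral, ref_neutral, cfg)
                neutral_aligned = neutral.with_points(cross.transform.apply(neutral.points))
                smile_aligned = smile.with_points(cross.transform.apply(smile.points))

            sym = compute_symmetry_report(smile_aligned, topo)
            if single_session:
                move = None
            else:
                within = register(smile_aligned, neutral_aligned, cfg)
                move = compute_movement_report(neutral_aligned, smile_aligned, topo, within)
        except FacesymError as exc:
            logger.error("session %s failed: %s", rec.session_label, exc)
            failures.append((rec.session_label, str(exc)))
            continue

        session_results.append(
            SessionResult(record=rec, symmetry=sym, movement=move, cross_session_registration=cross)
        )
        dist_rows += _metric_rows(rec.session_label, sym.per_muscle_distance, topo, "distance_symmetry")
        angle_rows += _metric_rows(rec.session_label, sym.per_muscle_angle, topo, "angle_symmetry")
        if move is not None:
            move_rows += _metric_rows(rec.session_label, move.per_muscle, topo, "movement_asymmetry")

    move_cols = ["session", "group_id", "group_name", "movement_asymmetry", "n_pairs"]
    return LongitudinalResult(
        sessions=tuple(session_results),
        distance_table=pd.DataFrame(dist_rows),
        angle_table=pd.DataFrame(angle_rows),
        movement_table=pd.DataFrame(move_rows, columns=move_cols if not move_rows else None),
        failed_sessions=tuple(failures),
    )
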