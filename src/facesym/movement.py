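"""Dynamic-expression asymmetry: landmark movement between neutral and smile.

After the smile capture is registered into the neutral capture's frame, the
i-th landmark's movement amount is its displacement magnitude between the
two expressions, taken separately for the left and right member of each
landmark pair. The per-pair left-right difference of movement amounts
measures how unevenly the two sides of the face move: 0 means perfectly
symmetric motion. The signed difference (left minus right) is kept in the
report, but the headline per-muscle value averages absolute differences —
opposing pairs would otherwise cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .landmarks import FaceTopology, LandmarkSet
from .registration import RegistrationResult
from .symmetry import PairKey, aggregate_by_muscle

__all__ = ["MovementReport", "movement_amounts", "movement_asymmetry", "compute_movement_report"]


@dataclass(frozen=True)
class MovementReport:
    """Per-pair movement amounts and their left-right differences.

    ``per_muscle`` holds group means of ``per_pair_diff`` (absolute
    differences) times ``scale``, rounded to ``decimals``; ``None`` marks
    groups without internal pairs. ``registration_used`` records the
    transform that carried smile into the neutral frame (None when the
    caller supplied already-aligned captures).
    """

    per_pair_left: dict[PairKey, float]
    per_pair_right: dict[PairKey, float]
    per_pair_diff: dict[PairKey, float]
    per_pair_signed: dict[PairKey, float]
    per_muscle: dict[int, float | None]
    scale: float = 100.0
    decimals: int = 3
    registration_used: RegistrationResult | None = None


def movement_amounts(
    neutral: LandmarkSet,
    smile: LandmarkSet,
    topo: FaceTopology,
    reg: RegistrationResult | None = None,
) -> tuple[dict[PairKey, float], dict[PairKey, float]]:
    """Per-side movement amounts ``m_L,i`` and ``m_R,i`` keyed by pair.

    ``reg`` must map the smile capture into the neutral frame (i.e. come
    from registering smile as source onto neutral as target); with ``None``
    the captures are assumed already co-registered.
    """
    if neutral.mode != smile.mode or topo.mode != neutral.mode:
        raise ValidationError("neutral, smile and topology modes must agree")
    smile_pts = reg.transform.apply(smile.points) if reg is not None else smile.points
    delta = smile_pts - neutral.points
    m = np.linalg.norm(delta, axis=1)
    left = {pair: float(m[l]) for pair, l in zip(topo.pairs, topo.left_indices)}
    right = {pair: float(m[r]) for pair, r in zip(topo.pairs, topo.right_indices)}
    return left, right


def movement_asymmetry(
    left: dict[PairKey, float],
    right: dict[PairKey, float],
    topo: FaceTopology,
    scale: float = 100.0,
    decimals: int = 3,
    registration_used: RegistrationResult | None = None,
) -> MovementReport:
    """Left-right movement differences per pair, aggregated per muscle."""
    if set(left) != set(right):
        raise ValidationError("left and right movement maps must share the same pair keys")
    signed = {p: left[p] - right[p] for p in left}
    diff = {p: abs(v) for p, v in signed.items()}
    per_muscle = aggregate_by_muscle(diff, topo, scale=scale, decimals=decimals)
    return MovementReport(
        per_pair_left=dict(left),
        per_pair_right=dict(right),
        per_pair_diff=diff,
        per_pair_signed=signed,
        per_muscle=per_muscle,
        scale=scale,
        decimals=decimals,
        registration_used=registration_used,
    )


def compute_movement_report(
    neutral: LandmarkSet,
    smile: LandmarkSet,
    topo: FaceTopology,
    reg: RegistrationResult | None = None,
    scale: float = 100.0,
    decimals: int = 3,
) -> MovementReport:
    """Movement amounts + asymmetry in one step."""
    left, right = movement_amounts(neutral, smile, topo, reg)
    return movement_asymmetry(left, right, topo, scale, decimals, registration_used=reg)
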