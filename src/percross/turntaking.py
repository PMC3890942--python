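"""Movement binarization and the turn-taking (TT) statistic.

Each player's trajectory is reduced to a binary moving/non-moving series:
a step counts as movement when the absolute wrapped displacement from the
previous step exceeds ``move_threshold`` (0.5 units, an eighth of the body
length), and pauses shorter than ``min_pause_steps`` (500 ms) are treated as
micro-saccades and kept as movement.

Given two binary series B1 and B2 over a window of T steps, the difference
series is D = B1 NAND B2, each player's active contribution is
C1 = sum(B1 AND D) and C2 = sum(B2 AND D), and

    TT = 4 * C1 * C2 / T**2

TT ranges over [0, 1]: 0 when there is no complementary activity at all,
1 when the two players perfectly exchange activity and passivity
(C1 = C2 = T/2).
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .geometry import EnvConfig, signed_displacement

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TrialRecording

__all__ = [
    "TurnTakingScore",
    "binarize_movement",
    "turn_taking_score",
    "tt_before_click",
]


@dataclasses.dataclass(frozen=True)
class TurnTakingScore:
    """A TT value together with its components C1, C2 and T."""

    tt: float
    c1: int
    c2: int
    t_steps: int


def _as_binary(values, name: str) -> np.ndarray:
    if isinstance(values, str):
        values = [int(ch) for ch in values]
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one step")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def binarize_movement(positions: Sequence[float], cfg: EnvConfig) -> np.ndarray:
    """Reduce a wrapped position series to a 0/1 movement indicator per step.

    The first step has no predecessor and starts as non-moving; like any
    other short pause it is absorbed into surrounding movement unless it
    belongs to a motionless run of at least ``cfg.min_pause_steps`` steps.

    Returns a ``uint8`` array the same length as ``positions``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 1 or pos.size < 2:
        raise ValueError("need at least two position samples to binarize movement")
    dx = np.abs(signed_displacement(pos[:-1], pos[1:], cfg.space_length))
    raw = np.zeros(pos.size, dtype=bool)
    raw[1:] = dx > cfg.move_threshold

    out = raw.copy()
    padded = np.concatenate(([True], raw, [True]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == -1)
    ends = np.flatnonzero(edges == 1)
    for s, e in zip(starts, ends):
        if e - s < cfg.min_pause_steps:
            out[s:e] = True
    return out.astype(np.uint8)


def turn_taking_score(b1, b2) -> TurnTakingScore:
    """Compute TT = 4*C1*C2/T^2 for two equal-length binary series."""
    a = _as_binary(b1, "b1")
    b = _as_binary(b2, "b2")
    if a.size != b.size:
        raise ValueError(f"series length mismatch: {a.size} != {b.size}")
    d = ~(a & b)
    c1 = int(np.count_nonzero(a & d))
    c2 = int(np.count_nonzero(b & d))
    t = int(a.size)
    tt = 4.0 * c1 * c2 / float(t) ** 2
    return TurnTakingScore(tt=tt, c1=c1, c2=c2, t_steps=t)


def tt_before_click(
    rec: "TrialRecording", player: int, click_step: int, cfg: EnvConfig | None = None
) -> TurnTakingScore:
    """TT over the window preceding a player's click.

    Both players' full-trial trajectories are binarized first (so pause
    merging sees the whole trial), then the window ``[click_step - W,
    click_step)`` is extracted with ``W = min(tt_window_steps, click_step)``
    and scored with ``T`` equal to the actual window length.
    """
    cfg = cfg or rec.cfg
    if not 0 < click_step < rec.n_steps:
        if click_step == 0:
            raise ValueError("click at step 0 leaves no window to score")
        raise ValueError(f"click_step {click_step} outside trial of {rec.n_steps} steps")
    w = min(cfg.tt_window_steps, click_step)
    b_self = binarize_movement(rec.pos[player], cfg)[click_step - w : click_step]
    b_other = binarize_movement(rec.pos[1 - player], cfg)[click_step - w : click_step]
    return turn_taking_score(b_self, b_other)
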