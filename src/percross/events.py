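"""Event attribution: contact segmentation and click-target assignment.

A *contact* is a maximal run of uninterrupted tactile stimulation; each
object type (the partner's avatar, the partner's shadow, the player's own
static object) contributes at most once per contact, no matter how many
distinct overlap episodes it has within the run.  This mirrors the player's
first-person experience of one continuous vibration.

A *click* is attributed by sampling relative positions one second before
the click: the partner's avatar wins if it is within ±``target_range``
units, otherwise the shadow, otherwise the static object, otherwise the
click has no target.  Because ``2 * target_range < shadow_offset``, the
avatar and the shadow can never be within range simultaneously.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

from .geometry import OBJECT_TYPES, signed_displacement

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TrialRecording

__all__ = [
    "TARGET_NONE",
    "Contact",
    "ClickEvent",
    "segment_contacts",
    "count_contacts_by_type",
    "assign_click_target",
]

TARGET_NONE = "none"


@dataclasses.dataclass(frozen=True)
class Contact:
    """One maximal run of stimulation, half-open over ``[start, end)`` steps."""

    player: int
    start: int
    end: int
    types: frozenset[str]


@dataclasses.dataclass(frozen=True)
class ClickEvent:
    """A retained click and its attributed target label."""

    player: int
    step: int
    target: str


def _as_bool_series(values, name: str) -> np.ndarray:
    if isinstance(values, str):
        values = [int(ch) for ch in values]
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be a 0/1 series")
    return arr.astype(bool)


def segment_contacts(
    stim, overlaps: Mapping[str, object], player: int = 0
) -> list[Contact]:
    """Segment a stimulation series into contacts with their object types.

    Parameters
    ----------
    stim : sequence of 0/1 (or a '0'/'1' string)
        The player's tactile stimulation per step.
    overlaps : mapping of object type -> 0/1 series
        Per-type overlap series of the same length; their elementwise OR
        must reproduce ``stim`` exactly.
    player : int
        Player id stored on the resulting contacts.
    """
    s = _as_bool_series(stim, "stim")
    typed = {name: _as_bool_series(series, name) for name, series in overlaps.items()}
    for name, series in typed.items():
        if series.size != s.size:
            raise ValueError(f"overlap series {name!r} length differs from stim")
    if typed:
        union = np.logical_or.reduce(list(typed.values()))
        if not np.array_equal(union, s):
            raise ValueError("stim series is not the OR of the per-type overlap series")
    elif s.any():
        raise ValueError("stimulation present but no overlap series given")

    padded = np.concatenate(([False], s, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    contacts = []
    for start, end in zip(starts, ends):
        types = frozenset(
            name for name, series in typed.items() if series[start:end].any()
        )
        contacts.append(Contact(player=player, start=int(start), end=int(end), types=types))
    return contacts


def count_contacts_by_type(contacts: Iterable[Contact]) -> dict[str, int]:
    """Number of contacts involving each object type.

    A single contact increments every type in its type set, so the counts
    can sum to more than the number of contacts.
    """
    counts: dict[str, int] = {t: 0 for t in OBJECT_TYPES}
    for contact in contacts:
        for t in contact.types:
            counts[t] = counts.get(t, 0) + 1
    return counts


def assign_click_target(rec: "TrialRecording", player: int, click_step: int) -> str:
    """Attribute a click to avatar, shadow, static or none.

    Relative positions are sampled at a single step one second before the
    click (clamped to step 0 for clicks earlier than that).  Ranges are
    inclusive, centre to centre, on the signed wrapped displacement.
    """
    cfg = rec.cfg
    if not 0 <= click_step < rec.n_steps:
        raise ValueError(f"click_step {click_step} outside trial of {rec.n_steps} steps")
    at = max(0, click_step - cfg.lookback_steps)
    me = rec.pos[player, at]
    other = 1 - player
    L = cfg.space_length

    def within(target_pos: float) -> bool:
        return abs(signed_displacement(me, target_pos, L)) <= cfg.target_range

    if within(rec.pos[other, at]):
        return "avatar"
    if within(rec.shadow_pos[other, at]):
        return "shadow"
    if within(rec.static_pos[player]):
        return "static"
    return TARGET_NONE
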