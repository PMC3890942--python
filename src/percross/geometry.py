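"""Circular-space arithmetic and the paradigm's geometric/temporal constants.

The perceptual crossing environment is a one-dimensional line that wraps
around after ``space_length`` units.  Every avatar, shadow and static object
is a 4-unit body; two objects stimulate each other's owners when their
wrapped centre distance falls below the body length.  All positions are kept
as continuous reals in ``[0, L)``.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import numpy as np

__all__ = [
    "OBJECT_TYPES",
    "ConfigurationError",
    "EnvConfig",
    "wrap_position",
    "signed_displacement",
    "objects_overlap",
]

#: Canonical object-type labels, from each player's point of view:
#: the partner's avatar, the partner's shadow lure, and the player's own
#: static object.
OBJECT_TYPES = ("avatar", "shadow", "static")


class ConfigurationError(ValueError):
    """Raised for invalid environment parameters."""


@dataclasses.dataclass(frozen=True)
class EnvConfig:
    """Geometric and temporal constants of the perceptual crossing paradigm.

    Parameters
    ----------
    space_length : float
        Circumference of the wrap-around 1D space, in environment units.
    body_length : float
        Length of every object (avatar, shadow, static), in units.  Two
        objects overlap when their wrapped centre distance is strictly
        smaller than this.
    shadow_offset : float
        Rigid displacement from an avatar to its attached shadow lure, in
        units.  The sign convention (+offset for both players) is fixed by
        the simulator and recorded in trial-log headers.
    sample_period : float
        Recording time step in milliseconds (10 ms, i.e. 100 Hz).
    trial_duration : float
        Trial length in seconds.
    target_range : float
        Half-width, in units, of the window used to attribute a click to a
        nearby object.  Must satisfy ``2 * target_range < shadow_offset`` so
        that an avatar and its shadow can never both be attributable.
    click_lookback : float
        Time before a click, in seconds, at which relative positions are
        sampled for click-target attribution.
    tt_window : float
        Length, in seconds, of the window preceding a click over which the
        turn-taking score is computed.
    move_threshold : float
        Minimum absolute per-step displacement, in units, for a step to
        count as movement (an eighth of the body length under defaults).
    min_pause_steps : int
        Minimum run of motionless steps for a pause to survive binarization;
        shorter pauses (micro-saccades) are counted as continued movement.
    """

    space_length: float = 600.0
    body_length: float = 4.0
    shadow_offset: float = 150.0
    sample_period: float = 10.0
    trial_duration: float = 60.0
    target_range: float = 70.0
    click_lookback: float = 1.0
    tt_window: float = 10.0
    move_threshold: float = 0.5
    min_pause_steps: int = 50

    def __post_init__(self) -> None:
        if self.space_length <= 0:
            raise ConfigurationError("space_length must be positive")
        if self.body_length <= 0:
            raise ConfigurationError("body_length must be positive")
        if not (0 < self.shadow_offset < self.space_length):
            raise ConfigurationError(
                "shadow_offset must lie strictly between 0 and space_length"
            )
        if 2 * self.target_range >= self.shadow_offset:
            raise ConfigurationError(
                "2 * target_range must be smaller than shadow_offset so that "
                "an avatar and its shadow are never both attributable"
            )
        if self.sample_period <= 0 or self.trial_duration <= 0:
            raise ConfigurationError("sample_period and trial_duration must be positive")
        steps = self.trial_duration * 1000.0 / self.sample_period
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError(
                "trial_duration * 1000 / sample_period must be an integer step count"
            )
        if self.move_threshold < 0:
            raise ConfigurationError("move_threshold must be non-negative")
        if self.min_pause_steps < 1:
            raise ConfigurationError("min_pause_steps must be at least 1")

    @property
    def n_steps(self) -> int:
        """Number of recorded steps per trial (6000 under defaults)."""
        return int(round(self.trial_duration * 1000.0 / self.sample_period))

    @property
    def lookback_steps(self) -> int:
        """Click-attribution lookback expressed in steps (100 under defaults)."""
        return int(round(self.click_lookback * 1000.0 / self.sample_period))

    @property
    def tt_window_steps(self) -> int:
        """Turn-taking window expressed in steps (1000 under defaults)."""
        return int(round(self.tt_window * 1000.0 / self.sample_period))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EnvConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))


def wrap_position(x, L):
    """Wrap position(s) ``x`` into ``[0, L)`` on a circle of circumference ``L``.

    Idempotent; accepts scalars or arrays.
    """
    if L <= 0:
        raise ConfigurationError("space length must be positive")
    r = np.mod(x, L)
    # float rounding can make np.mod return exactly L for tiny negatives
    r = np.where(r >= L, r - L, r)
    if np.ndim(x) == 0:
        return float(r)
    return r


def signed_displacement(a, b, L):
    """Minimal-magnitude signed offset from ``a`` to ``b`` on the circle.

    Returns the unique value in ``(-L/2, L/2]`` congruent to ``b - a``
    (mod ``L``); the antipodal tie at exactly ``L/2`` resolves to ``+L/2``.
    Accepts scalars or arrays.
    """
    if L <= 0:
        raise ConfigurationError("space length must be positive")
    d = np.mod(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), L)
    d = np.where(d > L / 2.0, d - L, d)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(d)
    return d


def objects_overlap(a, b, cfg: EnvConfig):
    """True where two objects at wrapped positions ``a`` and ``b`` overlap.

    Objects are treated as centre points with overlap when the wrapped
    centre distance is strictly smaller than ``cfg.body_length``, so abutting
    objects do not stimulate.
    """
    d = np.abs(signed_displacement(a, b, cfg.space_length))
    res = d < cfg.body_length
    if np.ndim(res) == 0:
        return bool(res)
    return res
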