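"""Closed-loop trial simulation with scripted agent controllers.

Two avatars move on the wrap-around line under the control of scripted
agents that stand in for human players.  A controller sees only its own
position and its own tactile stimulation — never the partner's state — and
emits a per-step velocity plus an optional click, exactly mirroring the
trackball-and-vibrator interface of the original paradigm.

Object semantics per player ``p`` (partner ``q``):

* ``avatar`` — the partner's avatar; mutual: touching it stimulates both.
* ``shadow`` — the partner's shadow lure at ``pos[q] + shadow_offset``;
  touching it stimulates only the toucher.
* ``static`` — the player's own private static object.

The generator builds whole tournaments of trials with ground-truth click
targets, which is what the analysis stages are scored against.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import OBJECT_TYPES, EnvConfig, wrap_position

__all__ = [
    "SimulationError",
    "TrialRecording",
    "AgentController",
    "StationaryAgent",
    "ScannerAgent",
    "TurnTakerAgent",
    "make_scanner_agent",
    "make_turn_taker_agent",
    "Dataset",
    "generate_dataset",
    "SCENARIOS",
]


class SimulationError(RuntimeError):
    """Raised when a controller misbehaves during a trial."""


def _sdisp(a: float, b: float, L: float) -> float:
    """Scalar minimal signed displacement, tuned for the inner loop."""
    d = (b - a) % L
    if d > L / 2.0:
        d -= L
    return d


@dataclasses.dataclass
class TrialRecording:
    """Full per-step state of one trial for a pair of players.

    Stimulation and per-type overlaps are derived from positions on demand,
    which makes the recording's internal consistency (stim = OR of
    overlaps, rigid avatar-shadow link) true by construction.
    """

    cfg: EnvConfig
    pos: np.ndarray  # (2, n_steps), wrapped avatar positions
    static_pos: np.ndarray  # (2,), each player's own static object
    clicks: list[tuple[int, int]]  # (player, step); at most one per player
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.pos.shape[1]

    @property
    def shadow_pos(self) -> np.ndarray:
        """Shadow positions, rigidly offset from the avatars (2, n_steps)."""
        return wrap_position(self.pos + self.cfg.shadow_offset, self.cfg.space_length)

    def overlap_series(self, player: int) -> dict[str, np.ndarray]:
        """Boolean overlap series per object type, from ``player``'s side."""
        from .geometry import objects_overlap

        other = 1 - player
        return {
            "avatar": objects_overlap(self.pos[player], self.pos[other], self.cfg),
            "shadow": objects_overlap(self.pos[player], self.shadow_pos[other], self.cfg),
            "static": objects_overlap(
                self.pos[player], np.full(self.n_steps, self.static_pos[player]), self.cfg
            ),
        }

    def stim(self, player: int) -> np.ndarray:
        """Binary stimulation series: OR over the player's three overlap channels."""
        ov = self.overlap_series(player)
        return ov["avatar"] | ov["shadow"] | ov["static"]

    def click_step(self, player: int) -> Optional[int]:
        for p, step in self.clicks:
            if p == player:
                return step
        return None

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        L = self.cfg.space_length
        if self.pos.shape[0] != 2:
            raise ValueError("recording must hold exactly two players")
        if ((self.pos < 0) | (self.pos >= L)).any():
            raise ValueError("positions must be wrapped into [0, L)")
        if ((self.static_pos < 0) | (self.static_pos >= L)).any():
            raise ValueError("static positions must be wrapped into [0, L)")
        players = [p for p, _ in self.clicks]
        if len(players) != len(set(players)):
            raise ValueError("at most one retained click per player")
        for p, step in self.clicks:
            if p not in (0, 1) or not 0 <= step < self.n_steps:
                raise ValueError(f"click ({p}, {step}) outside the trial")


class AgentController:
    """Base class for scripted players.

    Subclasses implement :meth:`step`, which receives the agent's own
    position and its stimulation at the previous step, and returns a
    velocity command (units/step) plus a click flag.  Controllers never
    observe the partner except through their own stimulation channel.
    """

    def reset(self, seed: Optional[int] = None) -> None:
        """Re-initialise internal state; deterministic given ``seed``."""
        self._rng = np.random.default_rng(seed)

    def step(self, t: int, pos: float, stim_prev: bool) -> tuple[float, bool]:
        raise NotImplementedError


class StationaryAgent(AgentController):
    """Never moves, never clicks."""

    def step(self, t: int, pos: float, stim_prev: bool) -> tuple[float, bool]:
        return 0.0, False


class ScannerAgent(AgentController):
    """Oscillating sweep searcher.

    Sweeps back and forth over ``span`` units at ``speed`` units/step
    (``span == 0`` degenerates to a stationary agent; a span equal to the
    space length gives a full-circle patrol).  With ``halt_on_stim`` the
    agent freezes at its first tactile contact after the settle period and,
    if ``click_after_contact_steps`` is set, clicks once the contact has
    lasted that many consecutive steps.
    """

    def __init__(
        self,
        speed: float,
        span: float,
        seed: Optional[int] = None,
        direction: int = 1,
        settle_steps: int = 0,
        halt_on_stim: bool = False,
        click_after_contact_steps: Optional[int] = None,
        jitter: float = 0.0,
    ):
        if speed <= 0:
            raise ValueError("speed must be positive")
        if span < 0:
            raise ValueError("span must be non-negative")
        self.speed = speed
        self.span = span
        self.seed = seed
        self.direction = 1 if direction >= 0 else -1
        self.settle_steps = settle_steps
        self.halt_on_stim = halt_on_stim
        self.click_after_contact_steps = click_after_contact_steps
        self.jitter = jitter
        self.reset(seed)

    def reset(self, seed: Optional[int] = None) -> None:
        super().reset(seed if seed is not None else self.seed)
        self._dir = self.direction
        self._travel = 0.0
        self._halted = False
        self._contact_steps = 0
        self._clicked = False

    def step(self, t: int, pos: float, stim_prev: bool) -> tuple[float, bool]:
        if t <= self.settle_steps:
            return 0.0, False
        if self._halted:
            if stim_prev:
                self._contact_steps += 1
            else:
                self._contact_steps = 0
            click = (
                self.click_after_contact_steps is not None
                and not self._clicked
                and self._contact_steps >= self.click_after_contact_steps
            )
            if click:
                self._clicked = True
            return 0.0, click
        if self.halt_on_stim and stim_prev:
            self._halted = True
            self._contact_steps = 1
            return 0.0, False
        if self.span == 0:
            return 0.0, False
        v = self._dir * self.speed
        if self.jitter > 0:
            v += float(self._rng.normal(0.0, self.jitter))
        self._travel += abs(self.speed)
        if self._travel >= self.span:
            self._dir = -self._dir
            self._travel = 0.0
        return v, False


class TurnTakerAgent(AgentController):
    """Seeks the partner, then alternates movement bursts with passivity.

    Before contact the agent sweeps in ``seek_direction`` at ``seek_speed``.
    The first tactile stimulation marks engagement; because mutual avatar
    contact is symmetric, both partners detect it on the same step, which
    gives the pair a shared clock from which complementary fixed-length
    bursts are scheduled: role 0 is active during the first ``burst_steps``
    of each cycle, role 1 during the second half.  While active the agent
    strokes back and forth within ``amplitude`` units of its engagement
    anchor at ``active_speed`` units/step; while passive it freezes.

    The agent clicks once, ``click_delay_steps`` after completing
    ``click_exchanges`` full cycles of the exchange.
    """

    def __init__(
        self,
        role: int,
        burst_steps: int = 500,
        seek_speed: float = 1.0,
        seek_direction: int = 1,
        amplitude: float = 2.0,
        active_speed: float = 0.8,
        click_exchanges: int = 3,
        click_delay_steps: int = 0,
        seed: Optional[int] = None,
    ):
        if burst_steps < 1:
            raise ValueError("burst_steps must be at least 1")
        if role not in (0, 1):
            raise ValueError("role must be 0 or 1")
        self.role = role
        self.burst_steps = burst_steps
        self.seek_speed = seek_speed
        self.seek_direction = 1 if seek_direction >= 0 else -1
        self.amplitude = amplitude
        self.active_speed = active_speed
        self.click_exchanges = click_exchanges
        self.click_delay_steps = click_delay_steps
        self.seed = seed
        self.reset(seed)

    def reset(self, seed: Optional[int] = None) -> None:
        super().reset(seed if seed is not None else self.seed)
        self._engaged_at: Optional[int] = None
        self._offset = 0.0
        self._osc_dir = 1
        self._clicked = False

    def step(self, t: int, pos: float, stim_prev: bool) -> tuple[float, bool]:
        if self._engaged_at is None:
            if stim_prev:
                self._engaged_at = t
            else:
                return self.seek_direction * self.seek_speed, False
        k = t - self._engaged_at
        cycle = 2 * self.burst_steps
        click = False
        if not self._clicked and k >= self.click_exchanges * cycle + self.click_delay_steps:
            click = True
            self._clicked = True
        phase = k % cycle
        active = (phase < self.burst_steps) if self.role == 0 else (phase >= self.burst_steps)
        if not active:
            return 0.0, click
        if self._offset >= self.amplitude:
            self._osc_dir = -1
        elif self._offset <= -self.amplitude:
            self._osc_dir = 1
        v = self._osc_dir * self.active_speed
        self._offset += v
        return v, click


def make_scanner_agent(speed: float, span: float, seed: Optional[int] = None) -> AgentController:
    """Oscillating sweep controller; ``span == 0`` yields a stationary agent."""
    if span == 0:
        return StationaryAgent()
    return ScannerAgent(speed=speed, span=span, seed=seed)


def make_turn_taker_agent(burst_steps: int, seed: Optional[int] = None, **kwargs) -> TurnTakerAgent:
    """Turn-taking controller with fixed-length complementary bursts."""
    role = kwargs.pop("role", 0)
    return TurnTakerAgent(role=role, burst_steps=burst_steps, seed=seed, **kwargs)


def _stim_now(p0: float, p1: float, statics: Sequence[float], cfg: EnvConfig) -> tuple[bool, bool]:
    """Scalar stimulation of both players at the current positions."""
    L = cfg.space_length
    body = cfg.body_length
    off = cfg.shadow_offset
    mutual = abs(_sdisp(p0, p1, L)) < body
    s0 = mutual or abs(_sdisp(p0, (p1 + off) % L, L)) < body or abs(_sdisp(p0, statics[0], L)) < body
    s1 = mutual or abs(_sdisp(p1, (p0 + off) % L, L)) < body or abs(_sdisp(p1, statics[1], L)) < body
    return s0, s1


def simulate_trial(
    controllers: Sequence[AgentController],
    cfg: EnvConfig,
    seed: Optional[int] = None,
    starts: Optional[Sequence[float]] = None,
    static_pos: Optional[Sequence[float]] = None,
    meta: Optional[dict] = None,
) -> TrialRecording:
    """Run one closed-loop trial and return its recording.

    Step 0 records the starting positions; from step 1 on, each controller
    is fed its own position and previous-step stimulation and its velocity
    command is applied and wrapped.  Only the first click per player is
    retained.  Starting and static positions default to random draws, with
    statics kept at least two body lengths from both starts.
    """
    if len(controllers) != 2:
        raise ValueError("exactly two controllers are required")
    rng = np.random.default_rng(seed)
    L = cfg.space_length
    n = cfg.n_steps

    if starts is None:
        starts = rng.uniform(0.0, L, size=2)
    starts = [wrap_position(float(s), L) for s in starts]
    if static_pos is None:
        static_pos = []
        for _ in range(2):
            while True:
                cand = float(rng.uniform(0.0, L))
                if all(abs(_sdisp(cand, s, L)) >= 2 * cfg.body_length for s in starts):
                    static_pos.append(cand)
                    break
    static_pos = np.array([wrap_position(float(s), L) for s in static_pos])

    for ctrl in controllers:
        ctrl.reset(int(rng.integers(0, 2**31)))

    pos = np.empty((2, n), dtype=float)
    p0, p1 = starts
    pos[0, 0], pos[1, 0] = p0, p1
    stim_prev = _stim_now(p0, p1, static_pos, cfg)
    clicks: dict[int, int] = {}

    for t in range(1, n):
        new = [0.0, 0.0]
        for p, ctrl in enumerate(controllers):
            cur = p0 if p == 0 else p1
            v, clicked = ctrl.step(t, cur, stim_prev[p])
            if not math.isfinite(v):
                raise SimulationError(f"player {p} emitted non-finite velocity at step {t}")
            new[p] = (cur + v) % L
            if clicked and p not in clicks:
                clicks[p] = t
        p0, p1 = new
        pos[0, t], pos[1, t] = p0, p1
        stim_prev = _stim_now(p0, p1, static_pos, cfg)

    rec = TrialRecording(
        cfg=cfg,
        pos=pos,
        static_pos=static_pos,
        clicks=sorted(clicks.items()),
        meta=dict(meta or {}),
    )
    rec.meta.setdefault("seed", seed)
    rec.meta.setdefault("shadow_sign", +1)
    return rec


# ---------------------------------------------------------------------------
# dataset generation


@dataclasses.dataclass
class Dataset:
    """A generated tournament: recordings plus ground truth and questionnaires."""

    cfg: EnvConfig
    recordings: list[TrialRecording]
    ground_truth: pd.DataFrame  # team, trial, player, scenario, clicked, click_step, true_target
    questionnaires: pd.DataFrame  # team, trial, player, clicked, pas, cr, free_text
    meta: dict = dataclasses.field(default_factory=dict)


SCENARIOS = ("stationary", "scanners", "turn_takers", "mixed")

_FREE_TEXT = {
    "joint": "clear back-and-forth, felt the partner responding to me",
    "single": "found something responsive-feeling, partner quiet",
    "wrong": "steady contact, hard to tell whether it was alive",
    "": "",
}


def _turn_taker_trial(cfg: EnvConfig, trng: np.random.Generator, seed: int, meta: dict):
    """Pair of turn-takers: approach, engage, exchange bursts, click on the partner."""
    L = cfg.space_length
    base = float(trng.uniform(0.0, L))
    gap = float(trng.uniform(20.0, 140.0))  # < shadow_offset so no lure is crossed en route
    burst = int(trng.integers(400, 601))
    exchanges = int(trng.integers(1, 6))
    delays = trng.integers(0, 201, size=2)
    # statics in the far arc, clear of both seek corridors and the meeting point
    statics = [
        wrap_position(base + float(trng.uniform(gap + 10.0, L - 10.0)), L) for _ in range(2)
    ]
    ctrls = [
        TurnTakerAgent(
            role=0, burst_steps=burst, seek_direction=-1,
            click_exchanges=exchanges, click_delay_steps=int(delays[0]),
        ),
        TurnTakerAgent(
            role=1, burst_steps=burst, seek_direction=+1,
            click_exchanges=exchanges, click_delay_steps=int(delays[1]),
        ),
    ]
    starts = [wrap_position(base + gap, L), base]
    rec = simulate_trial(ctrls, cfg, seed=seed, starts=starts, static_pos=statics, meta=meta)
    truth = []
    for player in (0, 1):
        step = rec.click_step(player)
        truth.append(
            dict(player=player, clicked=step is not None,
                 click_step=step if step is not None else -1,
                 true_target="avatar" if step is not None else "")
        )
    return rec, truth


def _scanner_trial(cfg: EnvConfig, trng: np.random.Generator, seed: int, meta: dict):
    """One halting scanner against a stationary partner.

    The partner's avatar, the partner's shadow and the scanner's own static
    object are kept at least 80 units apart, so whichever object the
    scanner halts on is unambiguous: it is the only object near the click.
    """
    L = cfg.space_length
    pB = float(trng.uniform(0.0, L))
    shadowB = wrap_position(pB + cfg.shadow_offset, L)
    while True:
        sA = float(trng.uniform(0.0, L))
        if min(abs(_sdisp(sA, pB, L)), abs(_sdisp(sA, shadowB, L))) >= 80.0:
            break
    while True:
        sB = float(trng.uniform(0.0, L))
        if abs(_sdisp(sB, pB, L)) >= 10.0:
            break
    sensed = [pB, shadowB, sA]
    while True:
        startA = float(trng.uniform(0.0, L))
        if all(abs(_sdisp(startA, obj, L)) >= 10.0 for obj in sensed):
            break
    ctrls = [
        ScannerAgent(
            speed=1.0, span=L, direction=1 if trng.random() < 0.5 else -1,
            settle_steps=150, halt_on_stim=True, click_after_contact_steps=110,
        ),
        StationaryAgent(),
    ]
    rec = simulate_trial(
        ctrls, cfg, seed=seed, starts=[startA, pB], static_pos=[sA, sB], meta=meta
    )
    truth = []
    step = rec.click_step(0)
    if step is None:
        truth.append(dict(player=0, clicked=False, click_step=-1, true_target=""))
    else:
        overlaps = rec.overlap_series(0)
        hit = [t for t in OBJECT_TYPES if overlaps[t][step]]
        truth.append(
            dict(player=0, clicked=True, click_step=step,
                 true_target=hit[0] if len(hit) == 1 else "ambiguous")
        )
    truth.append(dict(player=1, clicked=False, click_step=-1, true_target=""))
    return rec, truth


def _stationary_trial(cfg: EnvConfig, trng: np.random.Generator, seed: int, meta: dict):
    rec = simulate_trial([StationaryAgent(), StationaryAgent()], cfg, seed=seed, meta=meta)
    truth = [dict(player=p, clicked=False, click_step=-1, true_target="") for p in (0, 1)]
    return rec, truth


def _draw_rating(rng: np.random.Generator, context: str) -> tuple[object, object]:
    """Synthetic PAS/CR ratings conditioned on the click's interaction context."""
    if context == "joint":
        pas = int(rng.choice([4, 3], p=[0.75, 0.25]))
        cr = int(rng.choice([4, 3], p=[0.7, 0.3]))
    elif context == "single":
        pas = int(rng.choice([4, 3, 2], p=[0.2, 0.5, 0.3]))
        cr = int(rng.choice([4, 3, 2, 1], p=[0.1, 0.5, 0.3, 0.1]))
    else:  # wrong
        pas = int(rng.choice([3, 2, 1], p=[0.45, 0.35, 0.2]))
        cr = int(rng.choice([3, 2, 1], p=[0.35, 0.4, 0.25]))
    if rng.random() < 0.01:  # occasional unanswered questionnaire item
        pas = pd.NA
    if rng.random() < 0.01:
        cr = pd.NA
    return pas, cr


def generate_dataset(
    n_teams: int,
    n_trials: int,
    controller_mix: str = "mixed",
    seed: Optional[int] = None,
    cfg: Optional[EnvConfig] = None,
) -> Dataset:
    """Generate a reproducible tournament of simulated trials.

    Scenarios
    ---------
    ``turn_takers``
        Both players are turn-taking agents; they engage, exchange bursts
        and both click on the partner's avatar (ground truth ``avatar``).
    ``scanners``
        A halting scanner paired with a stationary partner; the scanner
        clicks on whichever object it halts on (avatar, shadow or static),
        recorded from the simulator's privileged overlap state.
    ``stationary``
        Two parked agents: no contacts, no clicks.
    ``mixed``
        Teams alternate between ``turn_takers`` (even team ids) and
        ``scanners`` (odd team ids).
    """
    if n_teams < 1 or n_trials < 1:
        raise ValueError("n_teams and n_trials must be at least 1")
    if controller_mix not in SCENARIOS:
        raise ValueError(f"unknown scenario {controller_mix!r}; choose from {SCENARIOS}")
    cfg = cfg or EnvConfig()
    rng = np.random.default_rng(seed)

    builders = {
        "turn_takers": _turn_taker_trial,
        "scanners": _scanner_trial,
        "stationary": _stationary_trial,
    }
    recordings: list[TrialRecording] = []
    truth_rows: list[dict] = []
    quest_rows: list[dict] = []

    for team in range(n_teams):
        if controller_mix == "mixed":
            scenario = "turn_takers" if team % 2 == 0 else "scanners"
        else:
            scenario = controller_mix
        for trial in range(n_trials):
            trial_seed = int(rng.integers(0, 2**31))
            trng = np.random.default_rng(trial_seed)
            meta = dict(team=team, trial=trial, scenario=scenario, seed=trial_seed)
            rec, truth = builders[scenario](cfg, trng, trial_seed, meta)
            recordings.append(rec)
            for row in truth:
                row.update(team=team, trial=trial, scenario=scenario)
                truth_rows.append(row)
                context = ""
                if row["clicked"]:
                    if scenario == "turn_takers":
                        context = "joint"
                    elif row["true_target"] == "avatar":
                        context = "single"
                    else:
                        context = "wrong"
                if context:
                    pas, cr = _draw_rating(trng, context)
                else:
                    pas, cr = pd.NA, pd.NA
                quest_rows.append(
                    dict(team=team, trial=trial, player=row["player"],
                         clicked=row["clicked"], pas=pas, cr=cr,
                         free_text=_FREE_TEXT[context])
                )

    columns = ["team", "trial", "player", "scenario", "clicked", "click_step", "true_target"]
    ground_truth = pd.DataFrame(truth_rows)[columns]
    questionnaires = pd.DataFrame(quest_rows)
    return Dataset(
        cfg=cfg,
        recordings=recordings,
        ground_truth=ground_truth,
        questionnaires=questionnaires,
        meta=dict(n_teams=n_teams, n_trials=n_trials, scenario=controller_mix,
                  seed=seed, shadow_sign=+1),
    )
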