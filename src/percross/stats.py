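"""Click/trial classification, team scoring, accuracies and rating tables.

A retained click is *correct* when its attributed target is the partner's
avatar.  A trial is a Joint Success when both players' clicks are correct,
a Single Success when exactly one click is correct (the partner clicked
wrongly or not at all), Wrong-only when clicks exist but none is correct,
and No-clicks otherwise.  A team gains one point per correct click and
loses one per wrong click (a click with no identifiable target counts as
wrong); absent clicks are neutral.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import OBJECT_TYPES

__all__ = [
    "JOINT_SUCCESS",
    "SINGLE_SUCCESS",
    "WRONG_ONLY",
    "NO_CLICKS",
    "CLICK_CATEGORIES",
    "TrialOutcome",
    "classify_trial",
    "team_score",
    "clicking_accuracy",
    "click_probability_per_contact",
    "rating_frequency_table",
]

JOINT_SUCCESS = "JointSuccess"
SINGLE_SUCCESS = "SingleSuccess"
WRONG_ONLY = "WrongOnly"
NO_CLICKS = "NoClicks"

#: Per-click categories used for rating summaries.
CLICK_CATEGORIES = ("joint_success", "single_success", "wrong")


@dataclasses.dataclass(frozen=True)
class TrialOutcome:
    """A trial's category plus the per-click category of each player's click."""

    category: str
    click_categories: tuple[Optional[str], Optional[str]]


def classify_trial(targets: Sequence[Optional[str]]) -> TrialOutcome:
    """Classify a trial from the two players' attributed click targets.

    ``targets`` holds one entry per player: the target label of the
    player's retained click, or ``None`` if the player did not click.
    """
    if len(targets) != 2:
        raise ValueError("exactly one attributed target (or None) per player required")
    correct = [t == "avatar" for t in targets]
    clicked = [t is not None for t in targets]
    n_correct = sum(correct)
    if n_correct == 2:
        category = JOINT_SUCCESS
    elif n_correct == 1:
        category = SINGLE_SUCCESS
    elif any(clicked):
        category = WRONG_ONLY
    else:
        category = NO_CLICKS

    per_click: list[Optional[str]] = []
    for t in targets:
        if t is None:
            per_click.append(None)
        elif t != "avatar":
            per_click.append("wrong")
        elif category == JOINT_SUCCESS:
            per_click.append("joint_success")
        else:
            per_click.append("single_success")
    return TrialOutcome(category=category, click_categories=tuple(per_click))


def team_score(targets: Iterable[Optional[str]]) -> int:
    """Tournament score: +1 per avatar click, -1 per any other retained click.

    ``targets`` iterates over the attributed targets of every retained
    click of the team across all trials; ``None`` entries (absent clicks)
    contribute nothing.
    """
    score = 0
    for t in targets:
        if t is None:
            continue
        score += 1 if t == "avatar" else -1
    return score


def clicking_accuracy(targets: Sequence[str]) -> Optional[float]:
    """Percentage of a player's clicks that hit the partner's avatar.

    Returns ``None`` when the player never clicked (the quantity is
    undefined, not zero).
    """
    targets = list(targets)
    if not targets:
        return None
    return 100.0 * sum(t == "avatar" for t in targets) / len(targets)


def click_probability_per_contact(
    clicks_by_type: Mapping[str, int], contacts_by_type: Mapping[str, int]
) -> dict[str, float]:
    """Per-type probability (%) that a single contact is followed by a click."""
    out: dict[str, float] = {}
    for t in OBJECT_TYPES:
        clicks = int(clicks_by_type.get(t, 0))
        contacts = int(contacts_by_type.get(t, 0))
        if contacts == 0:
            if clicks:
                raise ValueError(f"{clicks} clicks on {t!r} but zero contacts")
            continue
        out[t] = 100.0 * clicks / contacts
    return out


def rating_frequency_table(
    categories: Sequence[Optional[str]],
    ratings: Sequence[object],
    levels: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Relative frequency of each rating level within each click category.

    Parameters are aligned sequences: the per-click category (one of
    ``CLICK_CATEGORIES``, or ``None`` for unrated/unclicked entries, which
    are skipped) and the rating (1-4, or missing).  Missing ratings are
    excluded from the frequencies and counted in ``n_missing``.  Rows of
    non-empty categories sum to 1.
    """
    if len(categories) != len(ratings):
        raise ValueError("categories and ratings must be aligned")
    rows = []
    for cat in CLICK_CATEGORIES:
        values = [
            r for c, r in zip(categories, ratings) if c == cat and not pd.isna(r)
        ]
        missing = sum(1 for c, r in zip(categories, ratings) if c == cat and pd.isna(r))
        bad = [r for r in values if int(r) not in levels]
        if bad:
            raise ValueError(f"ratings outside levels {tuple(levels)}: {bad}")
        n = len(values)
        freq = {
            lvl: (sum(int(r) == lvl for r in values) / n if n else 0.0) for lvl in levels
        }
        rows.append({"category": cat, **freq, "n": n, "n_missing": missing,
                     "empty": n == 0})
    return pd.DataFrame(rows).set_index("category")


def outcome_bookkeeping(outcomes: Iterable[TrialOutcome]) -> dict[str, int]:
    """Counts of trial categories and per-click categories, with the identity

    ``2 * n_joint + n_single_clicks + n_wrong_clicks == total retained clicks``
    asserted (every retained click falls in exactly one click category).
    """
    trial_counts = {c: 0 for c in (JOINT_SUCCESS, SINGLE_SUCCESS, WRONG_ONLY, NO_CLICKS)}
    click_counts = {c: 0 for c in CLICK_CATEGORIES}
    total_clicks = 0
    for out in outcomes:
        trial_counts[out.category] += 1
        for c in out.click_categories:
            if c is not None:
                click_counts[c] += 1
                total_clicks += 1
    assert (
        2 * trial_counts[JOINT_SUCCESS]
        + click_counts["single_success"]
        + click_counts["wrong"]
        == total_clicks
    )
    return {**trial_counts, **{f"clicks_{k}": v for k, v in click_counts.items()},
            "total_clicks": total_clicks}


def median_over_players(values: Sequence[float]) -> float:
    """Median with the midpoint-of-two-central-values convention."""
    arr = np.asarray([v for v in values if v is not None and not pd.isna(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("median of an empty collection is undefined")
    return float(np.median(arr))
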