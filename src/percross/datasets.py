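"""Small reference inputs for worked examples and desk-scale checks.

``CONTACT_EXAMPLE`` is the standard 18-step illustrative stimulation series
used to demonstrate contact segmentation: the tactile row is the OR of the
three per-object overlap rows, and segmenting it yields two contacts
involving the partner's avatar, two involving the player's own static
object and one involving the partner's shadow.

``TOURNAMENT_TABLE`` is the published summary of a 17-team perceptual
crossing tournament (15 one-minute trials per team, at most one retained
click per player per trial): per player, the number of clicks attributed
to each object type, ordered by team score.  ``CONTACT_CLICK_TOTALS``
carries the corresponding study-wide totals of contacts and clicks per
object type.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONTACT_EXAMPLE",
    "TOURNAMENT_TABLE",
    "CONTACT_CLICK_TOTALS",
    "tournament_dataframe",
]

CONTACT_EXAMPLE = {
    "stim":   "111000111100111000",
    "avatar": "100000111000000000",
    "static": "011000101100000000",
    "shadow": "000000000000111000",
}

# (team_score, player-1 clicks (avatar, shadow, static, none),
#              player-2 clicks (avatar, shadow, static, none))
TOURNAMENT_TABLE = [
    (27, (12, 0, 0, 0), (15, 0, 0, 0)),
    (26, (13, 0, 0, 0), (13, 0, 0, 0)),
    (24, (12, 1, 0, 0), (13, 0, 0, 0)),
    (23, (12, 0, 0, 0), (11, 0, 0, 0)),
    (22, (13, 0, 0, 0), (9, 0, 0, 0)),
    (22, (10, 0, 0, 0), (12, 0, 0, 0)),
    (19, (9, 1, 0, 0), (11, 0, 0, 0)),
    (19, (14, 0, 0, 0), (8, 2, 1, 0)),
    (19, (11, 1, 0, 0), (10, 1, 0, 0)),
    (18, (8, 0, 0, 0), (12, 1, 1, 0)),
    (18, (11, 0, 0, 0), (10, 3, 0, 0)),
    (16, (11, 1, 0, 0), (8, 1, 1, 0)),
    (12, (10, 2, 0, 1), (6, 0, 0, 1)),
    (10, (9, 0, 1, 0), (6, 1, 2, 1)),
    (10, (9, 1, 1, 0), (3, 0, 0, 0)),
    (6, (9, 2, 1, 0), (6, 3, 2, 1)),
    (-1, (5, 7, 1, 0), (7, 5, 0, 0)),
]

#: Study-wide totals: contacts per object type and clicks per object type.
CONTACT_CLICK_TOTALS = {
    "contacts": {"avatar": 28996, "shadow": 5046, "static": 5621},
    "clicks": {"avatar": 338, "shadow": 33, "static": 11, "none": 4},
}


def tournament_dataframe() -> pd.DataFrame:
    """Per-player long form of the tournament table.

    Columns: ``team`` (row index of the table), ``team_score``, ``player``
    (0/1) and the click counts ``avatar, shadow, static, none``.
    """
    rows = []
    for team, (score, p1, p2) in enumerate(TOURNAMENT_TABLE):
        for player, counts in enumerate((p1, p2)):
            avatar, shadow, static, none = counts
            rows.append(
                dict(team=team, team_score=score, player=player,
                     avatar=avatar, shadow=shadow, static=static, none=none)
            )
    return pd.DataFrame(rows)
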