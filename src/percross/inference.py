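"""Variance-gated one-tailed t-tests, click-synchrony randomization, and
player-exclusion sensitivity reruns.

Group comparisons follow a two-stage recipe: an F-test first checks the
equality of the two group variances at level ``alpha``; if equality is not
rejected a pooled-variance (Student) two-sample t-test is used, otherwise a
Welch test with Satterthwaite degrees of freedom.  All reported p-values
are one-tailed, and the hypothesized direction must be stated explicitly
per comparison.

The synchrony analysis contrasts the distribution of inter-click delays
*within* jointly successful trials against the delays between clicks drawn
from *different* trials (all cross-trial pairings).  Only genuinely
interactive timing produces an excess of short delays in the pairwise
distribution; any shared external time cue would survive the cross-trial
shuffling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import CLICK_CATEGORIES, classify_trial

__all__ = [
    "GatedTestResult",
    "DelayDistribution",
    "f_test_equal_variance",
    "one_tailed_two_sample_t",
    "gated_comparison",
    "synchrony_analysis",
    "exclude_player_rerun",
    "summarize_clicks",
    "annotate_click_categories",
]


@dataclasses.dataclass(frozen=True)
class GatedTestResult:
    """Outcome of one variance-gated one-tailed comparison."""

    f_statistic: float
    f_p: float
    chosen_test: str  # "student" or "welch"
    t_statistic: float
    df: float
    p_one_tailed: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int
    direction: str


@dataclasses.dataclass(frozen=True)
class DelayDistribution:
    """Inter-click delays with a shared binning, normalized to unit mass."""

    delays: np.ndarray  # seconds, all >= 0
    kind: str  # "pairwise" or "randomized"
    bin_edges: np.ndarray
    frequencies: np.ndarray

    def frequency_below(self, threshold_s: float) -> float:
        """Fraction of delays strictly below ``threshold_s`` seconds."""
        if self.delays.size == 0:
            return 0.0
        return float(np.mean(self.delays < threshold_s))


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("each sample needs at least two observations")
    return arr


def f_test_equal_variance(x, y, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided F-test of equal variances.

    The statistic is the larger sample variance over the smaller, so
    ``F >= 1``; the two-sided p-value doubles the upper tail of the
    corresponding F distribution.  Returns ``(F, p, equal)`` with
    ``equal = (p >= alpha)``.
    """
    a, b = _clean(x), _clean(y)
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; F-test undefined")
    if va >= vb:
        num_v, num_n, den_v, den_n = va, a.size, vb, b.size
    else:
        num_v, num_n, den_v, den_n = vb, b.size, va, a.size
    if den_v == 0.0:
        return float("inf"), 0.0, False
    f_stat = num_v / den_v
    p = min(1.0, 2.0 * float(sps.f.sf(f_stat, num_n - 1, den_n - 1)))
    return f_stat, p, p >= alpha


def one_tailed_two_sample_t(
    x, y, equal_var: bool, direction: str
) -> tuple[float, float, float]:
    """One-tailed two-sample t-test; returns ``(t, df, p)``.

    ``direction="greater"`` hypothesizes mean(x) > mean(y);
    ``direction="less"`` the reverse.  With ``equal_var`` the pooled
    Student formulation is used (df = n1 + n2 - 2), otherwise Welch with
    Welch-Satterthwaite degrees of freedom.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less' (stated explicitly)")
    a, b = _clean(x), _clean(y)
    na, nb = a.size, b.size
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; t-test undefined")
    diff = float(np.mean(a) - np.mean(b))
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t_stat = diff / se
    p = float(sps.t.sf(t_stat, df)) if direction == "greater" else float(sps.t.cdf(t_stat, df))
    return float(t_stat), float(df), p


def gated_comparison(x, y, direction: str, alpha: float = 0.05) -> GatedTestResult:
    """F-test gate followed by the matching one-tailed two-sample t-test."""
    f_stat, f_p, equal = f_test_equal_variance(x, y, alpha=alpha)
    t_stat, df, p = one_tailed_two_sample_t(x, y, equal_var=equal, direction=direction)
    a, b = _clean(x), _clean(y)
    return GatedTestResult(
        f_statistic=f_stat,
        f_p=f_p,
        chosen_test="student" if equal else "welch",
        t_statistic=t_stat,
        df=df,
        p_one_tailed=p,
        mean_x=float(np.mean(a)),
        mean_y=float(np.mean(b)),
        n_x=int(a.size),
        n_y=int(b.size),
        direction=direction,
    )


def synchrony_analysis(
    click_time_pairs: Sequence[tuple[float, float]],
    bin_width_s: float = 2.0,
    seed: Optional[int] = None,
    max_cross_pairs: Optional[int] = None,
) -> tuple[DelayDistribution, DelayDistribution]:
    """Pairwise vs. cross-trial randomized inter-click delay distributions.

    ``click_time_pairs`` holds, per jointly successful trial, the two
    players' click times in seconds.  The pairwise distribution takes the
    absolute within-trial delay; the randomized distribution enumerates
    *all* cross-trial pairings of player-1 and player-2 click times
    (``i != j``), deterministically.  ``seed``/``max_cross_pairs`` allow
    optional subsampling of very large cross-pair sets.  Both histograms
    share bin edges of width ``bin_width_s`` starting at 0 and are
    normalized to unit mass.
    """
    pairs = [(float(a), float(b)) for a, b in click_time_pairs]
    if len(pairs) < 2:
        raise ValueError("need at least two jointly successful trials for randomization")
    t1 = np.array([a for a, _ in pairs])
    t2 = np.array([b for _, b in pairs])
    pairwise = np.abs(t1 - t2)

    cross = np.abs(t1[:, None] - t2[None, :])
    mask = ~np.eye(len(pairs), dtype=bool)
    randomized = cross[mask].ravel()
    if max_cross_pairs is not None and randomized.size > max_cross_pairs:
        rng = np.random.default_rng(seed)
        randomized = rng.choice(randomized, size=max_cross_pairs, replace=False)

    top = max(pairwise.max(), randomized.max(), bin_width_s)
    edges = np.arange(0.0, np.ceil(top / bin_width_s) * bin_width_s + bin_width_s, bin_width_s)
    freq_p = np.histogram(pairwise, bins=edges)[0] / pairwise.size
    freq_r = np.histogram(randomized, bins=edges)[0] / randomized.size
    return (
        DelayDistribution(pairwise, "pairwise", edges, freq_p),
        DelayDistribution(randomized, "randomized", edges, freq_r),
    )


# ---------------------------------------------------------------------------
# dataset-level summaries and the exclusion rerun


def annotate_click_categories(clicks: pd.DataFrame) -> pd.DataFrame:
    """Attach per-click categories re-derived from the clicks present.

    Expects columns ``team, trial, player, target``; returns a copy with a
    ``category`` column.  Classification is recomputed from scratch, so
    removing one player's clicks can legitimately turn a Joint Success
    trial into a Single Success one.
    """
    out = clicks.copy()
    out["category"] = None
    for (_, _), grp in out.groupby(["team", "trial"], sort=False):
        targets: list[Optional[str]] = [None, None]
        for _, row in grp.iterrows():
            targets[int(row["player"])] = row["target"]
        outcome = classify_trial(targets)
        for idx, row in grp.iterrows():
            out.loc[idx, "category"] = outcome.click_categories[int(row["player"])]
    return out


def summarize_clicks(clicks: pd.DataFrame) -> dict:
    """Group means per click category for the rated quantities.

    ``clicks`` must carry columns ``team, trial, player, target`` and may
    carry ``tt``, ``pas``, ``cr``.  Returns category counts plus per-
    category means of each available quantity.
    """
    annotated = annotate_click_categories(clicks)
    summary: dict = {"n_clicks": int(len(annotated))}
    summary["category_counts"] = {
        c: int((annotated["category"] == c).sum()) for c in CLICK_CATEGORIES
    }
    for col in ("tt", "pas", "cr"):
        if col in annotated.columns:
            means = {}
            for c in CLICK_CATEGORIES:
                vals = pd.to_numeric(
                    annotated.loc[annotated["category"] == c, col], errors="coerce"
                ).dropna()
                means[c] = float(vals.mean()) if len(vals) else None
            summary[f"mean_{col}"] = means
    return summary


def exclude_player_rerun(
    clicks: pd.DataFrame, team: int, player: int
) -> dict:
    """Re-run the click summaries without one player's clicks and ratings.

    Returns ``{"full": ..., "excluded": ..., "deltas": ...}`` where the
    deltas are excluded-minus-full differences of every per-category mean
    that is defined on both sides.
    """
    key = (clicks["team"] == team) & (clicks["player"] == player)
    if not key.any():
        known = sorted(set(map(tuple, clicks[["team", "player"]].values.tolist())))
        raise ValueError(f"no clicks for player {(team, player)}; players present: {known}")
    full = summarize_clicks(clicks)
    excluded = summarize_clicks(clicks.loc[~key])
    deltas: dict = {}
    for name, means in full.items():
        if not name.startswith("mean_"):
            continue
        deltas[name] = {
            c: (excluded[name][c] - means[c])
            if means[c] is not None and excluded[name][c] is not None
            else None
            for c in means
        }
    return {"full": full, "excluded": excluded, "deltas": deltas}
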