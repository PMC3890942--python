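"""End-to-end analysis pipeline: recordings in, tables and statistics out.

The pipeline re-derives everything the tournament analyses need from raw
recordings: per-player contacts, attributed clicks with turn-taking
scores, trial outcomes, team scores, clicking accuracies, per-contact
click probabilities, rating frequency tables, variance-gated group
comparisons and the click-synchrony contrast.  Every output is a pure
function of (inputs, config, seed); a manifest with per-file checksums
makes reruns verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .events import assign_click_target, count_contacts_by_type, segment_contacts
from .geometry import OBJECT_TYPES, EnvConfig
from .inference import annotate_click_categories, gated_comparison, synchrony_analysis
from .simulate import Dataset, TrialRecording
from .stats import (
    JOINT_SUCCESS,
    classify_trial,
    click_probability_per_contact,
    clicking_accuracy,
    rating_frequency_table,
    team_score,
)
from .turntaking import tt_before_click

__all__ = ["PipelineResult", "RunManifest", "analyze_recordings", "run_pipeline"]


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: Optional[int]
    version: str
    inputs: dict
    row_counts: dict
    outputs: dict  # filename -> sha256
    warnings: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclasses.dataclass
class PipelineResult:
    """All tables and statistics computed from a set of recordings."""

    clicks: pd.DataFrame
    contacts: pd.DataFrame
    outcomes: pd.DataFrame
    team_scores: pd.DataFrame
    accuracies: pd.DataFrame
    contact_totals: dict
    click_totals: dict
    click_probabilities: dict
    pas_table: Optional[pd.DataFrame]
    cr_table: Optional[pd.DataFrame]
    gated_tests: pd.DataFrame
    synchrony: Optional[dict]
    warnings: list


def _trial_events(rec: TrialRecording) -> tuple[list[dict], list[dict]]:
    """Contacts and attributed clicks (with TT) for one recording."""
    team = rec.meta.get("team", 0)
    trial = rec.meta.get("trial", 0)
    period_s = rec.cfg.sample_period / 1000.0
    contact_rows, click_rows = [], []
    for player in (0, 1):
        overlaps = rec.overlap_series(player)
        stim = rec.stim(player)
        for c in segment_contacts(stim, overlaps, player=player):
            contact_rows.append(
                dict(team=team, trial=trial, player=player,
                     start_ms=int(round(c.start * rec.cfg.sample_period)),
                     end_ms=int(round(c.end * rec.cfg.sample_period)),
                     types=",".join(sorted(c.types)))
            )
        step = rec.click_step(player)
        if step is not None:
            target = assign_click_target(rec, player, step)
            if step > 0:
                tt = tt_before_click(rec, player, step)
                tt_val, c1, c2, t_steps = tt.tt, tt.c1, tt.c2, tt.t_steps
            else:
                tt_val = np.nan
                c1 = c2 = t_steps = 0
            click_rows.append(
                dict(team=team, trial=trial, player=player, step=step,
                     time_s=step * period_s, target=target,
                     tt=tt_val, c1=c1, c2=c2, t_steps=t_steps)
            )
    return contact_rows, click_rows


def analyze_recordings(
    recordings: Sequence[TrialRecording],
    questionnaires: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the complete analysis over a collection of recordings."""
    warnings: list[str] = []
    contact_rows: list[dict] = []
    click_rows: list[dict] = []
    trial_keys: list[tuple[int, int]] = []
    for rec in recordings:
        key = (rec.meta.get("team", 0), rec.meta.get("trial", 0))
        trial_keys.append(key)
        c_rows, k_rows = _trial_events(rec)
        contact_rows.extend(c_rows)
        click_rows.extend(k_rows)

    contacts = pd.DataFrame(
        contact_rows, columns=["team", "trial", "player", "start_ms", "end_ms", "types"]
    )
    clicks = pd.DataFrame(
        click_rows,
        columns=["team", "trial", "player", "step", "time_s", "target", "tt", "c1", "c2", "t_steps"],
    )

    # ratings joined onto clicks
    if questionnaires is not None and len(questionnaires):
        q = questionnaires.copy()
        rated_but_unclicked = q[q["clicked"].astype(bool)
                                & ~q.set_index(["team", "trial", "player"]).index.isin(
                                    clicks.set_index(["team", "trial", "player"]).index)]
        if len(rated_but_unclicked):
            warnings.append(
                f"{len(rated_but_unclicked)} questionnaire rows marked clicked have no click"
            )
        clicks = clicks.merge(
            q[["team", "trial", "player", "pas", "cr"]],
            on=["team", "trial", "player"], how="left",
        )
    else:
        clicks["pas"] = pd.NA
        clicks["cr"] = pd.NA

    # per-trial outcomes
    outcome_rows = []
    by_trial = clicks.groupby(["team", "trial"], sort=False)
    seen = set()
    for (team, trial), grp in by_trial:
        targets: list[Optional[str]] = [None, None]
        for _, row in grp.iterrows():
            targets[int(row["player"])] = row["target"]
        outcome_rows.append(
            dict(team=team, trial=trial, category=classify_trial(targets).category)
        )
        seen.add((team, trial))
    for team, trial in trial_keys:
        if (team, trial) not in seen:
            outcome_rows.append(dict(team=team, trial=trial, category="NoClicks"))
    outcomes = pd.DataFrame(outcome_rows, columns=["team", "trial", "category"])
    outcomes = outcomes.sort_values(["team", "trial"]).reset_index(drop=True)
    clicks = annotate_click_categories(clicks)

    # team scores and player accuracies
    score_rows = [
        dict(team=team, score=team_score(grp["target"]))
        for team, grp in clicks.groupby("team", sort=True)
    ]
    team_scores = pd.DataFrame(score_rows, columns=["team", "score"])
    acc_rows = []
    for (team, player), grp in clicks.groupby(["team", "player"], sort=True):
        acc_rows.append(
            dict(team=team, player=player, n_clicks=len(grp),
                 accuracy=clicking_accuracy(list(grp["target"])))
        )
    accuracies = pd.DataFrame(acc_rows, columns=["team", "player", "n_clicks", "accuracy"])

    # totals and per-contact click probabilities
    contact_totals = {t: 0 for t in OBJECT_TYPES}
    for types in contacts["types"]:
        for t in str(types).split(","):
            if t:
                contact_totals[t] += 1
    click_totals = {t: int((clicks["target"] == t).sum())
                    for t in (*OBJECT_TYPES, "none")}
    try:
        click_probabilities = click_probability_per_contact(click_totals, contact_totals)
    except ValueError as exc:
        warnings.append(str(exc))
        click_probabilities = {}

    # rating frequency tables
    pas_table = cr_table = None
    if clicks["pas"].notna().any():
        pas_table = rating_frequency_table(list(clicks["category"]), list(clicks["pas"]))
    if clicks["cr"].notna().any():
        cr_table = rating_frequency_table(list(clicks["category"]), list(clicks["cr"]))

    # variance-gated comparisons of PAS and TT across click categories
    comparisons = [
        ("joint_success", "single_success"),
        ("joint_success", "wrong"),
        ("single_success", "wrong"),
    ]
    test_rows = []
    for measure in ("pas", "tt"):
        for hi, lo in comparisons:
            x = pd.to_numeric(clicks.loc[clicks["category"] == hi, measure],
                              errors="coerce").dropna().to_numpy()
            y = pd.to_numeric(clicks.loc[clicks["category"] == lo, measure],
                              errors="coerce").dropna().to_numpy()
            row = dict(measure=measure, group_x=hi, group_y=lo,
                       n_x=len(x), n_y=len(y))
            if len(x) >= 2 and len(y) >= 2:
                try:
                    res = gated_comparison(x, y, direction="greater")
                    row.update(mean_x=res.mean_x, mean_y=res.mean_y,
                               chosen_test=res.chosen_test, t=res.t_statistic,
                               df=res.df, p_one_tailed=res.p_one_tailed)
                except ValueError as exc:
                    warnings.append(f"{measure} {hi}>{lo}: {exc}")
            test_rows.append(row)
    gated_tests = pd.DataFrame(test_rows)

    # click synchrony within jointly successful trials
    synchrony = None
    joint = outcomes.loc[outcomes["category"] == JOINT_SUCCESS, ["team", "trial"]]
    pairs = []
    for _, row in joint.iterrows():
        grp = clicks[(clicks["team"] == row["team"]) & (clicks["trial"] == row["trial"])]
        times = grp.sort_values("player")["time_s"].to_list()
        if len(times) == 2:
            pairs.append((times[0], times[1]))
    if len(pairs) >= 2:
        pairwise, randomized = synchrony_analysis(pairs, seed=seed)
        synchrony = {"pairwise": pairwise, "randomized": randomized, "n_trials": len(pairs)}

    return PipelineResult(
        clicks=clicks, contacts=contacts, outcomes=outcomes,
        team_scores=team_scores, accuracies=accuracies,
        contact_totals=contact_totals, click_totals=click_totals,
        click_probabilities=click_probabilities,
        pas_table=pas_table, cr_table=cr_table,
        gated_tests=gated_tests, synchrony=synchrony, warnings=warnings,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    dataset: Dataset,
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> PipelineResult:
    """Analyze a dataset and write the full report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = analyze_recordings(dataset.recordings, dataset.questionnaires, seed=seed)

    files = {
        "contacts.csv": result.contacts,
        "clicks.csv": result.clicks,
        "outcomes.csv": result.outcomes,
        "team_scores.csv": result.team_scores,
        "accuracies.csv": result.accuracies,
        "gated_tests.csv": result.gated_tests,
    }
    if result.pas_table is not None:
        files["pas_ratings.csv"] = result.pas_table.reset_index()
    if result.cr_table is not None:
        files["cr_ratings.csv"] = result.cr_table.reset_index()
    for name, frame in files.items():
        frame.to_csv(out / name, index=False)

    summary = {
        "contact_totals": result.contact_totals,
        "click_totals": result.click_totals,
        "click_probabilities_pct": result.click_probabilities,
        "outcome_counts": result.outcomes["category"].value_counts().to_dict(),
    }
    if result.synchrony is not None:
        for kind in ("pairwise", "randomized"):
            dist = result.synchrony[kind]
            pd.DataFrame(
                {"bin_start_s": dist.bin_edges[:-1], "bin_end_s": dist.bin_edges[1:],
                 "frequency": dist.frequencies}
            ).to_csv(out / f"synchrony_{kind}.csv", index=False)
        summary["synchrony_short_delay_freq"] = {
            kind: result.synchrony[kind].frequency_below(10.0)
            for kind in ("pairwise", "randomized")
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))

    manifest = RunManifest(
        config=dataset.cfg.to_dict(),
        seed=seed if seed is not None else dataset.meta.get("seed"),
        version=__version__,
        inputs={"n_recordings": len(dataset.recordings), "meta": dataset.meta},
        row_counts={name: int(len(frame)) for name, frame in files.items()},
        outputs={},
        warnings=result.warnings,
    )
    manifest.outputs = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.name not in ("manifest.json",) and p.is_file()
    }
    (out / "manifest.json").write_text(manifest.to_json())
    return result
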