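"""Trial-log, config and questionnaire serialization.

Trial logs are plain TSV, one row per step, preceded by a ``#``-prefixed
header block carrying the environment config (JSON), the static-object
positions, and the generation metadata.  All times are serialized as
integer milliseconds (step x sample_period) so logs carry no float drift.
Positions use 17 significant digits, which round-trips IEEE doubles
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .geometry import EnvConfig
from .simulate import Dataset, TrialRecording

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "write_config",
    "read_config",
    "save_dataset",
    "load_dataset",
]

_LOG_MAGIC = "# percross-trial-log v1"
_COLUMNS = ["step", "time_ms", "p1_pos", "p2_pos", "p1_stim", "p2_stim", "p1_click", "p2_click"]


def write_trial_log(rec: TrialRecording, path: Union[str, Path]) -> None:
    """Write one recording as a header-plus-TSV trial log."""
    path = Path(path)
    cfg = rec.cfg
    n = rec.n_steps
    stim = np.stack([rec.stim(0), rec.stim(1)]).astype(int)
    click_cols = np.zeros((2, n), dtype=int)
    for p, step in rec.clicks:
        click_cols[p, step] = 1
    with path.open("w") as fh:
        fh.write(_LOG_MAGIC + "\n")
        fh.write(f"# config: {json.dumps(cfg.to_dict())}\n")
        fh.write(f"# static_pos: {json.dumps([float(x) for x in rec.static_pos])}\n")
        fh.write(f"# meta: {json.dumps(rec.meta, default=str)}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        period = cfg.sample_period
        for t in range(n):
            fh.write(
                f"{t}\t{int(round(t * period))}\t{rec.pos[0, t]:.17g}\t{rec.pos[1, t]:.17g}\t"
                f"{stim[0, t]}\t{stim[1, t]}\t{click_cols[0, t]}\t{click_cols[1, t]}\n"
            )


def read_trial_log(path: Union[str, Path]) -> TrialRecording:
    """Read a trial log back into a :class:`TrialRecording`.

    Validates the header, column set, step monotonicity and position
    range; stimulation columns are informational (they are re-derivable
    from positions) and are not stored.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != _LOG_MAGIC:
            raise ValueError(f"{path}: not a percross trial log (bad magic line)")
        pos_in_file = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
            pos_in_file = fh.tell()
        fh.seek(pos_in_file)
        table = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    for key in ("config", "static_pos"):
        if key not in header:
            raise ValueError(f"{path}: malformed header, missing '# {key}:' line")
    cfg = EnvConfig.from_dict(json.loads(header["config"]))
    static_pos = np.asarray(json.loads(header["static_pos"]), dtype=float)
    meta = json.loads(header.get("meta", "{}"))

    for col in _COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    steps = table["step"].to_numpy()
    if not (np.diff(steps) == 1).all() or steps[0] != 0:
        raise ValueError(f"{path}: step column must increase by 1 from 0")
    pos = np.stack([table["p1_pos"].to_numpy(float), table["p2_pos"].to_numpy(float)])
    if ((pos < 0) | (pos >= cfg.space_length)).any():
        bad = pos[(pos < 0) | (pos >= cfg.space_length)][0]
        raise ValueError(f"{path}: position {bad} outside [0, {cfg.space_length})")
    clicks = []
    for p, col in enumerate(("p1_click", "p2_click")):
        marked = np.flatnonzero(table[col].to_numpy(int))
        if marked.size > 1:
            raise ValueError(f"{path}: more than one retained click in {col}")
        if marked.size == 1:
            clicks.append((p, int(marked[0])))
    rec = TrialRecording(cfg=cfg, pos=pos, static_pos=static_pos, clicks=clicks, meta=meta)
    rec.validate()
    return rec


def write_config(cfg: EnvConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def read_config(path: Union[str, Path]) -> EnvConfig:
    return EnvConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_dataset(dataset: Dataset, out_dir: Union[str, Path]) -> None:
    """Write a generated dataset as trial logs plus CSV side tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        team, trial = rec.meta.get("team", 0), rec.meta.get("trial", 0)
        write_trial_log(rec, out / f"team{team:03d}_trial{trial:03d}.tsv")
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    dataset.questionnaires.to_csv(out / "questionnaires.csv", index=False)
    (out / "dataset.json").write_text(
        json.dumps({"meta": dataset.meta, "config": dataset.cfg.to_dict()}, indent=2)
    )


def load_dataset(in_dir: Union[str, Path]) -> Dataset:
    """Read back a dataset directory written by :func:`save_dataset`."""
    src = Path(in_dir)
    info = json.loads((src / "dataset.json").read_text())
    cfg = EnvConfig.from_dict(info["config"])
    recordings = [read_trial_log(p) for p in sorted(src.glob("team*_trial*.tsv"))]
    ground_truth = pd.read_csv(src / "ground_truth.csv")
    questionnaires = pd.read_csv(src / "questionnaires.csv")
    return Dataset(
        cfg=cfg,
        recordings=recordings,
        ground_truth=ground_truth,
        questionnaires=questionnaires,
        meta=info["meta"],
    )
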