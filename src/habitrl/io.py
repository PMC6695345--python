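"""Trial-log CSV format, config files, and report headers.

The cohort trial log is one CSV row per trial with columns
subject_id, group, phase, block, trial, stimulus_id, response, reward,
devalued_flag.  Responses are written as the strings left/right (learning
phase), go/nogo (devaluation phase) or miss, and held internally as the
integer codes 0/1/2/3/-1.  Schema violations are rejected with the
offending row numbers.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import TRIAL_COLUMNS

RESPONSE_TO_STR = {0: "left", 1: "right", 2: "go", 3: "nogo", -1: "miss"}
STR_TO_RESPONSE = {v: k for k, v in RESPONSE_TO_STR.items()}

_LEARNING_RESPONSES = {0, 1, -1}
_DEV_RESPONSES = {2, 3, -1}


class TrialLogError(ValueError):
    pass


def write_trial_log(records: pd.DataFrame, path, header_comment: str | None = None) -> None:
    df = records.loc[:, list(TRIAL_COLUMNS)].copy()
    df["response"] = df["response"].map(RESPONSE_TO_STR)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    extra = set(df.columns) - set(TRIAL_COLUMNS)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if extra or missing:
        raise TrialLogError(f"bad columns: extra {sorted(extra)}, missing {sorted(missing)}")
    if len(df) == 0:
        return df.loc[:, list(TRIAL_COLUMNS)]
    bad = df[~df["response"].isin(STR_TO_RESPONSE)]
    if len(bad):
        raise TrialLogError(f"unknown response codes at rows {list(bad.index[:5])}")
    df["response"] = df["response"].map(STR_TO_RESPONSE)
    problems = []
    learn = df[df["phase"] == "learning"]
    dev = df[df["phase"] == "devaluation"]
    unknown_phase = df[~df["phase"].isin(["learning", "devaluation"])]
    if len(unknown_phase):
        problems.append(f"unknown phase at rows {list(unknown_phase.index[:5])}")
    r = learn["reward"]
    bad = learn[(learn["response"] >= 0) & ~r.isin([0, 1])]
    if len(bad):
        problems.append(f"learning reward must be 0/1: rows {list(bad.index[:5])}")
    bad = learn[~learn["response"].isin(_LEARNING_RESPONSES)]
    if len(bad):
        problems.append(f"learning response must be left/right/miss: rows {list(bad.index[:5])}")
    bad = dev[~dev["response"].isin(_DEV_RESPONSES)]
    if len(bad):
        problems.append(f"devaluation response must be go/nogo/miss: rows {list(bad.index[:5])}")
    bad = dev[~dev["devalued_flag"].isin([0, 1])]
    if len(bad):
        problems.append(f"devaluation rows need devalued_flag 0/1: rows {list(bad.index[:5])}")
    stim_bad = df[~df["stimulus_id"].isin(range(6))]
    if len(stim_bad):
        problems.append(f"stimulus_id outside 0-5: rows {list(stim_bad.index[:5])}")
    keys = df[["subject_id", "phase", "block", "trial"]].astype(str).agg("|".join, axis=1)
    dup = df[keys.duplicated()]
    if len(dup):
        problems.append(f"duplicate (subject, phase, block, trial) keys: rows {list(dup.index[:5])}")
    if problems:
        raise TrialLogError("; ".join(problems))
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def report_header(cfg: dict | None = None) -> str:
    from . import __version__

    h = config_hash(cfg) if cfg is not None else "none"
    return f"habitrl {__version__}; config {h}"


def write_table(df: pd.DataFrame, path, cfg: dict | None = None) -> None:
    """CSV with a provenance header comment (package version + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# {report_header(cfg)}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
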