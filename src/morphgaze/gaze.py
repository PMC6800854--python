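"""Fixation records and per-trial eye-tracking measures.

Three measures per subject x item trial:

FFD
    first fixation duration — the duration of the first fixation on the
    target word (early processing index).
GD
    gaze duration — the summed duration of fixations on the word.  In the
    single-word design this is all fixations on the word; in the word-row
    design only the *first run* counts (the maximal initial block of
    consecutive fixations on the target, i.e. first-pass reading).
GmF
    GD minus FFD (late processing index); entered as missing when the
    defining run contains a single fixation.

Fixation report dialect (TSV with header)::

    subject trial item fixation_index interest_area onset_ms duration_ms
    x_offset_letters response_correct rt_ms list_id row_position
    presentation_order

``x_offset_letters`` is the signed letter offset of the fixation from the
left border of the *next* interest area to the right (negative when the
fixation lies left of that border).  The launch site of a target word is
minus that offset for the last fixation in the preceding interest area,
so positive values mean launches from the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MEASURE_COLUMNS = [
    "subject", "item", "FFD", "GD", "GmF", "presentation_order",
    "launch_site", "row_position", "rt_ms", "response_correct",
    "list_id", "excluded", "exclude_reason",
]


@dataclass(frozen=True)
class FixationRecord:
    subject: str
    trial: str
    index_in_trial: int
    interest_area: int
    onset: float
    duration: float
    x_offset_letters: float = math.nan

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")
        if self.index_in_trial < 1:
            raise ValueError("index_in_trial starts at 1")


@dataclass
class TrialRecord:
    subject: str
    item: str
    fixations: list[FixationRecord]
    presentation_order: int = 0
    list_id: str | None = None
    row_position: int | None = None
    response_correct: bool | None = None
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        onsets = [f.onset for f in self.fixations]
        if onsets != sorted(onsets):
            raise ValueError("fixations must be ordered by onset")


def _row(subject, item, ffd, gd, gmf, trial: TrialRecord,
         launch=math.nan, excluded=False, reason=""):
    return {
        "subject": subject, "item": item, "FFD": ffd, "GD": gd, "GmF": gmf,
        "presentation_order": trial.presentation_order,
        "launch_site": launch, "row_position": trial.row_position,
        "rt_ms": trial.rt_ms, "response_correct": trial.response_correct,
        "list_id": trial.list_id, "excluded": excluded,
        "exclude_reason": reason,
    }


def compute_measures_exp1(trial: TrialRecord) -> dict:
    """Single-word design: FFD, GD over all fixations, GmF.

    GmF is missing when the word received exactly one fixation.
    """
    fixes = [f for f in trial.fixations if f.interest_area == 1]
    if not fixes:
        return _row(trial.subject, trial.item, math.nan, math.nan, math.nan,
                    trial, excluded=True, reason="no-fixation")
    ffd = fixes[0].duration
    gd = sum(f.duration for f in fixes)
    gmf = gd - ffd if len(fixes) > 1 else math.nan
    return _row(trial.subject, trial.item, ffd, gd, gmf, trial)


def compute_measures_exp2(trial: TrialRecord, target_area: int) -> dict:
    """Word-row design: first-run (first-pass) measures plus launch site.

    The first run is the maximal block of consecutive fixations on the
    target area starting at first entry; refixations after leaving the
    area are excluded.  The launch site is the letter distance from the
    last fixation in the previous interest area to the left border of the
    target area.
    """
    fixes = trial.fixations
    entry = next(
        (i for i, f in enumerate(fixes) if f.interest_area == target_area),
        None,
    )
    if entry is None:
        return _row(trial.subject, f"{trial.item}", math.nan, math.nan,
                    math.nan, trial, excluded=True, reason="skipped")
    run = [fixes[entry]]
    for f in fixes[entry + 1:]:
        if f.interest_area != target_area:
            break
        run.append(f)
    ffd = run[0].duration
    gd = sum(f.duration for f in run)
    gmf = gd - ffd if len(run) > 1 else math.nan
    launch = math.nan
    if entry > 0 and fixes[entry - 1].interest_area == target_area - 1:
        off = fixes[entry - 1].x_offset_letters
        if not math.isnan(off):
            launch = -off
    return _row(trial.subject, trial.item, ffd, gd, gmf, trial, launch=launch)


def measures_table(trials: Iterable[TrialRecord], design: str) -> pd.DataFrame:
    """Build a measure table for a set of trials.

    In the word-row design each trial record covers one target occurrence
    (``row_position`` names its interest area) with the fixation context
    needed to recover the first run and the launch site.
    """
    rows = []
    if design == "exp1":
        for t in trials:
            rows.append(compute_measures_exp1(t))
    elif design == "exp2":
        for t in trials:
            rows.append(compute_measures_exp2(t, t.row_position))
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


# ---------------------------------------------------------------------------
# trimming and exclusion
# ---------------------------------------------------------------------------

def trim_outliers(
    table: pd.DataFrame, measure: str, k_sd: float = 3.0
) -> pd.DataFrame:
    """Per-subject +-k SD trimming on *measure* (single pass).

    Bounds use each subject's mean and sample SD (n-1) over that
    subject's currently included rows; rows outside them are flagged
    ``outlier``.  Subjects with fewer than two included rows, or zero SD,
    are left untouched.
    """
    if measure not in table.columns:
        raise ValueError(f"measure {measure!r} not in table")
    out = table.copy()
    included = ~out["excluded"] & out[measure].notna()
    for subj, grp in out.loc[included].groupby("subject"):
        vals = grp[measure]
        if len(vals) < 2:
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0 or not np.isfinite(k_sd):
            continue
        bad = grp.index[(vals > mean + k_sd * sd) | (vals < mean - k_sd * sd)]
        out.loc[bad, "excluded"] = True
        out.loc[bad, "exclude_reason"] = "outlier"
    return out


def exclude_error_and_subjects(
    table: pd.DataFrame, max_error_rate: float = 0.15
) -> pd.DataFrame:
    """Drop error trials, then subjects whose error rate exceeds the cap.

    The per-subject error rate is computed over all the subject's
    responses; the criterion is a strict inequality (a rate exactly at
    the cap is retained).
    """
    out = table.copy()
    has_resp = out["response_correct"].notna()
    rates = (
        (~out.loc[has_resp, "response_correct"].astype(bool))
        .groupby(out.loc[has_resp, "subject"])
        .mean()
    )
    err_trials = has_resp & ~out["response_correct"].astype(bool)
    out.loc[err_trials & ~out["excluded"], "exclude_reason"] = "error"
    out.loc[err_trials, "excluded"] = True
    bad_subjects = set(rates.index[rates > max_error_rate])
    in_bad = out["subject"].isin(bad_subjects)
    out.loc[in_bad & ~out["excluded"], "exclude_reason"] = "subject-error-rate"
    out.loc[in_bad, "excluded"] = True
    return out


def split_by_length(
    items: Iterable[str], threshold_letters: int = 8
) -> tuple[set[str], set[str]]:
    """Split items into short (<= threshold letters) and long (>=)."""
    short = {w for w in items if len(w) <= threshold_letters}
    long_ = {w for w in items if len(w) > threshold_letters}
    return short, long_


# ---------------------------------------------------------------------------
# fixation report I/O
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "subject", "trial", "item", "fixation_index", "interest_area",
    "onset_ms", "duration_ms", "x_offset_letters", "response_correct",
    "rt_ms", "list_id", "row_position", "presentation_order",
]


def write_fixation_report(
    trials: Iterable[TrialRecord], path: str | Path
) -> None:
    rows = []
    for i, t in enumerate(trials):
        for f in t.fixations:
            rows.append({
                "subject": t.subject, "trial": f"t{i}", "item": t.item,
                "fixation_index": f.index_in_trial,
                "interest_area": f.interest_area, "onset_ms": f.onset,
                "duration_ms": f.duration,
                "x_offset_letters": f.x_offset_letters,
                "response_correct": t.response_correct, "rt_ms": t.rt_ms,
                "list_id": t.list_id, "row_position": t.row_position,
                "presentation_order": t.presentation_order,
            })
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_fixation_report(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation report missing columns: {sorted(missing)}")
    trials: list[TrialRecord] = []
    for (_subj, trial_id), grp in df.groupby(["subject", "trial"], sort=False):
        grp = grp.sort_values("onset_ms")
        first = grp.iloc[0]
        fixes = [
            FixationRecord(
                subject=str(r.subject), trial=str(trial_id),
                index_in_trial=int(r.fixation_index),
                interest_area=int(r.interest_area), onset=float(r.onset_ms),
                duration=float(r.duration_ms),
                x_offset_letters=float(r.x_offset_letters),
            )
            for r in grp.itertuples()
        ]
        rc = first["response_correct"]
        trials.append(TrialRecord(
            subject=str(first["subject"]), item=str(first["item"]),
            fixations=fixes,
            presentation_order=int(first["presentation_order"]),
            list_id=None if pd.isna(first["list_id"]) else str(first["list_id"]),
            row_position=(
                None if pd.isna(first["row_position"])
                else int(first["row_position"])
            ),
            response_correct=None if pd.isna(rc) else bool(rc),
            rt_ms=None if pd.isna(first["rt_ms"]) else float(first["rt_ms"]),
        ))
    return trials
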