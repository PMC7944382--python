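"""Ingestion, validation and filtering of ecological momentary assessment data.

EMA responses arrive as a long-format table: one row per scheduled prompt per
participant, with three 0-9 integer items (desire to kill oneself, intent to
kill oneself, ability to resist the urge) that are empty when the prompt went
unanswered.  This module validates that table row by row, groups it into
per-participant :class:`EmaSeries`, applies the minimum-completed-surveys
inclusion rule, and computes percentage compliance (the complement of the
"missingness" predictor used by the secondary models).

A record counts as completed when at least one item was answered; features
downstream use whichever items are present.  The compliance denominator is
the number of scheduled prompts, which is known exactly in simulation and
can be supplied for real data via a schedule table (participant_id,
n_scheduled); without one it defaults to the number of rows present for the
participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ITEM_COLUMNS = ("desire", "intent", "resist_urge")
EMA_COLUMNS = ("participant_id", "timestamp", "answered") + ITEM_COLUMNS


class EmaValidationError(ValueError):
    """Raised for malformed EMA tables; message names the offending rows."""


@dataclass
class EmaSeries:
    """One participant's time-ordered EMA prompt records.

    ``records`` holds one row per scheduled prompt (answered or not), sorted
    by timestamp, with columns prompt_index, timestamp, answered, desire,
    intent, resist_urge.  ``n_scheduled`` may exceed ``len(records)`` when a
    schedule table reports prompts that produced no row at all.
    """

    participant_id: str
    records: pd.DataFrame
    n_scheduled: int = 0

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)
        if self.n_scheduled == 0:
            self.n_scheduled = len(self.records)
        if self.n_completed > self.n_scheduled:
            raise EmaValidationError(
                f"participant {self.participant_id}: completed "
                f"{self.n_completed} > scheduled {self.n_scheduled}"
            )

    @property
    def n_completed(self) -> int:
        return int(self.records["answered"].sum())

    def item_values(self, item: str) -> np.ndarray:
        """Completed responses for one item, in time order, missing dropped."""
        v = self.records.loc[self.records["answered"], item]
        return v.dropna().to_numpy(dtype=float)

    def compliance(self) -> float:
        if self.n_scheduled < 1:
            raise EmaValidationError(
                f"participant {self.participant_id}: schedule required "
                "(n_scheduled must be >= 1)"
            )
        return self.n_completed / self.n_scheduled

    def compliance_percent(self) -> float:
        return 100.0 * self.compliance()


def compliance_percent(series: EmaSeries) -> float:
    """Percentage compliance: 100 x completed / scheduled prompts."""
    return series.compliance_percent()


def _validate_rows(df: pd.DataFrame) -> None:
    problems = []
    for col in EMA_COLUMNS:
        if col not in df.columns:
            raise EmaValidationError(f"missing required column {col!r}")
    for col in ITEM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_numeric = df[col].notna() & vals.isna()
        out_of_range = vals.notna() & ((vals < 0) | (vals > 9) | (vals % 1 != 0))
        for idx in df.index[bad_numeric | out_of_range]:
            value = df.at[idx, col]
            value = value.item() if hasattr(value, "item") else value
            problems.append(f"row {idx + 2}: {col}={value!r} not an integer in 0-9")
    dup = df.duplicated(subset=["participant_id", "timestamp"], keep=False)
    if dup.any():
        for idx in df.index[dup]:
            problems.append(
                f"row {idx + 2}: duplicate prompt for participant "
                f"{df.at[idx, 'participant_id']} at {df.at[idx, 'timestamp']}"
            )
    answered = df["answered"].astype(bool)
    items = df[list(ITEM_COLUMNS)]
    ghost = ~answered & items.notna().any(axis=1)
    for idx in df.index[ghost]:
        problems.append(f"row {idx + 2}: unanswered prompt carries item values")
    empty = answered & items.isna().all(axis=1)
    for idx in df.index[empty]:
        problems.append(f"row {idx + 2}: answered prompt with no item values")
    if problems:
        raise EmaValidationError("malformed EMA table:\n  " + "\n  ".join(problems))


def read_ema_table(path, schedule_path=None) -> list[EmaSeries]:
    """Read a long-format EMA CSV into one :class:`EmaSeries` per participant.

    Row numbers in error messages are 1-based file lines (header = line 1).
    An optional schedule CSV (participant_id, n_scheduled) overrides the
    per-participant scheduled-prompt count.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    return series_from_frame(df, schedule=_read_schedule(schedule_path))


def _read_schedule(schedule_path) -> dict | None:
    if schedule_path is None:
        return None
    sched = pd.read_csv(schedule_path, dtype={"participant_id": str})
    return dict(zip(sched["participant_id"], sched["n_scheduled"].astype(int)))


def series_from_frame(df: pd.DataFrame, schedule: dict | None = None) -> list[EmaSeries]:
    """Group a validated long-format frame into time-sorted EmaSeries."""
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    _validate_rows(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        grp["prompt_index"] = np.arange(len(grp))
        grp["answered"] = grp["answered"].astype(bool)
        n_sched = schedule.get(pid, len(grp)) if schedule else len(grp)
        cols = ["prompt_index", "timestamp", "answered", *ITEM_COLUMNS]
        out.append(EmaSeries(pid, grp[cols], n_scheduled=int(n_sched)))
    return out


def write_ema_table(cohort, path) -> None:
    """Write a cohort back to the long-format CSV schema (round-trips exactly)."""
    frames = []
    for s in cohort:
        f = s.records.copy()
        f.insert(0, "participant_id", s.participant_id)
        frames.append(f[list(EMA_COLUMNS)])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_schedule_table(cohort, path) -> None:
    pd.DataFrame(
        {"participant_id": [s.participant_id for s in cohort],
         "n_scheduled": [s.n_scheduled for s in cohort]}
    ).to_csv(path, index=False)


def apply_inclusion_filter(cohort, min_completed: int = 3) -> tuple[list, list]:
    """Partition a cohort into (included, excluded) by completed-survey count.

    Participants with at least ``min_completed`` completed EMA surveys are
    included; the partition is exhaustive and disjoint.
    """
    included = [s for s in cohort if s.n_completed >= min_completed]
    excluded = [s for s in cohort if s.n_completed < min_completed]
    return included, excluded


def cohort_summary(cohort, included=None, outcomes=None) -> dict:
    """Descriptive summary in the study's reporting style.

    Percentages are rounded to one decimal as printed: retention =
    included/enrolled, base rate = positives/included, mean compliance over
    included participants.
    """
    summary: dict = {"n_enrolled": len(cohort)}
    if included is None:
        included, _ = apply_inclusion_filter(cohort)
    summary["n_included"] = len(included)
    summary["retention_percent"] = round(100.0 * len(included) / len(cohort), 1)
    counts = [s.n_completed for s in included]
    summary["total_surveys"] = int(np.sum(counts)) if counts else 0
    summary["median_responses"] = float(np.median(counts)) if counts else np.nan
    summary["response_range"] = (int(np.min(counts)), int(np.max(counts))) if counts else None
    comp = [s.compliance_percent() for s in included]
    summary["mean_compliance_percent"] = round(float(np.mean(comp)), 1) if comp else np.nan
    summary["sd_compliance_percent"] = round(float(np.std(comp, ddof=1)), 1) if len(comp) > 1 else np.nan
    if outcomes is not None:
        y = np.asarray([outcomes[s.participant_id] for s in included], dtype=int)
        summary["n_positive"] = int(y.sum())
        summary["base_rate_percent"] = round(100.0 * y.mean(), 1) if y.size else np.nan
    return summary
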