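"""Cohort I/O: tidy-CSV exchange format, NHANES-style ingestion, SSRI labels.

The internal exchange format is three tidy CSV files (UTF-8, header row,
missing values as empty fields):

* ``activity.csv``      — participant_id, minute_index (0-10079), intensity,
  reliability_flag
* ``medications.csv``   — participant_id, generic_name
* ``participants.csv``  — participant_id, age, sex, race, phq9 (blank =
  missing), label (optional ground truth)

Real NHANES files (PAXRAW_D, RXQ_RX_D, DPQ_D, DEMO_D) can be ingested from
SAS transport (XPT) via :func:`read_xpt`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MINUTES_PER_WEEK, SyntheticCohort

logger = logging.getLogger(__name__)

#: generic-name stems defining SSRI exposure
SSRI_STEMS = ("SERTRALINE", "ESCITALOPRAM", "FLUOXETINE", "PAROXETINE", "CITALOPRAM")

COMPLETENESS_POLICIES = ("strict-drop", "zero-pad")


@dataclass
class IngestReport:
    """Per-ingestion bookkeeping: who was kept, who was dropped and why."""

    kept_ids: list
    dropped: dict  # participant_id -> reason
    bad_rows: list  # (row_index, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def read_activity_records(
    source: pd.DataFrame | str | Path,
    completeness_policy: str = "strict-drop",
) -> tuple[np.ndarray, np.ndarray, IngestReport]:
    """Long-format minute records -> (participants x 10,080) activity matrix.

    ``strict-drop`` keeps only participants with all 10,080 minutes present
    and every reliability flag true; ``zero-pad`` fills absent minutes with
    zero and keeps everyone with at least one valid row.  Returns the matrix,
    the kept participant ids (sorted), and an :class:`IngestReport`.
    """
    if completeness_policy not in COMPLETENESS_POLICIES:
        raise ValueError(f"completeness_policy must be one of {COMPLETENESS_POLICIES}")
    table = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source.copy()

    bad_rows: list[tuple[int, str]] = []
    required = {"participant_id", "minute_index", "intensity"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"activity table missing columns: {sorted(missing_cols)}")
    if "reliability_flag" not in table.columns:
        table["reliability_flag"] = True

    minute = pd.to_numeric(table["minute_index"], errors="coerce")
    intensity = pd.to_numeric(table["intensity"], errors="coerce")
    bad = minute.isna() | intensity.isna()
    bad |= (minute < 0) | (minute >= MINUTES_PER_WEEK) | (intensity < 0)
    for idx in table.index[bad]:
        bad_rows.append((int(idx), "unparseable or out-of-range minute/intensity"))
    table = table.loc[~bad].assign(minute_index=minute[~bad].astype(int), intensity=intensity[~bad])

    dropped: dict = {}
    kept_ids: list = []
    rows: list[np.ndarray] = []
    for pid, sub in table.groupby("participant_id", sort=True):
        if sub["minute_index"].duplicated().any():
            dropped[pid] = "duplicate minute_index"
            continue
        reliable = sub["reliability_flag"].astype(bool).all()
        complete = len(sub) == MINUTES_PER_WEEK
        if completeness_policy == "strict-drop":
            if not complete:
                dropped[pid] = f"incomplete week ({len(sub)} of {MINUTES_PER_WEEK} minutes)"
                continue
            if not reliable:
                dropped[pid] = "reliability flag false"
                continue
            week = sub.sort_values("minute_index")["intensity"].to_numpy(dtype=float)
        else:  # zero-pad
            week = np.zeros(MINUTES_PER_WEEK)
            week[sub["minute_index"].to_numpy()] = sub["intensity"].to_numpy(dtype=float)
        kept_ids.append(pid)
        rows.append(week)

    report = IngestReport(kept_ids=kept_ids, dropped=dropped, bad_rows=bad_rows)
    if dropped:
        logger.info("read_activity_records: dropped %d participants: %s", len(dropped), dropped)
    if bad_rows:
        logger.warning("read_activity_records: %d malformed rows rejected", len(bad_rows))
    if not rows:
        raise ValueError("no participants survived the completeness policy")
    return np.vstack(rows), np.asarray(kept_ids), report


def classify_ssri(
    medications: pd.DataFrame, participant_ids: np.ndarray | list
) -> np.ndarray:
    """Binary SSRI-exposure label per participant from medication records.

    A participant is labelled exposed iff any reported generic name contains
    one of the five SSRI stems (sertraline, escitalopram, fluoxetine,
    paroxetine, citalopram).  Matching is case-insensitive and stem-based, so
    salt suffixes (hydrochloride, oxalate, ...) are irrelevant; participants
    absent from the medication table are labelled unexposed.
    """
    if medications["generic_name"].isna().any() or (medications["generic_name"] == "").any():
        raise ValueError("medication table contains empty generic names")
    names = medications["generic_name"].str.upper()
    is_ssri = np.zeros(len(medications), dtype=bool)
    for stem in SSRI_STEMS:
        is_ssri |= names.str.contains(stem, regex=False).to_numpy()
    exposed_ids = set(medications.loc[is_ssri, "participant_id"])
    ids = np.asarray(participant_ids)
    missing = set(ids) - set(medications["participant_id"])
    if missing:
        logger.info("classify_ssri: %d participants have no medication records", len(missing))
    return np.array([pid in exposed_ids for pid in ids], dtype=np.int8)


def read_phq9(
    source: pd.DataFrame | str | Path, participant_ids: np.ndarray | list
) -> tuple[np.ndarray, list]:
    """PHQ-9 scores aligned to ``participant_ids``; NaN marks missing.

    Scores must be integers in [0, 27] or blank; out-of-range rows are
    rejected (reported, not silently coerced).  Participants without a row
    are missing.
    """
    table = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    scores = pd.to_numeric(table["phq9"], errors="coerce")
    present = table["phq9"].notna() if table["phq9"].dtype == object else scores.notna()
    out_of_range = present & (scores.isna() | (scores < 0) | (scores > 27))
    rejected = [(int(i), str(table["phq9"].iloc[int(i)])) for i in np.flatnonzero(out_of_range)]
    if rejected:
        logger.warning("read_phq9: rejected %d out-of-range rows: %s", len(rejected), rejected)
    valid = table.loc[~out_of_range]
    lookup = dict(zip(valid["participant_id"], scores.loc[valid.index]))
    values = np.array([lookup.get(pid, np.nan) for pid in np.asarray(participant_ids)], dtype=float)
    return values, rejected


def read_xpt(path: str | Path) -> pd.DataFrame:
    """Read a SAS transport (XPT v5) file as distributed by NHANES."""
    return pd.read_sas(path, format="xport")


# ---------------------------------------------------------------------------
# tidy-CSV round trip for synthetic cohorts


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to the tidy-CSV exchange format; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = cohort.participant_ids

    n = cohort.n_participants
    activity = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, MINUTES_PER_WEEK),
            "minute_index": np.tile(np.arange(MINUTES_PER_WEEK), n),
            "intensity": cohort.activity.ravel(),
            "reliability_flag": True,
        }
    )
    participants = cohort.demographics.copy()
    participants["phq9"] = cohort.phq9
    participants["label"] = cohort.labels

    paths = {
        "activity": directory / "activity.csv",
        "medications": directory / "medications.csv",
        "participants": directory / "participants.csv",
    }
    activity.to_csv(paths["activity"], index=False)
    cohort.medication_table().to_csv(paths["medications"], index=False)
    participants.to_csv(paths["participants"], index=False)
    return paths


def read_cohort(directory: str | Path):
    """Read back a tidy-CSV cohort directory.

    Returns (activity matrix, participant ids, labels, demographics, phq9);
    labels are derived from the medication table via :func:`classify_ssri`.
    """
    directory = Path(directory)
    activity, ids, report = read_activity_records(directory / "activity.csv")
    medications = pd.read_csv(directory / "medications.csv")
    labels = classify_ssri(medications, ids)
    participants = pd.read_csv(directory / "participants.csv")
    participants = (
        participants.set_index("participant_id").loc[ids].reset_index()
    )
    phq9, _ = read_phq9(participants, ids)
    demographics = participants[["participant_id", "age", "sex", "race"]]
    return activity, ids, labels, demographics, phq9
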