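"""Trial data schema, CSV I/O and cross-table validation.

Two tables describe a two-arm randomized trial:

``subjects``
    one row per randomized patient: treatment arm, progression-free survival
    (PFS) and overall survival (OS) in integer study days (day 1 = day of
    randomization) with event flags, plus arbitrary categorical covariate
    columns used for subgroup analyses.

``adverse_events``
    one row per adverse-event episode: onset and resolution study day
    (resolution may be blank for an ongoing event), CTCAE grade 1-5, a
    regulatory seriousness flag and a treatment-emergent flag.

All times are integer study days; fractional days are rejected so that the
day-level union rule for overlapping toxicity intervals is well defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ReferentialError, SchemaError

ARM_ACTIVE = "active"
ARM_CONTROL = "control"
ARMS = (ARM_ACTIVE, ARM_CONTROL)

SUBJECT_REQUIRED = [
    "subject_id",
    "arm",
    "pfs_days",
    "pfs_event",
    "os_days",
    "os_event",
]
AE_REQUIRED = [
    "subject_id",
    "start_day",
    "end_day",
    "grade",
    "serious",
    "treatment_emergent",
]


def _check_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _coerce_int(
    series: pd.Series, table: str, column: str, *, allow_na: bool = False, minimum: int | None = None
) -> pd.Series:
    """Coerce a column to integers, reporting offending rows by CSV row number.

    Row numbers are 1-based including the header row, matching what a user
    sees in a text editor.
    """
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if not allow_na:
        bad |= series.isna()
    fractional = numeric.notna() & (numeric % 1 != 0)
    bad |= fractional
    if minimum is not None:
        bad |= numeric.notna() & (numeric < minimum)
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise SchemaError(
            f"{table}.{column}: unparseable, fractional or out-of-range values "
            f"at row(s) {rows} (integer study days required)"
        )
    return numeric.astype("Int64" if allow_na else "int64")


def _coerce_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = series.isna() | numeric.isna() | ~numeric.isin([0, 1])
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise SchemaError(f"{table}.{column}: values must be 0/1; bad row(s) {rows}")
    return numeric.astype(bool)


@dataclass
class TrialDataset:
    """Validated subject and adverse-event tables for a two-arm trial.

    Parameters
    ----------
    subjects
        Subject-level table with the :data:`SUBJECT_REQUIRED` columns plus any
        number of categorical covariate columns.
    adverse_events
        Adverse-event interval table with the :data:`AE_REQUIRED` columns.
    metadata
        Free-form mapping; recognized keys are ``cutoff_day`` (administrative
        data cutoff, integer study day, used to impute resolution of ongoing
        adverse events) and ``scenario`` (provenance of simulated data).
    """

    subjects: pd.DataFrame
    adverse_events: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.subjects.columns if c not in SUBJECT_REQUIRED]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def arm_sizes(self) -> dict[str, int]:
        return self.subjects["arm"].value_counts().to_dict()

    def validate(self) -> "TrialDataset":
        """Normalize dtypes and enforce every schema and cross-table invariant.

        Returns self (with coerced columns) on success; raises
        :class:`SchemaError`, :class:`ReferentialError` or
        :class:`ConsistencyError` otherwise. Validation is total: no rows are
        silently dropped.
        """
        subj = self.subjects
        aes = self.adverse_events
        _check_columns(subj, SUBJECT_REQUIRED, "subjects")
        _check_columns(aes, AE_REQUIRED, "adverse_events")

        subj = subj.copy()
        subj["subject_id"] = subj["subject_id"].astype(str)
        if subj["subject_id"].duplicated().any():
            dups = sorted(subj.loc[subj["subject_id"].duplicated(), "subject_id"].unique())
            raise ConsistencyError(f"subjects: duplicated subject_id(s) {dups}")
        bad_arm = ~subj["arm"].isin(ARMS)
        if bad_arm.any():
            raise SchemaError(
                f"subjects.arm: labels must be one of {ARMS}; "
                f"found {sorted(subj.loc[bad_arm, 'arm'].unique())}"
            )
        for arm in ARMS:
            if not (subj["arm"] == arm).any():
                raise ConsistencyError(f"subjects: arm '{arm}' has no patients")
        subj["pfs_days"] = _coerce_int(subj["pfs_days"], "subjects", "pfs_days", minimum=0)
        subj["os_days"] = _coerce_int(subj["os_days"], "subjects", "os_days", minimum=0)
        subj["pfs_event"] = _coerce_bool(subj["pfs_event"], "subjects", "pfs_event")
        subj["os_event"] = _coerce_bool(subj["os_event"], "subjects", "os_event")

        bad = subj["pfs_days"] > subj["os_days"]
        if bad.any():
            ids = sorted(subj.loc[bad, "subject_id"])
            raise ConsistencyError(f"subjects: pfs_days > os_days for subject(s) {ids}")
        # A death (OS event) implies progression was called at or before the
        # death day; datasets must encode death-before-progression as a PFS
        # event at the death day before entering the pipeline.
        bad = subj["os_event"] & ~subj["pfs_event"]
        if bad.any():
            ids = sorted(subj.loc[bad, "subject_id"])
            raise ConsistencyError(
                f"subjects: os_event without pfs_event for subject(s) {ids}; "
                "encode death before documented progression as a PFS event at "
                "the death day"
            )

        aes = aes.copy()
        aes["subject_id"] = aes["subject_id"].astype(str)
        unknown = ~aes["subject_id"].isin(set(subj["subject_id"]))
        if unknown.any():
            ids = sorted(aes.loc[unknown, "subject_id"].unique())
            raise ReferentialError(f"adverse_events: unknown subject_id(s) {ids}")
        aes["start_day"] = _coerce_int(aes["start_day"], "adverse_events", "start_day", minimum=1)
        aes["end_day"] = _coerce_int(aes["end_day"], "adverse_events", "end_day", allow_na=True, minimum=1)
        bad = aes["end_day"].notna() & (aes["end_day"] < aes["start_day"])
        if bad.any():
            rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
            raise ConsistencyError(f"adverse_events: end_day < start_day at row(s) {rows}")
        aes["grade"] = _coerce_int(aes["grade"], "adverse_events", "grade", minimum=1)
        if (aes["grade"] > 5).any():
            rows = [int(i) + 2 for i in np.flatnonzero((aes["grade"] > 5).to_numpy())]
            raise SchemaError(f"adverse_events.grade: grade must be 1-5; bad row(s) {rows}")
        aes["serious"] = _coerce_bool(aes["serious"], "adverse_events", "serious")
        aes["treatment_emergent"] = _coerce_bool(
            aes["treatment_emergent"], "adverse_events", "treatment_emergent"
        )

        self.subjects = subj.reset_index(drop=True)
        self.adverse_events = aes.reset_index(drop=True)
        return self

    def subset(self, subject_ids: Iterable[str]) -> "TrialDataset":
        """Restrict to the given subjects; their adverse events travel along."""
        wanted = set(subject_ids)
        subj = self.subjects[self.subjects["subject_id"].isin(wanted)].reset_index(drop=True)
        aes = self.adverse_events[
            self.adverse_events["subject_id"].isin(wanted)
        ].reset_index(drop=True)
        return TrialDataset(subj, aes, dict(self.metadata))


def read_trial(
    subjects_path: str | Path, ae_path: str | Path, metadata: dict | None = None
) -> TrialDataset:
    """Read and validate the two CSV tables into a :class:`TrialDataset`."""
    # read everything as text: validation coerces the required numeric columns
    # and covariate labels stay opaque strings regardless of their spelling
    subjects = pd.read_csv(subjects_path, dtype=str)
    aes = pd.read_csv(ae_path, dtype=str)
    return TrialDataset(subjects, aes, dict(metadata or {})).validate()


def write_trial(dataset: TrialDataset, subjects_path: str | Path, ae_path: str | Path) -> None:
    """Write the dataset back to the CSV dialect :func:`read_trial` reads.

    Booleans are encoded 0/1 and a missing adverse-event resolution day is an
    empty field, so write-then-read is the identity.
    """
    subj = dataset.subjects.copy()
    for col in ("pfs_event", "os_event"):
        subj[col] = subj[col].astype(int)
    subj.to_csv(subjects_path, index=False)

    aes = dataset.adverse_events.copy()
    for col in ("serious", "treatment_emergent"):
        aes[col] = aes[col].astype(int)
    aes.to_csv(ae_path, index=False)


def subject_records(dataset: TrialDataset) -> list[dict]:
    """Subject rows as plain dicts with covariates gathered under 'covariates'."""
    cov = dataset.covariate_columns
    out = []
    for row in dataset.subjects.itertuples(index=False):
        d = row._asdict()
        d["covariates"] = {c: d.pop(c) for c in cov}
        out.append(d)
    return out
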