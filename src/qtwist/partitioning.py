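"""Health-state partitioning: TOX / TWiST / REL durations per patient.

Each patient's survival time is split into three clinically relevant states:

* **TOX** — pre-progression days spent with a qualifying toxicity (grade 3/4
  treatment-emergent adverse events in the primary definition, any serious
  TEAE in the sensitivity definition). A day covered by several qualifying
  events counts once (day-level union of closed intervals).
* **TWiST** — pre-progression days free of qualifying toxicity
  (time without symptoms of disease or toxicity).
* **REL** — days from disease progression to death or last known alive.

By construction ``tox + twist = pfs`` and ``rel = os - pfs`` exactly, in
integer days; months are obtained by dividing days by 30.437.

Conventions (all stated in the module's own terms):

* Adverse-event intervals are closed on both ends; a one-day event has
  ``end_day == start_day`` and contributes one day.
* The pre-progression window is study days 1..pfs_days inclusive; the
  relapse period starts the day after progression, so the three states
  add up to OS exactly.
* An ongoing adverse event (missing resolution day) is imputed to end at
  ``min(pfs_days, cutoff_day)``: toxicity cannot extend past progression by
  definition, and extrapolating past the data cutoff is unsupported.
* Death before documented progression must be encoded upstream as a PFS
  event at the death day (``rel = 0``); the data model enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TrialDataset
from .errors import ConsistencyError

#: Average days per month used to convert study days to months.
DAYS_PER_MONTH = 30.437

MODE_GRADE34 = "grade34"
MODE_SERIOUS = "serious"


@dataclass(frozen=True)
class ToxDefinition:
    """Which adverse events qualify as toxicity.

    ``mode="grade34"`` qualifies CTCAE grade 3 or 4 events (primary analysis);
    ``mode="serious"`` qualifies events with the regulatory seriousness flag
    (sensitivity analysis). Non-treatment-emergent events are excluded unless
    ``require_treatment_emergent`` is set to False.
    """

    mode: str = MODE_GRADE34
    require_treatment_emergent: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (MODE_GRADE34, MODE_SERIOUS):
            raise ValueError(f"unknown toxicity mode {self.mode!r}")

    def qualifies(self, grade: np.ndarray, serious: np.ndarray, te: np.ndarray) -> np.ndarray:
        if self.mode == MODE_GRADE34:
            mask = (grade == 3) | (grade == 4)
        else:
            mask = serious.astype(bool)
        if self.require_treatment_emergent:
            mask = mask & te.astype(bool)
        return mask


GRADE34 = ToxDefinition(MODE_GRADE34)
SERIOUS = ToxDefinition(MODE_SERIOUS)


@dataclass(frozen=True)
class PatientStateDurations:
    """Per-patient state durations in integer study days."""

    subject_id: str
    tox_days: int
    twist_days: int
    rel_days: int
    pfs_days: int
    os_days: int
    pfs_event: bool
    os_event: bool

    def __post_init__(self) -> None:
        if self.tox_days + self.twist_days != self.pfs_days:
            raise ConsistencyError(
                f"{self.subject_id}: tox+twist != pfs "
                f"({self.tox_days}+{self.twist_days} != {self.pfs_days})"
            )
        if self.rel_days != self.os_days - self.pfs_days:
            raise ConsistencyError(f"{self.subject_id}: rel != os - pfs")
        if self.rel_days < 0:
            raise ConsistencyError(f"{self.subject_id}: negative relapse duration")


def days_to_months(days: float) -> float:
    """Convert study days to months by dividing by 30.437."""
    if days < 0:
        raise ValueError(f"negative duration: {days}")
    return days / DAYS_PER_MONTH


def qualifying_day_set(
    aes: pd.DataFrame | None,
    tox_def: ToxDefinition,
    window_end_day: int,
    cutoff_day: int | None = None,
) -> set[int]:
    """Study days in 1..window_end_day covered by at least one qualifying AE.

    Overlapping intervals contribute each covered day once. An interval with
    a missing end day is imputed to end at ``min(window_end_day, cutoff_day)``.
    """
    if window_end_day < 0:
        raise ValueError("window_end_day must be >= 0")
    if aes is None or len(aes) == 0 or window_end_day == 0:
        return set()
    mask = tox_def.qualifies(
        aes["grade"].to_numpy(),
        aes["serious"].to_numpy(),
        aes["treatment_emergent"].to_numpy(),
    )
    if not mask.any():
        return set()
    imputed_end = window_end_day if cutoff_day is None else min(window_end_day, cutoff_day)
    starts = aes["start_day"].to_numpy()[mask]
    ends = aes["end_day"].to_numpy(dtype=float)[mask]
    days: set[int] = set()
    for s, e in zip(starts, ends):
        e = imputed_end if np.isnan(e) else int(e)
        lo = max(int(s), 1)
        hi = min(e, window_end_day)
        if hi >= lo:
            days.update(range(lo, hi + 1))
    return days


def partition_patient(
    subject,
    aes: pd.DataFrame | None,
    tox_def: ToxDefinition = GRADE34,
    cutoff_day: int | None = None,
) -> PatientStateDurations:
    """Partition one patient's survival time into TOX / TWiST / REL days.

    ``subject`` is any object with ``subject_id``, ``pfs_days``, ``os_days``,
    ``pfs_event`` and ``os_event`` attributes (a subjects-table row works).
    """
    pfs = int(subject.pfs_days)
    os_ = int(subject.os_days)
    tox = len(qualifying_day_set(aes, tox_def, pfs, cutoff_day))
    return PatientStateDurations(
        subject_id=str(subject.subject_id),
        tox_days=tox,
        twist_days=pfs - tox,
        rel_days=os_ - pfs,
        pfs_days=pfs,
        os_days=os_,
        pfs_event=bool(subject.pfs_event),
        os_event=bool(subject.os_event),
    )


def partition_trial(dataset: TrialDataset, tox_def: ToxDefinition = GRADE34) -> pd.DataFrame:
    """Partition every patient; returns one row per patient.

    Columns: subject_id, arm, tox_days, twist_days, rel_days, pfs_days,
    os_days, pfs_event, os_event plus the corresponding ``*_months`` columns
    and any covariate columns carried over from the subject table.
    """
    cutoff = dataset.metadata.get("cutoff_day")
    groups = {sid: g for sid, g in dataset.adverse_events.groupby("subject_id", sort=False)}
    rows = []
    for subj in dataset.subjects.itertuples(index=False):
        d = partition_patient(subj, groups.get(subj.subject_id), tox_def, cutoff)
        rows.append(
            (
                d.subject_id,
                subj.arm,
                d.tox_days,
                d.twist_days,
                d.rel_days,
                d.pfs_days,
                d.os_days,
                d.pfs_event,
                d.os_event,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "arm",
            "tox_days",
            "twist_days",
            "rel_days",
            "pfs_days",
            "os_days",
            "pfs_event",
            "os_event",
        ],
    )
    for state in ("tox", "twist", "rel", "pfs", "os"):
        out[f"{state}_months"] = out[f"{state}_days"] / DAYS_PER_MONTH
    cov = dataset.covariate_columns
    if cov:
        out = out.merge(dataset.subjects[["subject_id", *cov]], on="subject_id", how="left")
    return out
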