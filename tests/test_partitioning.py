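"""Health-state partitioning: day-union toxicity rule and state additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtwist import (
    DAYS_PER_MONTH,
    GRADE34,
    SERIOUS,
    ToxDefinition,
    days_to_months,
    partition_patient,
    partition_trial,
    qualifying_day_set,
)
from conftest import brute_force_day_union


def ae_frame(rows):
    """rows: (start, end, grade, serious, te)"""
    return pd.DataFrame(
        rows, columns=["start_day", "end_day", "grade", "serious", "treatment_emergent"]
    ).assign(subject_id="S1")[
        ["subject_id", "start_day", "end_day", "grade", "serious", "treatment_emergent"]
    ]


class Subject:
    def __init__(self, pfs, os_, pfs_event=True, os_event=True, sid="S1"):
        self.subject_id = sid
        self.pfs_days = pfs
        self.os_days = os_
        self.pfs_event = pfs_event
        self.os_event = os_event


@pytest.mark.parametrize(
    "rows,window,expected",
    [
        # overlapping grade 3/4 intervals: each covered day counts once
        ([(3, 5, 3, 0, 1), (4, 8, 4, 0, 1)], 10, set(range(3, 9))),
        # same intervals clipped at the progression window
        ([(3, 5, 3, 0, 1), (4, 8, 4, 0, 1)], 4, {3, 4}),
        # grade 2 never qualifies under the grade-3/4 definition
        ([(3, 5, 2, 0, 1)], 10, set()),
        # non-treatment-emergent grade 3 excluded by default
        ([(3, 5, 3, 0, 0)], 10, set()),
    ],
)
def test_qualifying_day_set_examples(rows, window, expected):
    assert qualifying_day_set(ae_frame(rows), GRADE34, window) == expected
    qualifying = [(r[0], r[1]) for r in rows if r[2] in (3, 4) and r[4]]
    assert brute_force_day_union(qualifying, window) == expected


def test_qualifying_day_set_matches_brute_force_on_random_intervals():
    rng = np.random.default_rng(42)
    for _ in range(200):
        window = int(rng.integers(0, 60))
        rows = []
        for _ in range(rng.integers(0, 6)):
            s = int(rng.integers(1, 70))
            rows.append(
                (s, s + int(rng.integers(0, 15)), int(rng.integers(1, 5)),
                 int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            )
        aes = ae_frame(rows) if rows else None
        got = qualifying_day_set(aes, GRADE34, window)
        qualifying = [(r[0], r[1]) for r in rows if r[2] in (3, 4) and r[4]]
        assert got == brute_force_day_union(qualifying, window)


def test_ongoing_ae_imputed_to_progression_or_cutoff():
    aes = ae_frame([(10, None, 3, 0, 1)])
    assert qualifying_day_set(aes, GRADE34, 20) == set(range(10, 21))
    assert qualifying_day_set(aes, GRADE34, 20, cutoff_day=14) == set(range(10, 15))


def test_serious_mode_selects_on_flag_not_grade():
    aes = ae_frame([(1, 2, 2, 1, 1), (5, 6, 4, 0, 1)])
    assert qualifying_day_set(aes, SERIOUS, 10) == {1, 2}
    assert qualifying_day_set(aes, GRADE34, 10) == {5, 6}


@pytest.mark.parametrize(
    "pfs,os_,rows,expected",
    [
        (120, 250, [(10, 24, 3, 0, 1)], (15, 105, 130)),
        (60, 60, [], (0, 60, 0)),  # progression and death the same day
        (0, 45, [], (0, 0, 45)),  # immediate progression
    ],
)
def test_partition_patient_examples(pfs, os_, rows, expected):
    aes = ae_frame(rows) if rows else None
    d = partition_patient(Subject(pfs, os_), aes, GRADE34)
    assert (d.tox_days, d.twist_days, d.rel_days) == expected


def test_ae_straddling_progression_is_clipped():
    d = partition_patient(Subject(20, 40), ae_frame([(15, 30, 4, 0, 1)]), GRADE34)
    assert d.tox_days == 6  # days 15..20 only
    assert d.twist_days == 14


@pytest.mark.parametrize("days,months", [(30.437, 1.0), (0, 0.0), (60.874, 2.0)])
def test_days_to_months(days, months):
    assert days_to_months(days) == pytest.approx(months, abs=1e-12)


def test_days_to_months_rejects_negative():
    with pytest.raises(ValueError):
        days_to_months(-1)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    pfs=st.integers(0, 200),
    rel=st.integers(0, 200),
    intervals=st.lists(
        st.tuples(st.integers(1, 220), st.integers(0, 30), st.integers(1, 4)),
        max_size=5,
    ),
)
def test_state_months_additivity_and_clipping(pfs, rel, intervals):
    """TOX+TWiST+REL months equals OS months; AEs never leak past progression."""
    rows = [(s, s + length, grade, 0, 1) for s, length, grade in intervals]
    d = partition_patient(Subject(pfs, pfs + rel), ae_frame(rows) if rows else None, GRADE34)
    total = days_to_months(d.tox_days) + days_to_months(d.twist_days) + days_to_months(d.rel_days)
    assert total == pytest.approx(days_to_months(d.os_days), abs=1e-9)
    assert 0 <= d.tox_days <= d.pfs_days


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    pfs=st.integers(1, 120),
    base=st.lists(st.tuples(st.integers(1, 120), st.integers(0, 20)), max_size=4),
    extra=st.tuples(st.integers(1, 120), st.integers(0, 20)),
)
def test_adding_a_qualifying_interval_is_monotone(pfs, base, extra):
    rows = [(s, s + k, 3, 0, 1) for s, k in base]
    before = partition_patient(Subject(pfs, pfs + 10), ae_frame(rows) if rows else None, GRADE34)
    rows_after = rows + [(extra[0], extra[0] + extra[1], 3, 0, 1)]
    after = partition_patient(Subject(pfs, pfs + 10), ae_frame(rows_after), GRADE34)
    assert after.tox_days >= before.tox_days
    assert after.tox_days + after.twist_days == before.tox_days + before.twist_days


def test_serious_superset_dominates_grade34():
    """When every grade-3/4 AE is also serious, serious-mode TOX >= grade-mode TOX."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        rows = []
        for _ in range(rng.integers(1, 5)):
            s = int(rng.integers(1, 80))
            g = int(rng.integers(1, 5))
            serious = 1 if g >= 3 else int(rng.integers(0, 2))
            rows.append((s, s + int(rng.integers(0, 10)), g, serious, 1))
        pfs = int(rng.integers(1, 100))
        tox_g = partition_patient(Subject(pfs, pfs + 5), ae_frame(rows), GRADE34).tox_days
        tox_s = partition_patient(Subject(pfs, pfs + 5), ae_frame(rows), SERIOUS).tox_days
        assert tox_s >= tox_g


def test_partition_trial_shapes_and_identities(small_trial):
    dur = partition_trial(small_trial)
    assert len(dur) == small_trial.n_subjects
    assert (dur["tox_days"] + dur["twist_days"] == dur["pfs_days"]).all()
    assert (dur["rel_days"] == dur["os_days"] - dur["pfs_days"]).all()
    assert np.allclose(dur["os_months"], dur["os_days"] / DAYS_PER_MONTH)
    # covariates travel with the durations for subgroup use
    assert "sex" in dur.columns
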