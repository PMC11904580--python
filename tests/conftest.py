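import numpy as np
import pandas as pd
import pytest

from qtwist import BootstrapConfig, TrialDataset, default_scenario, run_primary, simulate_trial


@pytest.fixture
def tiny_dataset() -> TrialDataset:
    """Hand-written 3-subject trial with two adverse events."""
    subjects = pd.DataFrame(
        {
            "subject_id": ["A1", "A2", "C1"],
            "arm": ["active", "active", "control"],
            "pfs_days": [120, 60, 90],
            "pfs_event": [1, 1, 1],
            "os_days": [250, 60, 200],
            "os_event": [1, 1, 1],
            "sex": ["male", "female", "male"],
        }
    )
    aes = pd.DataFrame(
        {
            "subject_id": ["A1", "A1"],
            "start_day": [10, 200],
            "end_day": [24, 210],
            "grade": [3, 4],
            "serious": [0, 1],
            "treatment_emergent": [1, 1],
        }
    )
    return TrialDataset(subjects, aes).validate()


@pytest.fixture(scope="session")
def small_trial() -> TrialDataset:
    """Simulated default-scenario trial at reduced size, shared across tests."""
    return simulate_trial(default_scenario(n_active=120, n_control=60), seed=7)


@pytest.fixture(scope="session")
def small_report(small_trial):
    return run_primary(small_trial, boot=BootstrapConfig(n_replicates=100, seed=3))


def brute_force_day_union(intervals, window_end):
    """Independent oracle: enumerate covered study days one by one."""
    days = set()
    for lo, hi in intervals:
        for d in range(lo, hi + 1):
            if 1 <= d <= window_end:
                days.add(d)
    return days
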