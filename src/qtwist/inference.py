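"""Nonparametric bootstrap standard errors and z-method confidence intervals.

Patients are resampled with replacement independently within each treatment
arm (the estimand is a between-arm contrast of arm-level functionals, and the
allocation ratio is fixed by design); a patient's adverse-event records
travel with the patient. The standard error of a statistic is the sample
standard deviation of its bootstrap replicates, and confidence intervals are
symmetric normal ("z-method") intervals, estimate ± z * SE, with the exact
normal quantile rather than the rounded 1.96.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ARMS, TrialDataset


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``frozen_tau=False`` recomputes the common restriction time on every
    resample (tau is data-dependent; freezing it understates variance), but a
    frozen tau is available for comparison.
    """

    n_replicates: int = 1000
    seed: int = 0
    frozen_tau: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with bootstrap SE, z-interval and optional p-value."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    p_value: float | None = None


def z_interval(
    estimate: float, se: float, level: float = 0.95, *, null: float | None = None
) -> EstimateWithCI:
    """Symmetric normal interval; two-sided p-value against ``null`` if given.

    With ``se == 0`` the interval degenerates to the point estimate and a
    nonzero contrast is reported as p = 0.0 (below machine floor).
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2))
    p = None
    if null is not None:
        if se > 0:
            p = float(2 * stats.norm.sf(abs(estimate - null) / se))
        else:
            p = 1.0 if estimate == null else 0.0
    return EstimateWithCI(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - z * se),
        ci_high=float(estimate + z * se),
        level=level,
        p_value=p,
    )


def resample_dataset(dataset: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    """One bootstrap resample: patients drawn with replacement within each arm,
    arm sizes preserved, adverse events travelling with their patient.

    Resampled patients get fresh unique ids (a patient drawn twice is two
    independent pseudo-patients).
    """
    subj_parts: list[pd.DataFrame] = []
    ae_parts: list[pd.DataFrame] = []
    ae_groups = {sid: g for sid, g in dataset.adverse_events.groupby("subject_id", sort=False)}
    for arm in ARMS:
        arm_df = dataset.subjects[dataset.subjects["arm"] == arm].reset_index(drop=True)
        idx = rng.integers(0, len(arm_df), size=len(arm_df))
        take = arm_df.iloc[idx].reset_index(drop=True)
        new_ids = [f"{sid}~{arm[0]}{k}" for k, sid in enumerate(take["subject_id"])]
        old_ids = list(take["subject_id"])
        take["subject_id"] = new_ids
        subj_parts.append(take)
        for new_id, old_id in zip(new_ids, old_ids):
            g = ae_groups.get(old_id)
            if g is not None:
                g = g.copy()
                g["subject_id"] = new_id
                ae_parts.append(g)
    subjects = pd.concat(subj_parts, ignore_index=True)
    if ae_parts:
        aes = pd.concat(ae_parts, ignore_index=True)
    else:
        aes = dataset.adverse_events.iloc[0:0].copy()
    return TrialDataset(subjects, aes, dict(dataset.metadata))


def bootstrap_statistics(
    dataset: TrialDataset,
    statistic: Callable[[TrialDataset], float | np.ndarray],
    config: BootstrapConfig,
) -> np.ndarray:
    """Bootstrap replicates of ``statistic``; shape (n_replicates, ...).

    A statistic failing on a degenerate resample is not retried: the error
    propagates annotated with the replicate index.
    """
    rng = np.random.default_rng(config.seed)
    reps = []
    for b in range(config.n_replicates):
        resample = resample_dataset(dataset, rng)
        try:
            reps.append(np.asarray(statistic(resample), dtype=float))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"statistic failed on bootstrap replicate {b}") from exc
    return np.stack(reps)


def bootstrap_se(
    dataset: TrialDataset,
    statistic: Callable[[TrialDataset], float | np.ndarray],
    config: BootstrapConfig,
) -> float | np.ndarray:
    """Bootstrap standard error: sample SD (ddof=1) over replicates."""
    reps = bootstrap_statistics(dataset, statistic, config)
    se = reps.std(axis=0, ddof=1)
    return float(se) if se.ndim == 0 else se
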