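"""Utility-weighted quality-adjusted survival (Q-TWiST) and its contrasts.

Q-TWiST combines the mean state durations with utility coefficients::

    Q-TWiST = u_tox * TOX + u_twist * TWiST + u_rel * REL

with the standard weights u_twist = 1 (time without symptoms or toxicity is
full-quality time) and u_tox = u_rel = 0.5. The between-arm Q-TWiST
difference divided by the control arm's mean OS gives the relative
improvement; relative gains above 10% are conventionally read as clinically
important and above 15% as clearly clinically important.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import StateMeans

#: Relative-improvement thresholds (percent); strict inequalities apply.
CLINICALLY_IMPORTANT_PCT = 10.0
CLEARLY_CLINICALLY_IMPORTANT_PCT = 15.0


@dataclass(frozen=True)
class UtilityWeights:
    """Utility coefficients in [0, 1] for the three health states."""

    u_tox: float = 0.5
    u_twist: float = 1.0
    u_rel: float = 0.5

    def __post_init__(self) -> None:
        for name in ("u_tox", "u_twist", "u_rel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_WEIGHTS = UtilityWeights()


class Importance(str, enum.Enum):
    """Clinical-importance classification of a relative Q-TWiST gain."""

    NOT_IMPORTANT = "not_important"
    CLINICALLY_IMPORTANT = "clinically_important"
    CLEARLY_CLINICALLY_IMPORTANT = "clearly_clinically_important"


def qtwist_value(means: StateMeans, weights: UtilityWeights = DEFAULT_WEIGHTS) -> float:
    """Utility-weighted sum of the arm's mean state durations, in months."""
    return (
        weights.u_tox * means.mean_tox
        + weights.u_twist * means.mean_twist
        + weights.u_rel * means.mean_rel
    )


def classify_relative_improvement(percent: float) -> Importance:
    """Apply the >10% / >15% thresholds (strict; boundaries classify down)."""
    if percent > CLEARLY_CLINICALLY_IMPORTANT_PCT:
        return Importance.CLEARLY_CLINICALLY_IMPORTANT
    if percent > CLINICALLY_IMPORTANT_PCT:
        return Importance.CLINICALLY_IMPORTANT
    return Importance.NOT_IMPORTANT


def relative_improvement(
    difference: float, control_mean_os: float
) -> tuple[float, Importance]:
    """Q-TWiST difference as a percentage of the control arm's mean OS."""
    if control_mean_os <= 0:
        raise ValueError(f"control mean OS must be positive, got {control_mean_os}")
    pct = 100.0 * difference / control_mean_os
    return pct, classify_relative_improvement(pct)


@dataclass(frozen=True)
class QTwistContrast:
    """Between-arm Q-TWiST contrast with its relative-improvement reading."""

    qtwist_active: float
    qtwist_control: float
    difference: float
    relative_improvement_pct: float
    classification: Importance

    @classmethod
    def from_means(
        cls,
        active: StateMeans,
        control: StateMeans,
        weights: UtilityWeights = DEFAULT_WEIGHTS,
    ) -> "QTwistContrast":
        qa = qtwist_value(active, weights)
        qc = qtwist_value(control, weights)
        diff = qa - qc
        pct, cls_ = relative_improvement(diff, control.mean_os)
        return cls(qa, qc, diff, pct, cls_)


def utility_threshold_grid(
    active: StateMeans,
    control: StateMeans,
    grid_step: float = 0.1,
) -> pd.DataFrame:
    """Q-TWiST difference over the (u_tox, u_rel) grid with u_twist fixed at 1.

    Returns a DataFrame indexed by u_tox (rows) and u_rel (columns), both
    spanning [0, 1] inclusive in steps of ``grid_step``. A positive entry
    everywhere means the active arm gains quality-adjusted time under every
    utility assumption.
    """
    if not 0 < grid_step <= 0.5:
        raise ValueError(f"grid_step must be in (0, 0.5], got {grid_step}")
    values = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    diffs = np.empty((len(values), len(values)))
    for i, u_tox in enumerate(values):
        for j, u_rel in enumerate(values):
            w = UtilityWeights(u_tox=u_tox, u_twist=1.0, u_rel=u_rel)
            diffs[i, j] = qtwist_value(active, w) - qtwist_value(control, w)
    out = pd.DataFrame(diffs, index=values, columns=values)
    out.index.name = "u_tox"
    out.columns.name = "u_rel"
    return out
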