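"""Product-limit (Kaplan–Meier) estimation and partitioned restricted means.

The mean time spent in each health state is estimated per arm as a difference
of areas under nested Kaplan–Meier curves (partitioned survival): the curves
for cumulative toxicity duration, PFS and OS are nested, and the area between
consecutive curves up to a restriction time tau estimates the mean duration of
TOX, TWiST and REL respectively.

The estimator lives in the bootstrap hot path, so the product-limit fit is a
small vectorized numpy routine rather than a model object; tests cross-check
it against an independent survival library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError

_ATOL = 1e-12


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``survival_prob[i]`` is the estimate just after ``time_grid[i]``; the
    curve starts at 1.0 at time 0 and is a right-continuous step function.
    Ties are handled by the standard convention that subjects censored at a
    time remain at risk for the events at that same time.
    """

    time_grid: np.ndarray
    survival_prob: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_observed_time: float

    @property
    def closed(self) -> bool:
        """True when the estimate has dropped to zero: the area under the
        curve is complete and restriction times beyond the last observation
        add nothing."""
        return bool(self.survival_prob[-1] <= _ATOL)


def km_fit(times, events) -> KMCurve:
    """Fit the product-limit estimator.

    Parameters
    ----------
    times
        Observed durations (event or censoring times), all >= 0.
    events
        Event indicators; False marks a censored observation.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit: empty input")
    if t.shape != e.shape:
        raise ValueError("km_fit: times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("km_fit: negative time")
    order = np.argsort(t, kind="mergesort")
    ts = t[order]
    es = e[order]
    n = ts.size
    first = np.concatenate(([0], np.flatnonzero(np.diff(ts)) + 1))
    uniq = ts[first]
    cum_events = np.concatenate(([0], np.cumsum(es)))
    bounds = np.append(first, n)
    d = cum_events[bounds[1:]] - cum_events[bounds[:-1]]
    n_risk = n - first
    surv = np.cumprod(1.0 - d / n_risk)
    return KMCurve(
        time_grid=uniq,
        survival_prob=surv,
        n_risk=n_risk,
        n_event=d,
        max_observed_time=float(ts[-1]),
    )


def rmst(curve: KMCurve, tau: float, *, tail: str = "refuse") -> float:
    """Restricted mean: area under the step function from 0 to tau.

    Exact rectangle sum, no interpolation. When ``tau`` exceeds the last
    observed time the area is complete only if the curve has dropped to zero;
    otherwise the tail is unidentified and the default is to refuse.
    ``tail="carry"`` instead carries the final plateau forward to tau, the
    conventional treatment for the toxicity-duration curve whose support is
    much shorter than the restriction time.
    """
    if tau <= 0:
        raise ValueError("rmst: tau must be positive")
    if tau > curve.max_observed_time + _ATOL and not curve.closed:
        if tail == "refuse":
            raise ValueError(
                f"rmst: tau={tau} exceeds the last observed time "
                f"{curve.max_observed_time} and the curve has not reached zero; "
                "lower tau or pass tail='carry'"
            )
        if tail != "carry":
            raise ValueError(f"rmst: unknown tail policy {tail!r}")
    edges = np.minimum(np.concatenate(([0.0], curve.time_grid)), tau)
    widths = np.diff(np.append(edges, tau))
    s = np.concatenate(([1.0], curve.survival_prob))
    return float(np.dot(widths, s))


@dataclass(frozen=True)
class StateMeans:
    """Arm-level mean state durations in months at restriction time tau."""

    arm: str
    mean_tox: float
    mean_twist: float
    mean_rel: float
    mean_pfs: float
    mean_os: float
    tau: float

    @classmethod
    def from_components(
        cls, tox: float, twist: float, rel: float, arm: str = "", tau: float = math.inf
    ) -> "StateMeans":
        """Build from the three state means; PFS and OS means follow by
        additivity (pfs = tox + twist, os = pfs + rel)."""
        pfs = tox + twist
        return cls(arm=arm, mean_tox=tox, mean_twist=twist, mean_rel=rel,
                   mean_pfs=pfs, mean_os=pfs + rel, tau=tau)

    def __post_init__(self) -> None:
        if not (
            -1e-9 <= self.mean_tox
            and self.mean_tox <= self.mean_pfs + 1e-9
            and self.mean_pfs <= self.mean_os + 1e-9
            and self.mean_os <= self.tau + 1e-9
        ):
            raise ConsistencyError(
                f"state means out of order for arm {self.arm!r}: "
                f"tox={self.mean_tox}, pfs={self.mean_pfs}, os={self.mean_os}, tau={self.tau}"
            )
        if abs(self.mean_tox + self.mean_twist - self.mean_pfs) > 1e-9:
            raise ConsistencyError("mean_tox + mean_twist != mean_pfs")
        if abs(self.mean_pfs + self.mean_rel - self.mean_os) > 1e-9:
            raise ConsistencyError("mean_pfs + mean_rel != mean_os")


def common_tau(durations: pd.DataFrame) -> float:
    """Default restriction time: the smaller of the two arms' largest observed
    OS times (in months), so between-arm contrasts compare like with like."""
    taus = durations.groupby("arm")["os_months"].max()
    return float(taus.min())


def partitioned_state_means(
    arm_durations: pd.DataFrame, tau: float, *, tox_tail: str = "carry"
) -> StateMeans:
    """Mean TOX/TWiST/REL/PFS/OS for one arm as KM restricted-mean differences.

    Fits three curves — cumulative toxicity duration, PFS and OS, the first
    inheriting the PFS event indicator since toxicity accrual is only observed
    while progression-free — and partitions the areas:
    ``mean_tox = auc(TOX)``, ``mean_twist = auc(PFS) - auc(TOX)``,
    ``mean_rel = auc(OS) - auc(PFS)``.
    """
    if len(arm_durations) == 0:
        raise ValueError("partitioned_state_means: empty arm")
    if tau <= 0:
        raise ValueError("partitioned_state_means: tau must be positive")
    arms = arm_durations["arm"].unique()
    if len(arms) > 1:
        raise ValueError(f"partitioned_state_means: mixed arms {list(arms)}")
    pfs_event = arm_durations["pfs_event"].to_numpy()
    os_curve = km_fit(arm_durations["os_months"], arm_durations["os_event"])
    pfs_curve = km_fit(arm_durations["pfs_months"], pfs_event)
    tox_curve = km_fit(arm_durations["tox_months"], pfs_event)
    mean_os = rmst(os_curve, tau)
    mean_pfs = rmst(pfs_curve, tau)
    mean_tox = rmst(tox_curve, tau, tail=tox_tail)
    means = StateMeans(
        arm=str(arms[0]),
        mean_tox=mean_tox,
        mean_twist=mean_pfs - mean_tox,
        mean_rel=mean_os - mean_pfs,
        mean_pfs=mean_pfs,
        mean_os=mean_os,
        tau=tau,
    )
    return means
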