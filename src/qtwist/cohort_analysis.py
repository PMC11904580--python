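"""End-to-end Q-TWiST analyses: primary, subgroup and sensitivity reports.

`run_primary` partitions every patient into health states, estimates per-arm
mean state durations as partitioned Kaplan–Meier restricted means at a common
restriction time, combines them into Q-TWiST, and attaches bootstrap standard
errors, z-method confidence intervals and p-values to each row of the report
(OS, PFS, Q-TWiST, TWiST, TOX, REL for each arm and their differences).

The bootstrap resamples patients within arm on the partitioned per-patient
durations: health-state partitioning is deterministic per patient, so
resampling durations is equivalent to resampling patients with their
adverse-event records and repartitioning, at a fraction of the cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ARM_ACTIVE, ARM_CONTROL, TrialDataset
from .errors import QTwistError, SchemaError
from .inference import BootstrapConfig, EstimateWithCI, z_interval
from .partitioning import GRADE34, SERIOUS, ToxDefinition, partition_trial
from .qtwist_core import DEFAULT_WEIGHTS, QTwistContrast, UtilityWeights, qtwist_value
from .survival import StateMeans, km_fit, rmst

logger = logging.getLogger(__name__)

#: Report rows, in the order they are displayed.
ROWS = ("os", "pfs", "qtwist", "twist", "tox", "rel")

VARIANT_PRIMARY = "primary"
VARIANT_SENSITIVITY_SERIOUS = "sensitivity_serious"


@dataclass(frozen=True)
class SubgroupSpec:
    """A covariate to stratify on, with optional category whitelist."""

    covariate: str
    categories: tuple[str, ...] | None = None
    min_size: int = 10


@dataclass(frozen=True)
class SkippedSubgroup:
    """Placeholder emitted for a subgroup too small to analyze."""

    variant: str
    reason: str
    n_active: int
    n_control: int


@dataclass
class QTwistReport:
    """Arm-level and between-arm estimates for one analysis variant."""

    variant: str
    active: dict[str, EstimateWithCI]
    control: dict[str, EstimateWithCI]
    differences: dict[str, EstimateWithCI]
    contrast: QTwistContrast
    state_means: dict[str, StateMeans]
    tau: float
    n_active: int
    n_control: int
    n_replicates: int
    weights: UtilityWeights = field(default=DEFAULT_WEIGHTS)
    tox_mode: str = "grade34"


class _ArmArrays:
    """Per-arm duration columns as flat numpy arrays for the bootstrap."""

    __slots__ = ("os_m", "os_e", "pfs_m", "pfs_e", "tox_m", "n")

    def __init__(self, frame: pd.DataFrame):
        self.os_m = frame["os_months"].to_numpy(dtype=float)
        self.os_e = frame["os_event"].to_numpy(dtype=bool)
        self.pfs_m = frame["pfs_months"].to_numpy(dtype=float)
        self.pfs_e = frame["pfs_event"].to_numpy(dtype=bool)
        self.tox_m = frame["tox_months"].to_numpy(dtype=float)
        self.n = len(frame)

    def take(self, idx: np.ndarray) -> "_ArmArrays":
        out = object.__new__(_ArmArrays)
        out.os_m = self.os_m[idx]
        out.os_e = self.os_e[idx]
        out.pfs_m = self.pfs_m[idx]
        out.pfs_e = self.pfs_e[idx]
        out.tox_m = self.tox_m[idx]
        out.n = len(idx)
        return out


def _arm_stats(arm: _ArmArrays, tau: float, weights: UtilityWeights, tail: str) -> np.ndarray:
    """(os, pfs, qtwist, twist, tox, rel) restricted means for one arm.

    ``tail`` governs restriction times beyond a curve's last observed time;
    the bootstrap path carries the KM plateau forward so that replicates that
    happen to drop the extreme observation remain well defined.
    """
    mean_os = rmst(km_fit(arm.os_m, arm.os_e), tau, tail=tail)
    mean_pfs = rmst(km_fit(arm.pfs_m, arm.pfs_e), tau, tail=tail)
    mean_tox = rmst(km_fit(arm.tox_m, arm.pfs_e), tau, tail="carry")
    twist = mean_pfs - mean_tox
    rel = mean_os - mean_pfs
    q = weights.u_tox * mean_tox + weights.u_twist * twist + weights.u_rel * rel
    return np.array([mean_os, mean_pfs, q, twist, mean_tox, rel])


def _bootstrap_matrix(
    active: _ArmArrays,
    control: _ArmArrays,
    boot: BootstrapConfig,
    weights: UtilityWeights,
    tau_point: float,
    tau_is_user_fixed: bool,
) -> np.ndarray:
    """Replicate matrix of shape (B, 18): active 6, control 6, differences 6."""
    rng = np.random.default_rng(boot.seed)
    out = np.empty((boot.n_replicates, 18))
    recompute_tau = not (boot.frozen_tau or tau_is_user_fixed)
    for b in range(boot.n_replicates):
        a = active.take(rng.integers(0, active.n, size=active.n))
        c = control.take(rng.integers(0, control.n, size=control.n))
        tau = min(a.os_m.max(), c.os_m.max()) if recompute_tau else tau_point
        try:
            sa = _arm_stats(a, tau, weights, tail="carry")
            sc = _arm_stats(c, tau, weights, tail="carry")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"statistic failed on bootstrap replicate {b}") from exc
        out[b, :6] = sa
        out[b, 6:12] = sc
        out[b, 12:] = sa - sc
    return out


def run_primary(
    dataset: TrialDataset,
    tox_def: ToxDefinition = GRADE34,
    weights: UtilityWeights = DEFAULT_WEIGHTS,
    boot: BootstrapConfig | None = None,
    tau: float | None = None,
    variant: str = VARIANT_PRIMARY,
    validate: bool = True,
) -> QTwistReport:
    """Run the full Q-TWiST analysis on a validated two-arm dataset.

    Parameters
    ----------
    tau
        Restriction time in months. Defaults to the smaller of the two arms'
        largest observed OS times, recomputed per bootstrap replicate; an
        explicit tau stays fixed across replicates.
    """
    if validate:
        dataset.validate()
    boot = boot or BootstrapConfig()
    durations = partition_trial(dataset, tox_def)
    act_frame = durations[durations["arm"] == ARM_ACTIVE]
    ctl_frame = durations[durations["arm"] == ARM_CONTROL]
    if len(act_frame) == 0 or len(ctl_frame) == 0:
        raise QTwistError("both arms must be non-empty")
    active = _ArmArrays(act_frame)
    control = _ArmArrays(ctl_frame)

    tau_is_user_fixed = tau is not None
    tau_point = float(tau) if tau_is_user_fixed else float(
        min(active.os_m.max(), control.os_m.max())
    )
    if tau_point <= 0:
        raise QTwistError(f"restriction time must be positive, got {tau_point}")
    logger.info(
        "%s: n=%d/%d, tau=%.3f months, tox_mode=%s, B=%d",
        variant, active.n, control.n, tau_point, tox_def.mode, boot.n_replicates,
    )

    point_a = _arm_stats(active, tau_point, weights, tail="refuse")
    point_c = _arm_stats(control, tau_point, weights, tail="refuse")
    reps = _bootstrap_matrix(active, control, boot, weights, tau_point, tau_is_user_fixed)
    ses = reps.std(axis=0, ddof=1)

    arm_means = {
        ARM_ACTIVE: StateMeans(
            arm=ARM_ACTIVE, mean_tox=point_a[4], mean_twist=point_a[3],
            mean_rel=point_a[5], mean_pfs=point_a[1], mean_os=point_a[0], tau=tau_point,
        ),
        ARM_CONTROL: StateMeans(
            arm=ARM_CONTROL, mean_tox=point_c[4], mean_twist=point_c[3],
            mean_rel=point_c[5], mean_pfs=point_c[1], mean_os=point_c[0], tau=tau_point,
        ),
    }
    act_est = {row: z_interval(point_a[i], ses[i]) for i, row in enumerate(ROWS)}
    ctl_est = {row: z_interval(point_c[i], ses[6 + i]) for i, row in enumerate(ROWS)}
    diff_est = {
        row: z_interval(point_a[i] - point_c[i], ses[12 + i], null=0.0)
        for i, row in enumerate(ROWS)
    }
    contrast = QTwistContrast.from_means(
        arm_means[ARM_ACTIVE], arm_means[ARM_CONTROL], weights
    )
    return QTwistReport(
        variant=variant,
        active=act_est,
        control=ctl_est,
        differences=diff_est,
        contrast=contrast,
        state_means=arm_means,
        tau=tau_point,
        n_active=active.n,
        n_control=control.n,
        n_replicates=boot.n_replicates,
        weights=weights,
        tox_mode=tox_def.mode,
    )


def run_sensitivity_serious(
    dataset: TrialDataset,
    weights: UtilityWeights = DEFAULT_WEIGHTS,
    boot: BootstrapConfig | None = None,
    tau: float | None = None,
    require_treatment_emergent: bool = True,
) -> QTwistReport:
    """Re-derive Q-TWiST with TOX = time spent with any serious TEAE."""
    if "serious" not in dataset.adverse_events.columns:
        raise SchemaError("adverse_events table carries no serious flags")
    tox_def = ToxDefinition("serious", require_treatment_emergent)
    return run_primary(
        dataset, tox_def, weights, boot, tau, variant=VARIANT_SENSITIVITY_SERIOUS
    )


def run_subgroups(
    dataset: TrialDataset,
    specs: list[SubgroupSpec],
    tox_def: ToxDefinition = GRADE34,
    weights: UtilityWeights = DEFAULT_WEIGHTS,
    boot: BootstrapConfig | None = None,
    tau: float | None = None,
    validate: bool = True,
) -> list[QTwistReport | SkippedSubgroup]:
    """One report per subgroup category, each with its own common tau.

    Categories whose total size falls below ``spec.min_size``, or with an
    empty arm, are emitted as :class:`SkippedSubgroup` entries with a reason.
    """
    if validate:
        dataset.validate()
    results: list[QTwistReport | SkippedSubgroup] = []
    for spec in specs:
        if spec.covariate not in dataset.covariate_columns:
            raise QTwistError(
                f"covariate {spec.covariate!r} not in dataset "
                f"(have {dataset.covariate_columns})"
            )
        col = dataset.subjects[spec.covariate]
        domain = sorted(col.dropna().astype(str).unique())
        if spec.categories is None:
            categories = domain
        else:
            unknown = [c for c in spec.categories if c not in domain]
            if unknown:
                raise QTwistError(
                    f"categories {unknown} not in domain of {spec.covariate!r} ({domain})"
                )
            categories = list(spec.categories)
        for label in categories:
            variant = f"subgroup:{spec.covariate}={label}"
            ids = dataset.subjects.loc[col.astype(str) == label, "subject_id"]
            sub = dataset.subset(ids)
            sizes = sub.subjects["arm"].value_counts()
            n_a = int(sizes.get(ARM_ACTIVE, 0))
            n_c = int(sizes.get(ARM_CONTROL, 0))
            if n_a + n_c < spec.min_size or n_a == 0 or n_c == 0:
                reason = (
                    f"subgroup size {n_a + n_c} below minimum {spec.min_size}"
                    if n_a and n_c
                    else "one arm empty"
                )
                logger.info("%s skipped: %s", variant, reason)
                results.append(SkippedSubgroup(variant, reason, n_a, n_c))
                continue
            results.append(
                run_primary(sub, tox_def, weights, boot, tau, variant=variant, validate=False)
            )
    return results


def report_frame(reports: list[QTwistReport | SkippedSubgroup]) -> pd.DataFrame:
    """Tidy long-format table: one row per (variant, arm, state) estimate."""
    records = []
    for rep in reports:
        if isinstance(rep, SkippedSubgroup):
            records.append(
                {"variant": rep.variant, "arm": "skipped", "state": None,
                 "estimate": None, "se": None, "ci_low": None, "ci_high": None,
                 "p_value": None, "n": rep.n_active + rep.n_control, "tau": None,
                 "note": rep.reason}
            )
            continue
        for arm_label, est_map, n in (
            ("active", rep.active, rep.n_active),
            ("control", rep.control, rep.n_control),
            ("difference", rep.differences, rep.n_active + rep.n_control),
        ):
            for state, est in est_map.items():
                records.append(
                    {"variant": rep.variant, "arm": arm_label, "state": state,
                     "estimate": est.estimate, "se": est.se, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "p_value": est.p_value, "n": n,
                     "tau": rep.tau, "note": ""}
                )
        records.append(
            {"variant": rep.variant, "arm": "difference", "state": "relative_improvement_pct",
             "estimate": rep.contrast.relative_improvement_pct, "se": None,
             "ci_low": None, "ci_high": None, "p_value": None,
             "n": rep.n_active + rep.n_control, "tau": rep.tau,
             "note": rep.contrast.classification.value}
        )
    return pd.DataFrame.from_records(records)


def format_report(report: QTwistReport) -> str:
    """Human-readable fixed-width table mirroring the tidy frame."""
    lines = [
        f"Q-TWiST analysis [{report.variant}]  "
        f"n={report.n_active}/{report.n_control}, tau={report.tau:.2f} mo, "
        f"tox_mode={report.tox_mode}, B={report.n_replicates}",
        f"{'state':<8}{'active':>16}{'control':>16}{'difference':>24}{'p':>8}",
    ]
    for row in ROWS:
        a, c, d = report.active[row], report.control[row], report.differences[row]
        p = "<0.001" if d.p_value is not None and d.p_value < 0.001 else f"{d.p_value:.3f}"
        lines.append(
            f"{row.upper():<8}"
            f"{a.estimate:7.2f} ({a.ci_low:.2f}-{a.ci_high:.2f})"
            f"{c.estimate:7.2f} ({c.ci_low:.2f}-{c.ci_high:.2f})"
            f"{d.estimate:9.2f} ({d.ci_low:.2f} to {d.ci_high:.2f})"
            f"{p:>8}"
        )
    lines.append(
        f"relative improvement: {report.contrast.relative_improvement_pct:.1f}% "
        f"({report.contrast.classification.value})"
    )
    return "\n".join(lines)


def write_reports(
    reports: list[QTwistReport | SkippedSubgroup], out_dir: str | Path
) -> Path:
    """Write report.csv (tidy) and report.txt (human-readable); returns dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame(reports).to_csv(out / "report.csv", index=False)
    texts = [
        format_report(r)
        if isinstance(r, QTwistReport)
        else f"Q-TWiST analysis [{r.variant}] skipped: {r.reason}"
        for r in reports
    ]
    (out / "report.txt").write_text("\n\n".join(texts) + "\n", encoding="utf-8")
    return out
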