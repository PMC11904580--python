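"""Primary, subgroup and sensitivity analysis orchestration."""

import numpy as np
import pandas as pd
import pytest

from qtwist import (
    ARM_ACTIVE,
    ARM_CONTROL,
    BootstrapConfig,
    QTwistError,
    QTwistReport,
    SkippedSubgroup,
    SubgroupSpec,
    TrialDataset,
    UtilityWeights,
    default_scenario,
    format_report,
    report_frame,
    run_primary,
    run_sensitivity_serious,
    run_subgroups,
    simulate_trial,
    write_reports,
)
from qtwist.cohort_analysis import ROWS

BOOT = BootstrapConfig(n_replicates=60, seed=17)


def test_report_rows_internally_consistent(small_report):
    rep = small_report
    for est_map in (rep.active, rep.control, rep.differences):
        assert est_map["tox"].estimate + est_map["twist"].estimate + est_map[
            "rel"
        ].estimate == pytest.approx(est_map["os"].estimate, abs=1e-9)
        assert est_map["tox"].estimate + est_map["twist"].estimate == pytest.approx(
            est_map["pfs"].estimate, abs=1e-9
        )
        w = rep.weights
        assert est_map["qtwist"].estimate == pytest.approx(
            w.u_tox * est_map["tox"].estimate
            + w.u_twist * est_map["twist"].estimate
            + w.u_rel * est_map["rel"].estimate,
            abs=1e-9,
        )
    for row in ROWS:
        assert rep.differences[row].estimate == pytest.approx(
            rep.active[row].estimate - rep.control[row].estimate, abs=1e-9
        )


def test_report_is_reproducible_under_fixed_seed(small_trial):
    r1 = run_primary(small_trial, boot=BOOT)
    r2 = run_primary(small_trial, boot=BOOT)
    for row in ROWS:
        assert r1.differences[row] == r2.differences[row]


def test_explicit_tau_is_respected(small_trial):
    rep = run_primary(small_trial, boot=BOOT, tau=6.0)
    assert rep.tau == 6.0
    assert rep.active["os"].estimate <= 6.0


def test_sensitivity_equals_primary_when_serious_matches_grade34(small_trial):
    ds = TrialDataset(
        small_trial.subjects.copy(),
        small_trial.adverse_events.copy(),
        dict(small_trial.metadata),
    )
    grade34 = ds.adverse_events["grade"].isin([3, 4])
    ds.adverse_events["serious"] = grade34
    primary = run_primary(ds, boot=BOOT)
    sens = run_sensitivity_serious(ds, boot=BOOT)
    assert sens.variant == "sensitivity_serious"
    for row in ROWS:
        assert sens.differences[row].estimate == pytest.approx(
            primary.differences[row].estimate, abs=1e-12
        )


def test_sensitivity_dominates_when_serious_is_superset(small_trial):
    ds = TrialDataset(
        small_trial.subjects.copy(), small_trial.adverse_events.copy(), dict(small_trial.metadata)
    )
    # make the serious set a strict superset of the grade-3/4 set
    ds.adverse_events["serious"] = True
    primary = run_primary(ds, boot=BOOT)
    sens = run_sensitivity_serious(ds, boot=BOOT)
    assert sens.state_means[ARM_ACTIVE].mean_tox >= primary.state_means[ARM_ACTIVE].mean_tox
    assert sens.state_means[ARM_CONTROL].mean_tox >= primary.state_means[ARM_CONTROL].mean_tox


def test_zero_serious_aes_gives_zero_tox(small_trial):
    ds = TrialDataset(
        small_trial.subjects.copy(), small_trial.adverse_events.copy(), dict(small_trial.metadata)
    )
    ds.adverse_events["serious"] = False
    rep = run_sensitivity_serious(ds, boot=BOOT)
    for arm in (ARM_ACTIVE, ARM_CONTROL):
        assert rep.state_means[arm].mean_tox == 0.0
        assert rep.state_means[arm].mean_twist == pytest.approx(
            rep.state_means[arm].mean_pfs, abs=1e-12
        )


def test_variant_isolation_under_custom_weights(small_trial):
    """Primary and sensitivity differ only through the toxicity definition."""
    w = UtilityWeights(u_tox=0.3, u_rel=0.7)
    primary = run_primary(small_trial, weights=w, boot=BOOT)
    sens = run_sensitivity_serious(small_trial, weights=w, boot=BOOT)
    assert primary.tau == sens.tau
    assert primary.active["os"].estimate == pytest.approx(
        sens.active["os"].estimate, abs=1e-12
    )
    assert primary.active["pfs"].estimate == pytest.approx(
        sens.active["pfs"].estimate, abs=1e-12
    )


def test_subgroups_partition_the_cohort(small_trial):
    results = run_subgroups(small_trial, [SubgroupSpec("sex")], boot=BOOT)
    assert all(isinstance(r, QTwistReport) for r in results)
    total = sum(r.n_active + r.n_control for r in results)
    assert total == small_trial.n_subjects
    assert {r.variant for r in results} == {"subgroup:sex=female", "subgroup:sex=male"}


def test_small_subgroup_is_skipped_with_reason(small_trial):
    ds = TrialDataset(
        small_trial.subjects.copy(), small_trial.adverse_events.copy(), dict(small_trial.metadata)
    )
    ds.subjects["rare"] = "common"
    ds.subjects.loc[ds.subjects.index[:3], "rare"] = "rare"
    results = run_subgroups(ds, [SubgroupSpec("rare", min_size=10)], boot=BOOT)
    skipped = [r for r in results if isinstance(r, SkippedSubgroup)]
    assert len(skipped) == 1
    assert "below minimum" in skipped[0].reason or "empty" in skipped[0].reason


def test_unknown_covariate_raises(small_trial):
    with pytest.raises(QTwistError, match="unknown_var"):
        run_subgroups(small_trial, [SubgroupSpec("unknown_var")], boot=BOOT)


def test_unknown_category_raises(small_trial):
    with pytest.raises(QTwistError, match="other"):
        run_subgroups(small_trial, [SubgroupSpec("sex", categories=("other",))], boot=BOOT)


def test_report_frame_and_writers(small_report, tmp_path):
    frame = report_frame([small_report])
    assert set(frame["arm"]) == {"active", "control", "difference"}
    # 6 rows per arm column plus the relative-improvement row
    assert len(frame) == 19
    out = write_reports([small_report], tmp_path / "out")
    assert (out / "report.csv").exists()
    text = (out / "report.txt").read_text()
    assert "relative improvement" in text
    assert "QTWIST" in text


def test_format_report_shows_counts(small_report):
    text = format_report(small_report)
    assert f"n={small_report.n_active}/{small_report.n_control}" in text


def test_censored_scenario_runs_end_to_end():
    ds = simulate_trial(default_scenario(n_active=90, n_control=45, cutoff_month=13.0), seed=5)
    rep = run_primary(ds, boot=BootstrapConfig(n_replicates=80, seed=2))
    assert rep.tau <= 13.0 + 0.5 / 30.437 * 13  # within a rounding day of the cutoff
    assert rep.active["os"].estimate > rep.active["pfs"].estimate
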