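"""Evaluation harnesses: metric, LOSO, sweeps, weight diagnostic."""

import numpy as np
import pytest

from stig.baselines import majority_vote
from stig.ensemble import PredictionMatrix, ensemble_predict
from stig.evaluate import (
    RECORD_COLUMNS,
    balanced_accuracy,
    calibration_curve,
    ensemble_size_curve,
    fit_study_models,
    loso_compare,
    loso_run,
    stig_batch_labels,
    weight_accuracy_diagnostic,
)
from stig.exceptions import OneClassError
from stig.simulate import LabelNoiseSpec, simulate_label_noise_ensemble


class TestBalancedAccuracy:
    def test_hand_computed(self):
        y = np.array([1, 1, -1, -1, -1])
        p = np.array([1, -1, -1, -1, 1])
        # sens 1/2, spec 2/3
        assert balanced_accuracy(y, p) == pytest.approx(0.5 * (0.5 + 2 / 3))

    def test_perfect_and_inverted(self):
        y = np.array([1, -1, 1, -1])
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, -y) == 0.0

    def test_insensitive_to_class_imbalance(self):
        y = np.array([1] + [-1] * 99)
        p = np.full(100, -1)
        assert balanced_accuracy(y, p) == 0.5

    def test_one_class_truth_rejected(self):
        with pytest.raises(OneClassError):
            balanced_accuracy(np.ones(4), np.ones(4))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.ones(3), np.ones(4))


class TestStigBatchLabels:
    def test_beats_majority_vote_on_heterogeneous_ensemble(self):
        spec = LabelNoiseSpec(
            m=13,
            n=2000,
            psi=np.linspace(0.55, 0.95, 13),
            eta=np.linspace(0.55, 0.95, 13),
            prior=0.2,
            seed=0,
        )
        f, y = simulate_label_noise_ensemble(spec)
        stig_acc = balanced_accuracy(y, stig_batch_labels(f))
        mv_acc = balanced_accuracy(y, majority_vote(f))
        assert stig_acc >= mv_acc

    def test_degenerate_covariance_falls_back_to_mv(self):
        # orthogonal rows with equal variance: Q is a multiple of I
        vals = np.array([[1, 1, -1, -1], [1, -1, 1, -1]])
        f = PredictionMatrix(vals)
        assert np.array_equal(stig_batch_labels(f), majority_vote(f))

    def test_em_flag_changes_nothing_on_easy_case(self):
        spec = LabelNoiseSpec(
            m=9, n=800, psi=[0.9] * 9, eta=[0.9] * 9, prior=0.3, seed=1
        )
        f, y = simulate_label_noise_ensemble(spec)
        a = balanced_accuracy(y, stig_batch_labels(f, em=False))
        b = balanced_accuracy(y, stig_batch_labels(f, em=True))
        assert b >= a - 0.01


class TestLoso:
    def test_table_schema_and_methods(self, tiny_study, tiny_models):
        tab = loso_compare(
            tiny_study,
            ["stig", "mv", "mss"],
            seed=3,
            models=tiny_models,
        )
        assert list(tab.columns) == RECORD_COLUMNS
        assert len(tab) == 3 * len(tiny_study)
        assert set(tab["method_tag"]) == {"stig", "mv", "mss"}
        assert (tab["ensemble_size"] == len(tiny_study) - 1).all()
        assert (tab["seed"] == 3).all()
        assert tab["balanced_accuracy"].between(0, 1).all()

    def test_mv_rows_match_manual_recomputation(self, tiny_study, tiny_models):
        tab = loso_compare(tiny_study, ["mv"], models=tiny_models)
        for t, target in enumerate(tiny_study):
            src = [m for i, m in enumerate(tiny_models) if i != t]
            f = ensemble_predict(src, target)
            expected = balanced_accuracy(target.labels, majority_vote(f))
            got = tab.loc[
                tab["test_subject"] == target.subject_id, "balanced_accuracy"
            ].item()
            assert got == pytest.approx(expected)

    def test_calibration_methods_use_prefix(self, tiny_study, tiny_models):
        cfg = {"n_calibration_trials": 20}
        tab = loso_compare(
            tiny_study, ["calib", "awe"], config=cfg, models=tiny_models
        )
        assert (tab["n_calibration_trials"] == 20).all()

    def test_loso_run_is_single_method_view(self, tiny_study, tiny_models):
        a = loso_run(tiny_study, "mv", models=tiny_models)
        b = loso_compare(tiny_study, ["mv"], models=tiny_models)
        assert a.equals(b)

    def test_unknown_method_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            loso_compare(tiny_study, ["nope"])

    def test_needs_three_subjects(self, tiny_study):
        with pytest.raises(ValueError):
            loso_compare(tiny_study[:2], ["mv"])

    def test_infeasible_calibration_rejected(self, tiny_study, tiny_models):
        with pytest.raises(ValueError):
            loso_compare(
                tiny_study,
                ["calib"],
                config={"n_calibration_trials": 10_000},
                models=tiny_models,
            )


class TestEnsembleSizeCurve:
    def test_schema_and_targets(self, tiny_study):
        tab = ensemble_size_curve(tiny_study, [2, 3], n_boot=2, seed=0, targets=[0])
        assert list(tab["size"]) == [2, 3]
        assert "trend" in tab.attrs
        runs = tab.attrs["runs"]
        assert set(runs["test_subject"]) == {tiny_study[0].subject_id}
        # 1 target x 2 sizes x 2 boots
        assert len(runs) == 4

    def test_size_bounds(self, tiny_study):
        with pytest.raises(ValueError):
            ensemble_size_curve(tiny_study, [1])
        with pytest.raises(ValueError):
            ensemble_size_curve(tiny_study, [len(tiny_study)])

    def test_bad_targets(self, tiny_study):
        with pytest.raises(ValueError):
            ensemble_size_curve(tiny_study, [2], targets=[99])
        with pytest.raises(ValueError):
            ensemble_size_curve(tiny_study, [2], targets=[0, 0])

    def test_deterministic(self, tiny_study):
        a = ensemble_size_curve(tiny_study, [2], n_boot=2, seed=1, targets=[1])
        b = ensemble_size_curve(tiny_study, [2], n_boot=2, seed=1, targets=[1])
        assert a.equals(b)


class TestCalibrationCurve:
    def test_schema_and_zero_calibration_rows(self, tiny_study):
        tab = calibration_curve(
            tiny_study,
            methods=["calib"],
            trial_counts=[10],
            n_boot=2,
            seed=0,
            test_size=30,
            targets=[0],
        )
        stig_rows = tab[tab["method_tag"] == "stig"]
        assert (stig_rows["n_calibration_trials"] == 0).all()
        assert len(stig_rows) == 2  # one per bootstrap
        calib_rows = tab[tab["method_tag"] == "calib"]
        assert set(calib_rows["n_calibration_trials"]) == {10}

    def test_causal_mode_single_split(self, tiny_study):
        tab = calibration_curve(
            tiny_study,
            methods=["awe"],
            trial_counts=[10],
            n_boot=7,
            causal=True,
            test_size=30,
            targets=[0],
        )
        assert set(tab["boot"]) == {0}

    def test_empty_counts(self, tiny_study):
        tab = calibration_curve(tiny_study, trial_counts=[])
        assert tab.empty

    def test_infeasible_sizes_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            calibration_curve(
                tiny_study, methods=["calib"], trial_counts=[55], test_size=30
            )

    def test_unknown_method(self, tiny_study):
        with pytest.raises(ValueError):
            calibration_curve(tiny_study, methods=["stig"], trial_counts=[5])


class TestWeightDiagnostic:
    def test_correlates_weight_with_accuracy(self):
        spec = LabelNoiseSpec(
            m=9,
            n=3000,
            psi=np.linspace(0.55, 0.95, 9),
            eta=np.linspace(0.55, 0.95, 9),
            prior=0.2,
            seed=2,
        )
        f, y = simulate_label_noise_ensemble(spec)
        diag = weight_accuracy_diagnostic(f, y)
        assert diag.correlation > 0.9
        assert diag.flag is None
        assert list(diag.table.columns) == [
            "classifier_id",
            "weight",
            "transfer_balanced_accuracy",
        ]
        # table accuracies are honest recomputations
        for i, row in enumerate(f.values):
            assert diag.table["transfer_balanced_accuracy"][i] == pytest.approx(
                balanced_accuracy(y, row)
            )

    def test_identical_classifiers_flagged(self):
        y = np.array([1, -1, 1, -1])
        vals = np.tile(y, (3, 1))
        diag = weight_accuracy_diagnostic(PredictionMatrix(vals), y)
        assert np.isnan(diag.correlation)
        assert "identical" in diag.flag

    def test_m2_flagged_uninformative(self):
        rng = np.random.default_rng(3)
        y = rng.choice([-1, 1], size=200)
        y[:2] = [1, -1]
        vals = np.stack(
            [np.where(rng.random(200) < 0.2, -y, y) for _ in range(2)]
        ).astype(np.int8)
        diag = weight_accuracy_diagnostic(PredictionMatrix(vals), y)
        assert diag.flag is not None and "m=2" in diag.flag
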