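"""Spectral meta-learning: covariance, eigenvector weights, MLE labels, EM."""

import itertools

import numpy as np
import pytest

from stig.ensemble import (
    EnsembleWeights,
    PredictionMatrix,
    em_refine,
    estimate_operating_points,
    mle_labels,
    prediction_covariance,
    sml_labels,
    spectral_weights,
    trial_score,
)
from stig.exceptions import (
    DegenerateSpectrumError,
    DimensionMismatchError,
    OneClassError,
)
from stig.simulate import LabelNoiseSpec, simulate_label_noise_ensemble


def brute_covariance(vals: np.ndarray) -> np.ndarray:
    """Literal double-loop sample covariance of the rows across trials."""
    m, n = vals.shape
    mean = vals.mean(axis=1)
    q = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            acc = 0.0
            for t in range(n):
                acc += (vals[i, t] - mean[i]) * (vals[j, t] - mean[j])
            q[i, j] = acc / (n - 1)
    return q


def bayes_labels(vals: np.ndarray, psi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Enumeration oracle: the conditional-independence likelihood-ratio rule
    with a flat label prior; ties resolve to -1."""
    m, n = vals.shape
    out = np.empty(n, dtype=np.int8)
    for t in range(n):
        lp, ln = 1.0, 1.0
        for i in range(m):
            if vals[i, t] == 1:
                lp *= psi[i]
                ln *= 1 - eta[i]
            else:
                lp *= 1 - psi[i]
                ln *= eta[i]
        out[t] = 1 if lp > ln else -1
    return out


class TestPredictionMatrix:
    def test_valid_and_defaults(self):
        f = PredictionMatrix(np.array([[1, -1], [-1, 1]]))
        assert f.n_classifiers == 2 and f.n_trials == 2
        assert f.classifier_ids == ("clf0", "clf1")
        assert f.trial_ids == (0, 1)
        assert f.values.dtype == np.int8

    def test_rejects_non_pm1(self):
        with pytest.raises(ValueError):
            PredictionMatrix(np.array([[1, 0], [1, -1]]))

    def test_rejects_bad_shape_and_ids(self):
        with pytest.raises(DimensionMismatchError):
            PredictionMatrix(np.array([1, -1]))
        with pytest.raises(DimensionMismatchError):
            PredictionMatrix(np.ones((2, 2)), classifier_ids=["a"])
        with pytest.raises(DimensionMismatchError):
            PredictionMatrix(np.ones((2, 2)), trial_ids=[0])


class TestEnsembleWeights:
    def test_requires_unit_norm(self):
        with pytest.raises(ValueError):
            EnsembleWeights(v=np.array([1.0, 1.0]), eigenvalue=1.0)

    def test_requires_nonnegative_sum(self):
        v = -np.ones(2) / np.sqrt(2)
        with pytest.raises(ValueError):
            EnsembleWeights(v=v, eigenvalue=1.0)


class TestPredictionCovariance:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([-1, 1], size=(4, 30))
        got = prediction_covariance(PredictionMatrix(vals))
        assert np.allclose(got, brute_covariance(vals.astype(float)), atol=1e-12)

    def test_weighted_matches_manual(self):
        rng = np.random.default_rng(1)
        vals = rng.choice([-1, 1], size=(3, 20)).astype(float)
        w = rng.uniform(0.5, 2.0, size=20)
        got = prediction_covariance(vals, weights=w)
        # manual aweights covariance: weighted mean, normalization
        # v1 - v2/v1 with v1 = sum(w), v2 = sum(w^2)
        mu = (vals * w).sum(axis=1) / w.sum()
        d = vals - mu[:, None]
        v1, v2 = w.sum(), (w**2).sum()
        manual = (d * w) @ d.T / (v1 - v2 / v1)
        assert np.allclose(got, manual, atol=1e-12)

    def test_rejects_single_trial_and_bad_weights(self):
        with pytest.raises(DimensionMismatchError):
            prediction_covariance(np.array([[1.0], [1.0]]))
        with pytest.raises(ValueError):
            prediction_covariance(np.ones((2, 3)), weights=np.array([1.0, -1.0, 1.0]))


class TestSpectralWeights:
    def test_recovers_planted_eigenvector(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(5)
        v = np.abs(v)  # positive entries: sum convention unambiguous
        v /= np.linalg.norm(v)
        q = 3.0 * np.outer(v, v) + 1e-4 * np.diag(rng.uniform(1, 2, 5))
        w = spectral_weights(q)
        assert np.allclose(w.v, v, atol=1e-3)
        assert w.v.sum() >= 0
        assert w.eigenvalue == pytest.approx(3.0, rel=1e-3)

    def test_sign_convention(self):
        q = np.outer([0.6, 0.8], [0.6, 0.8])
        w = spectral_weights(q)
        assert w.v.sum() > 0

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            spectral_weights(np.eye(3))

    def test_rejects_nonsquare(self):
        with pytest.raises(DimensionMismatchError):
            spectral_weights(np.ones((2, 3)))


class TestSmlLabels:
    def test_weighted_vote_sign(self):
        f = np.array([[1, -1, 1], [1, 1, -1]])
        v = np.array([0.8, 0.6])
        got = sml_labels(f, v)
        assert np.array_equal(got, np.sign(v @ f).astype(np.int8))

    def test_tie_resolves_to_nontarget(self):
        f = np.array([[1], [-1]])
        v = np.array([1.0, 1.0]) / np.sqrt(2)
        assert sml_labels(f, v)[0] == -1

    def test_length_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            sml_labels(np.ones((3, 2)), np.ones(2) / np.sqrt(2))


class TestOperatingPoints:
    def test_hand_computed(self):
        f = np.array(
            [
                [1, 1, -1, -1, 1],
                [1, -1, 1, -1, -1],
            ]
        )
        labels = np.array([1, 1, -1, -1, -1])
        psi, eta = estimate_operating_points(f, labels, clip=0.01)
        assert psi[0] == pytest.approx(1.0 - 0.01)  # 2/2 clipped
        assert psi[1] == pytest.approx(0.5)
        assert eta[0] == pytest.approx(2.0 / 3.0)
        assert eta[1] == pytest.approx(2.0 / 3.0)

    def test_default_laplace_clip(self):
        f = np.array([[1, 1, -1, -1]])
        labels = np.array([1, 1, -1, -1])
        psi, eta = estimate_operating_points(f, labels)
        # 2 positives -> clip 1/(2*2+2) = 1/6
        assert psi[0] == pytest.approx(1 - 1 / 6)
        assert eta[0] == pytest.approx(1 - 1 / 6)

    def test_one_class_labels_rejected(self):
        with pytest.raises(OneClassError):
            estimate_operating_points(np.ones((2, 3)), np.array([1, 1, 1]))

    def test_label_flip_swaps_psi_eta(self):
        rng = np.random.default_rng(3)
        f = rng.choice([-1, 1], size=(4, 40))
        labels = rng.choice([-1, 1], size=40)
        labels[0], labels[1] = 1, -1
        psi, eta = estimate_operating_points(f, labels, clip=0.01)
        psi2, eta2 = estimate_operating_points(-f, -labels, clip=0.01)
        # flipping all decisions and labels swaps the roles of the classes
        assert np.allclose(psi2, eta)
        assert np.allclose(eta2, psi)


class TestMleLabels:
    def test_matches_bayes_enumeration(self):
        rng = np.random.default_rng(4)
        m = 4
        for _ in range(5):
            psi = rng.uniform(0.55, 0.95, m)
            eta = rng.uniform(0.55, 0.95, m)
            patterns = np.array(
                list(itertools.product([-1, 1], repeat=m))
            ).T  # m x 2^m
            got = mle_labels(patterns, psi, eta)
            assert np.array_equal(got, bayes_labels(patterns, psi, eta))

    def test_literal_variant(self):
        rng = np.random.default_rng(5)
        m = 3
        psi = rng.uniform(0.55, 0.95, m)
        eta = rng.uniform(0.55, 0.95, m)
        alpha = np.log(psi * eta / ((1 - psi) * (1 - eta)))
        beta = np.log(psi * (1 - psi) / (eta * (1 - eta)))
        patterns = np.array(list(itertools.product([-1, 1], repeat=m))).T
        got = mle_labels(patterns, psi, eta, literal=True)
        expected = np.where((alpha + beta) @ patterns > 0, 1, -1)
        assert np.array_equal(got, expected)

    def test_rejects_boundary_operating_points(self):
        with pytest.raises(ValueError):
            mle_labels(np.ones((1, 2)), np.array([1.0]), np.array([0.7]))

    def test_trial_score_formula(self):
        psi = np.array([0.8, 0.7])
        eta = np.array([0.9, 0.6])
        alpha = np.log(psi * eta / ((1 - psi) * (1 - eta)))
        beta = np.log(psi * (1 - psi) / (eta * (1 - eta)))
        f = np.array([1.0, -1.0])
        assert trial_score(f, psi, eta) == pytest.approx(abs(f @ alpha + beta.sum()))


class TestEmRefine:
    def test_zero_iterations_returns_init(self):
        f = np.array([[1, -1, 1, -1]])
        init = np.array([1, -1, 1, -1], dtype=np.int8)
        res = em_refine(f, init, max_iter=0)
        assert np.array_equal(res.labels, init)
        assert res.iterations == 0

    def test_fixed_point_detection(self):
        # strong ensemble, init at the truth: EM should stop quickly and
        # keep the labels
        spec = LabelNoiseSpec(
            m=9, n=400, psi=[0.9] * 9, eta=[0.9] * 9, prior=0.3, seed=0
        )
        f, y = simulate_label_noise_ensemble(spec)
        res = em_refine(f, y)
        assert res.iterations <= 5
        assert not res.degenerate
        assert np.mean(res.labels == y) > 0.95

    def test_improves_noisy_init(self):
        spec = LabelNoiseSpec(
            m=15, n=600, psi=[0.85] * 15, eta=[0.85] * 15, prior=0.3, seed=1
        )
        f, y = simulate_label_noise_ensemble(spec)
        rng = np.random.default_rng(2)
        init = np.where(rng.random(600) < 0.3, -y, y).astype(np.int8)
        res = em_refine(f, init)
        assert np.mean(res.labels == y) > np.mean(init == y)

    def test_collapse_flags_degenerate(self):
        # every classifier always votes +1: the MLE labels collapse to one
        # class after the first relabeling
        f = np.ones((3, 6), dtype=int)
        init = np.array([1, 1, 1, 1, -1, -1], dtype=np.int8)
        with pytest.warns(RuntimeWarning):
            res = em_refine(f, init)
        assert res.degenerate
        assert np.array_equal(res.labels, init)

    def test_input_validation(self):
        with pytest.raises(DimensionMismatchError):
            em_refine(np.ones((2, 3)), np.array([1, -1]))
        with pytest.raises(ValueError):
            em_refine(np.ones((2, 3)), np.array([1, 0, -1]))


class TestEndToEndSpectral:
    def test_recovers_labels_on_easy_ensemble(self):
        spec = LabelNoiseSpec(
            m=11,
            n=1000,
            psi=np.linspace(0.6, 0.95, 11),
            eta=np.linspace(0.65, 0.9, 11),
            prior=0.2,
            seed=3,
        )
        f, y = simulate_label_noise_ensemble(spec)
        w = spectral_weights(prediction_covariance(f))
        labels = sml_labels(f, w)
        assert np.mean(labels == y) > 0.9
        # eigenvector correlates with the true accuracy profile
        pi = (np.asarray(spec.psi) + np.asarray(spec.eta)) / 2
        assert np.corrcoef(w.v, 2 * pi - 1)[0, 1] > 0.5
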