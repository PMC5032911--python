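"""Metrics and multi-subject evaluation harnesses.

Implements the balanced-accuracy metric, leave-one-subject-out (LOSO)
transfer evaluation for every combiner in the package, ensemble-size and
calibration-size sweeps, and the weight-versus-transfer-accuracy
diagnostic. All harnesses are deterministic given their seeds and emit
tidy per-run tables suitable for downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .baselines import (
    LinearCombiner,
    awe_weights,
    best_single_subject,
    l1_ensemble_weights,
    majority_vote,
    pooled_mdrm,
)
from .ensemble import (
    PredictionMatrix,
    em_refine,
    ensemble_predict,
    prediction_covariance,
    sml_labels,
    spectral_weights,
)
from .epochs import EpochSet, NONTARGET, TARGET
from .exceptions import (
    ConvergenceError,
    DegenerateSpectrumError,
    MissingClassError,
    OneClassError,
)
from .mdrm import MDRMModel, fit_mdrm, predict_epochs
from .streaming import StreamConfig, init_stream, process_trial

ZERO_CALIBRATION_METHODS = ("stig", "mv", "l1", "pmdrm", "mss")
CALIBRATION_METHODS = ("awe", "calib")
KNOWN_METHODS = ZERO_CALIBRATION_METHODS + CALIBRATION_METHODS

RECORD_COLUMNS = [
    "method_tag",
    "test_subject",
    "n_calibration_trials",
    "ensemble_size",
    "balanced_accuracy",
    "seed",
]


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2; requires both classes in y_true."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    pos = y_true == TARGET
    neg = y_true == NONTARGET
    if not pos.any() or not neg.any():
        raise OneClassError("balanced accuracy is undefined without both classes")
    sens = float((y_pred[pos] == TARGET).mean())
    spec = float((y_pred[neg] == NONTARGET).mean())
    return 0.5 * (sens + spec)


def stig_batch_labels(
    f: PredictionMatrix,
    clip: Optional[float] = None,
    em: bool = True,
    em_max_iter: int = 50,
) -> np.ndarray:
    """Batch spectral transfer on a fixed prediction matrix.

    Principal-eigenvector weighting, first-order labels, and (by default) EM
    refinement. Falls back to majority vote if the covariance spectrum is
    degenerate or the provisional labels are one-class.
    """
    try:
        weights = spectral_weights(prediction_covariance(f))
    except DegenerateSpectrumError:
        return majority_vote(f)
    labels = sml_labels(f, weights)
    if em:
        try:
            labels = em_refine(f, labels, clip=clip, max_iter=em_max_iter).labels
        except OneClassError:
            pass
    return labels


def fit_study_models(
    study: Sequence[EpochSet], tol: float = 1e-8, max_iter: int = 150
) -> List[MDRMModel]:
    """One MDRM model per subject in the study."""
    return [fit_mdrm(s, tol=tol, max_iter=max_iter) for s in study]


def _stacked_l1_combiner(
    src_sets: Sequence[EpochSet],
    src_models: Sequence[MDRMModel],
    lambda_grid,
    cv_folds: int,
    seed: int,
) -> LinearCombiner:
    """Leave-one-source-subject-out stacking for the l1 baseline.

    Each classifier's decisions on its own training subject are unavailable
    by construction; those entries are 0 (abstentions).
    """
    blocks = []
    labels = []
    for s_idx, s_set in enumerate(src_sets):
        block = np.zeros((len(src_models), len(s_set)))
        for m_idx, model in enumerate(src_models):
            if m_idx == s_idx:
                continue
            block[m_idx] = predict_epochs(model, s_set)[0]
        blocks.append(block)
        labels.append(s_set.labels)
    return l1_ensemble_weights(
        np.concatenate(blocks, axis=1),
        np.concatenate(labels),
        lambda_grid=lambda_grid,
        cv_folds=cv_folds,
        seed=seed,
    )


def _calib_predict(calib: EpochSet, test: EpochSet) -> np.ndarray:
    """Within-subject calibration baseline; an unfittable calibration set
    (one class only, or class means that do not converge on a handful of
    trials) degrades to the constant non-target rule."""
    try:
        model = fit_mdrm(calib)
    except (MissingClassError, ConvergenceError):
        return np.full(len(test), NONTARGET, dtype=np.int8)
    return predict_epochs(model, test)[0]


_LOSO_DEFAULTS = {
    "causal": False,
    "em": True,
    "clip": None,
    "n_calibration_trials": 100,
    "lambda_grid": (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    "cv_folds": 5,
}


def _stream_labels(models, test: EpochSet, clip) -> np.ndarray:
    state = init_stream(models, StreamConfig(clip=clip))
    out = []
    for epoch in test:
        label, _, state = process_trial(state, epoch)
        out.append(label)
    return np.asarray(out, dtype=np.int8)


def loso_compare(
    study: Sequence[EpochSet],
    methods: Sequence[str],
    config: Optional[dict] = None,
    seed: int = 0,
    models: Optional[Sequence[MDRMModel]] = None,
) -> pd.DataFrame:
    """Leave-one-subject-out transfer evaluation of several methods on the
    same folds.

    For each held-out subject, per-source MDRM models are fitted on the
    remaining subjects (or taken from ``models``) and every named combiner
    is applied to the held-out stream; per-fold prediction matrices are
    shared across methods. Calibration methods (awe, calib) consume a
    sequential prefix of ``n_calibration_trials`` from the held-out subject
    and are scored on the remainder; zero-calibration methods are scored on
    the full stream.
    """
    methods = [m.lower() for m in methods]
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; known: {KNOWN_METHODS}")
    if len(study) < 3:
        raise ValueError("LOSO evaluation needs at least 3 subjects")
    cfg = {**_LOSO_DEFAULTS, **(config or {})}
    if models is None:
        models = fit_study_models(study)
    records = []
    for t, target_set in enumerate(study):
        src_models = [m for i, m in enumerate(models) if i != t]
        src_sets = [s for i, s in enumerate(study) if i != t]
        full_f = None
        if any(m not in ("pmdrm", "calib") for m in methods):
            full_f = ensemble_predict(src_models, target_set)

        for method in methods:
            n_calib = 0
            if method in CALIBRATION_METHODS:
                n_calib = int(cfg["n_calibration_trials"])
                if n_calib < 1 or n_calib >= len(target_set):
                    raise ValueError("infeasible n_calibration_trials for this study")
                calib_idx = np.arange(n_calib)
                test_idx = np.arange(n_calib, len(target_set))
                calib = target_set.subset(calib_idx)
                test = target_set.subset(test_idx)
            else:
                calib_idx = test_idx = None
                calib, test = None, target_set

            acc = None
            if method == "pmdrm":
                y_pred = predict_epochs(pooled_mdrm(src_sets), test)[0]
            elif method == "calib":
                y_pred = _calib_predict(calib, test)
            else:
                f = (
                    full_f
                    if test_idx is None
                    else PredictionMatrix(
                        full_f.values[:, test_idx],
                        classifier_ids=full_f.classifier_ids,
                    )
                )
                if method == "stig":
                    if cfg["causal"]:
                        y_pred = _stream_labels(src_models, test, cfg["clip"])
                    else:
                        y_pred = stig_batch_labels(f, clip=cfg["clip"], em=cfg["em"])
                elif method == "mv":
                    y_pred = majority_vote(f)
                elif method == "mss":
                    _, acc = best_single_subject(f, test.labels)
                elif method == "l1":
                    combiner = _stacked_l1_combiner(
                        src_sets, src_models, cfg["lambda_grid"], cfg["cv_folds"], seed
                    )
                    y_pred = combiner.predict(f)
                elif method == "awe":
                    f_cal = PredictionMatrix(
                        full_f.values[:, calib_idx],
                        classifier_ids=full_f.classifier_ids,
                    )
                    y_pred = awe_weights(f_cal, calib.labels).predict(f)

            if acc is None:
                acc = balanced_accuracy(test.labels, y_pred)
            records.append(
                {
                    "method_tag": method,
                    "test_subject": target_set.subject_id or str(t),
                    "n_calibration_trials": n_calib,
                    "ensemble_size": len(src_models),
                    "balanced_accuracy": acc,
                    "seed": seed,
                }
            )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def loso_run(
    study: Sequence[EpochSet],
    method_tag: str,
    config: Optional[dict] = None,
    seed: int = 0,
    models: Optional[Sequence[MDRMModel]] = None,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation of a single method (see
    :func:`loso_compare`)."""
    return loso_compare(study, [method_tag], config=config, seed=seed, models=models)


def _resolve_targets(
    study: Sequence[EpochSet], targets: Optional[Sequence[int]]
) -> List[int]:
    if targets is None:
        return list(range(len(study)))
    targets = [int(t) for t in targets]
    if not targets or len(set(targets)) != len(targets):
        raise ValueError("targets must be a non-empty list of distinct indices")
    if any(t < 0 or t >= len(study) for t in targets):
        raise ValueError("target index out of range")
    return targets


def _fit_source_models(
    study: Sequence[EpochSet], targets: Sequence[int]
) -> List[Optional[MDRMModel]]:
    """Fit models only for subjects that act as a source for some target."""
    needed = {
        i for t in targets for i in range(len(study)) if i != t
    }
    return [fit_mdrm(s) if i in needed else None for i, s in enumerate(study)]


def ensemble_size_curve(
    study: Sequence[EpochSet],
    sizes: Sequence[int],
    n_boot: int = 10,
    seed: int = 0,
    targets: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Mean spectral-transfer accuracy as a function of ensemble size.

    For each held-out subject (all of them, or the indices in ``targets``)
    and each size, ``n_boot`` random source subsets are drawn and batch
    spectral transfer is scored on the held-out stream. Returns one row per
    size with the mean and standard error, and a Spearman monotone-trend
    statistic in ``DataFrame.attrs['trend']``.
    """
    s = len(study)
    sizes = [int(k) for k in sizes]
    if any(k < 2 or k > s - 1 for k in sizes):
        raise ValueError("each ensemble size must lie in [2, S-1]")
    target_idx = _resolve_targets(study, targets)
    models = _fit_source_models(study, target_idx)
    rng = np.random.default_rng(seed)
    runs = []
    for t in target_idx:
        test = study[t]
        src_models = [m for i, m in enumerate(models) if i != t]
        f_full = ensemble_predict(src_models, test)
        pool = len(src_models)
        for k in sizes:
            for b in range(n_boot):
                idx = np.sort(rng.choice(pool, size=k, replace=False))
                sub = PredictionMatrix(
                    f_full.values[idx],
                    classifier_ids=[f_full.classifier_ids[i] for i in idx],
                    trial_ids=f_full.trial_ids,
                )
                labels = stig_batch_labels(sub)
                runs.append(
                    {
                        "size": k,
                        "test_subject": test.subject_id or str(t),
                        "boot": b,
                        "balanced_accuracy": balanced_accuracy(test.labels, labels),
                    }
                )
    runs = pd.DataFrame(runs)
    out = (
        runs.groupby("size")["balanced_accuracy"]
        .agg(mean_balanced_accuracy="mean", stderr=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    if len(out) >= 2:
        trend = scipy.stats.spearmanr(runs["size"], runs["balanced_accuracy"])
        out.attrs["trend"] = {
            "spearman_rho": float(trend.statistic),
            "p_value": float(trend.pvalue),
        }
    out.attrs["runs"] = runs
    return out


def calibration_curve(
    study: Sequence[EpochSet],
    methods: Sequence[str] = ("awe", "calib"),
    trial_counts: Sequence[int] = (),
    n_boot: int = 50,
    seed: int = 0,
    causal: bool = False,
    test_size: Optional[int] = None,
    targets: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Calibration-size sweep for calibration-dependent methods vs.
    zero-calibration spectral transfer.

    Bootstrap mode (``causal=False``) draws disjoint random calibration and
    test trials per iteration; causal mode uses sequential prefixes for
    calibration and the fixed stream tail for testing (one deterministic
    split, so ``n_boot`` is forced to 1). Spectral transfer is evaluated on
    the same test trials with zero calibration for comparison
    (``n_calibration_trials = 0`` rows). ``targets`` restricts the sweep to
    the given held-out subject indices; subjects outside ``targets`` only
    need enough trials to fit a source model.
    """
    methods = [m.lower() for m in methods]
    unknown = [m for m in methods if m not in CALIBRATION_METHODS]
    if unknown:
        raise ValueError(f"unknown calibration methods: {unknown}")
    trial_counts = [int(c) for c in trial_counts]
    if not trial_counts:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    target_idx = _resolve_targets(study, targets)
    n_trials = min(len(study[t]) for t in target_idx)
    if test_size is None:
        test_size = min(600, n_trials - max(trial_counts))
    if test_size < 10 or max(trial_counts) + test_size > n_trials:
        raise ValueError("infeasible trial_counts/test_size for this study")
    if causal:
        n_boot = 1
    models = _fit_source_models(study, target_idx)
    records = []
    for t in target_idx:
        target_set = study[t]
        src_models = [m for i, m in enumerate(models) if i != t]
        f_all = ensemble_predict(src_models, target_set)
        n = len(target_set)
        for b in range(n_boot):
            rng = np.random.default_rng([seed, t, b])
            if causal:
                test_idx = np.arange(n - test_size, n)
                remaining = np.arange(n - test_size)
            else:
                perm = rng.permutation(n)
                test_idx = np.sort(perm[:test_size])
                remaining = perm[test_size:]
            test = target_set.subset(test_idx)
            f_test = PredictionMatrix(
                f_all.values[:, test_idx],
                classifier_ids=f_all.classifier_ids,
            )
            records.append(
                {
                    "method_tag": "stig",
                    "test_subject": target_set.subject_id or str(t),
                    "n_calibration_trials": 0,
                    "ensemble_size": len(src_models),
                    "balanced_accuracy": balanced_accuracy(
                        test.labels, stig_batch_labels(f_test)
                    ),
                    "seed": seed,
                    "boot": b,
                }
            )
            for count in trial_counts:
                calib_idx = remaining[:count] if causal else np.sort(remaining[:count])
                calib = target_set.subset(calib_idx)
                for method in methods:
                    if method == "awe":
                        f_cal = PredictionMatrix(
                            f_all.values[:, calib_idx],
                            classifier_ids=f_all.classifier_ids,
                        )
                        try:
                            y_pred = awe_weights(f_cal, calib.labels).predict(f_test)
                        except OneClassError:
                            y_pred = majority_vote(f_test)
                    else:
                        y_pred = _calib_predict(calib, test)
                    records.append(
                        {
                            "method_tag": method,
                            "test_subject": target_set.subject_id or str(t),
                            "n_calibration_trials": count,
                            "ensemble_size": len(src_models),
                            "balanced_accuracy": balanced_accuracy(test.labels, y_pred),
                            "seed": seed,
                            "boot": b,
                        }
                    )
    return pd.DataFrame(records, columns=RECORD_COLUMNS + ["boot"])


@dataclass
class WeightDiagnostic:
    """Spectral weight vs. direct-transfer accuracy, per classifier."""

    table: pd.DataFrame
    correlation: float
    flag: Optional[str] = None


def weight_accuracy_diagnostic(f: PredictionMatrix, y_true) -> WeightDiagnostic:
    """Pair each classifier's spectral weight with its true direct-transfer
    balanced accuracy and report their Pearson correlation.

    The correlation is NaN (with a reason flag) when the classifiers are
    indistinguishable; with only two classifiers it is +/-1 by construction
    and flagged as uninformative.
    """
    y_true = np.asarray(y_true)
    vals = f.values
    accs = np.array([balanced_accuracy(y_true, row) for row in vals])
    flag = None
    if np.all(vals == vals[0]):
        v = np.full(vals.shape[0], 1.0 / np.sqrt(vals.shape[0]))
        corr = float("nan")
        flag = "identical classifiers: correlation undefined"
    else:
        v = spectral_weights(prediction_covariance(f)).v
        if np.std(accs) == 0 or np.std(v) == 0:
            corr = float("nan")
            flag = "zero variance in weights or accuracies: correlation undefined"
        else:
            corr = float(scipy.stats.pearsonr(v, accs).statistic)
            if vals.shape[0] == 2:
                flag = "m=2: correlation is +/-1 by construction"
    table = pd.DataFrame(
        {
            "classifier_id": list(f.classifier_ids),
            "weight": v,
            "transfer_balanced_accuracy": accs,
        }
    )
    return WeightDiagnostic(table=table, correlation=corr, flag=flag)
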