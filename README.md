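# stig-bci

Zero-calibration single-trial ERP detection by **S**pectral **T**ransfer
with **I**nformation **G**eometry.

A new brain–computer-interface user normally has to sit through a
calibration session before a classifier can decode their EEG. This package
removes that step: classifiers trained on *other* people are applied to the
new user's unlabeled stream, and their votes are fused by spectral
meta-learning, which infers — from the votes alone — how accurate each
source classifier is on this particular user and weights it accordingly.

## How it works

1. **Per-subject classifiers.** Each source subject's labeled epochs are
   turned into extended-trial sample covariance matrices (ESCM): the epoch
   is stacked on a class-mean "prototype" so the covariance captures both
   spatial structure and temporal alignment with the average evoked
   response. A minimum-distance-to-Riemannian-mean (MDRM) classifier stores
   the Fréchet (geometric) mean of each class under the affine-invariant
   metric and labels a new epoch by the nearer class mean.
2. **Unsupervised fusion.** Applying `m` source models to `n` unlabeled
   target epochs gives an `m x n` matrix of ±1 votes. Under a
   conditional-independence model, the off-diagonal of the vote covariance
   factors through each classifier's balanced accuracy, so the principal
   eigenvector of the sample covariance recovers (up to scale) how good
   each classifier is *on this target* — with no target labels. Votes are
   combined with those weights; an optional Dawid–Skene EM pass refines the
   labels under per-classifier sensitivity/specificity estimates.
3. **Streaming.** For online use the ensemble starts with a majority vote
   (cold start), switches to spectral weights once the vote covariance
   reaches full rank, and updates the eigenvector per trial with an exact
   rank-one eigendecomposition update.

Baselines included for comparison: majority vote (`mv`), accuracy-weighted
ensemble fit on calibration labels (`awe`), L1-regularized stacking (`l1`),
pooled-covariance MDRM (`pmdrm`), best-single-subject oracle (`mss`), and a
within-subject calibrated MDRM (`calib`).

No public single-trial ERP transfer corpus ships with the package; instead
`stig.simulate` provides two generators — a label-noise ensemble with known
operating points (for validating the spectral machinery against ground
truth) and a multi-subject RSVP-style ERP study with between-subject
amplitude/latency/topography variation (for end-to-end transfer
experiments).

## Worked example

```python
import numpy as np
from stig import (
    ERPStudySpec, simulate_study, fit_study_models,
    ensemble_predict, stig_batch_labels, balanced_accuracy,
    weight_accuracy_diagnostic,
)
from stig.baselines import majority_vote

# eight simulated subjects; the last one is the unlabeled "new user"
spec = ERPStudySpec(subjects=8, trials_per_subject=300, seed=5)
study = simulate_study(spec)
target, sources = study[-1], study[:-1]

models = fit_study_models(sources)          # one MDRM model per source subject
f = ensemble_predict(models, target)        # 7 x 300 matrix of +/-1 votes

stig = stig_batch_labels(f)                 # spectral weights, no target labels
mv = majority_vote(f)

print(f"STIG balanced accuracy: {balanced_accuracy(target.labels, stig):.3f}")
print(f"MV   balanced accuracy: {balanced_accuracy(target.labels, mv):.3f}")

diag = weight_accuracy_diagnostic(f, target.labels)
print(f"weight/accuracy correlation: {diag.correlation:.3f}")
print(diag.table.round(3).to_string(index=False))
```

Output (exact, deterministic given the seed):

```text
STIG balanced accuracy: 0.633
MV   balanced accuracy: 0.550
weight/accuracy correlation: 0.957
classifier_id  weight  transfer_balanced_accuracy
        sim00   0.380                       0.580
        sim01  -0.000                       0.500
        sim02   0.271                       0.550
        sim03   0.397                       0.626
        sim04   0.635                       0.717
        sim05  -0.000                       0.500
        sim06   0.470                       0.617
```

The spectral weights, computed without ever seeing a target label, rank
the source subjects almost exactly by how well they actually transfer
(held-out correlation 0.957 here): subjects whose models are at chance on
this user get zero weight, and the fused label beats the unweighted vote.

## Command line

Every step is also exposed through the `stig` CLI (see `stig --help`):

```bash
stig --seed 0 simulate-study --out study.h5        # config via --config cfg.yaml
stig fit-models --study study.h5 --out models.h5
stig transfer --models models.h5 --target study.h5 --subject sim07 \
     --method stig --out labels.csv
stig evaluate-loso --study study.h5 --method stig --out loso.csv
stig sweep-ensemble-size --study study.h5 --sizes 3,5,7 --out sizes.csv
stig sweep-calibration --study study.h5 --counts 16,64,256 --out calib.csv
stig simulate-ensemble --out pred.csv --m 31 --n 5000
stig diagnose-weights --predictions pred.csv --labels pred.csv.labels.csv \
     --out diag.csv
```

## Evaluation harnesses

- `loso_compare(study, methods)` — leave-one-subject-out comparison of any
  subset of `stig/mv/l1/pmdrm/mss/awe/calib`, one tidy row per
  (method, held-out subject).
- `ensemble_size_curve(study, sizes)` — accuracy vs number of source
  subjects, bootstrapped over source subsets.
- `calibration_curve(study, methods, trial_counts)` — zero-calibration
  STIG against methods that consume labeled target trials, as a function
  of calibration-set size.
- `weight_accuracy_diagnostic(f, y)` — the weight-vs-transfer-accuracy
  table shown above.

All three return pandas DataFrames and are deterministic given `seed`.

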