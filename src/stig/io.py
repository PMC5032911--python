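"""File formats: HDF5 epoch containers and model stores, CSV tables.

Epoch container layout — one HDF5 group per subject:
    <subject>/signals   float dataset, (n_trials, C, N)
    <subject>/labels    int8 dataset, (n_trials,), values in {-1, +1, 0}
    group attrs: fs, channel_names, subject_id
Trial axis order is presentation order (required for causal evaluation).

Model store — one group per fitted MDRM model with ``prototype``,
``mean_neg`` and ``mean_pos`` datasets and the same attrs.
"""

from __future__ import annotations

from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .baselines import LinearCombiner
from .ensemble import PredictionMatrix
from .epochs import EpochSet, Prototype
from .mdrm import MDRMModel
from .spd import SymmetricPositiveDefinite


def save_study(path, study: Sequence[EpochSet]) -> None:
    with h5py.File(path, "w") as h:
        for i, s in enumerate(study):
            name = s.subject_id or f"subject{i:02d}"
            g = h.create_group(name)
            g.create_dataset("signals", data=s.signals)
            g.create_dataset("labels", data=s.labels.astype(np.int8))
            g.attrs["fs"] = s.fs
            g.attrs["channel_names"] = list(s.channel_names)
            g.attrs["subject_id"] = name


def load_study(path) -> List[EpochSet]:
    out = []
    with h5py.File(path, "r") as h:
        for name in sorted(h.keys()):
            g = h[name]
            out.append(
                EpochSet(
                    signals=g["signals"][...],
                    labels=g["labels"][...],
                    fs=float(g.attrs["fs"]),
                    channel_names=[str(c) for c in g.attrs["channel_names"]],
                    subject_id=str(g.attrs["subject_id"]),
                )
            )
    return out


def save_models(path, models: Sequence[MDRMModel]) -> None:
    with h5py.File(path, "w") as h:
        for i, m in enumerate(models):
            name = m.subject_id or f"model{i:02d}"
            g = h.create_group(name)
            g.create_dataset("prototype", data=m.prototype.values)
            g.create_dataset("mean_neg", data=m.mean_neg.values)
            g.create_dataset("mean_pos", data=m.mean_pos.values)
            g.attrs["fs"] = m.fs
            g.attrs["channel_names"] = list(m.channels)
            g.attrs["subject_id"] = name


def load_models(path) -> List[MDRMModel]:
    out = []
    with h5py.File(path, "r") as h:
        for name in sorted(h.keys()):
            g = h[name]
            out.append(
                MDRMModel(
                    prototype=Prototype(g["prototype"][...]),
                    mean_neg=SymmetricPositiveDefinite(g["mean_neg"][...]),
                    mean_pos=SymmetricPositiveDefinite(g["mean_pos"][...]),
                    channels=[str(c) for c in g.attrs["channel_names"]],
                    fs=float(g.attrs["fs"]),
                    subject_id=str(g.attrs["subject_id"]),
                )
            )
    return out


def prediction_matrix_to_csv(f: PredictionMatrix, path) -> None:
    df = pd.DataFrame(
        f.values, index=list(f.classifier_ids), columns=list(f.trial_ids)
    )
    df.index.name = "classifier_id"
    df.to_csv(path)


def prediction_matrix_from_csv(path) -> PredictionMatrix:
    df = pd.read_csv(path, index_col=0)
    return PredictionMatrix(
        values=df.to_numpy(dtype=np.int8),
        classifier_ids=list(df.index),
        trial_ids=list(df.columns),
    )


def combiner_to_csv(c: LinearCombiner, classifier_ids: Sequence[str], path) -> None:
    pd.DataFrame(
        {"classifier_id": list(classifier_ids), "weight": c.weights}
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
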