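"""Quick-look figures (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_weight_trajectories(state, ax=None, top_k: int | None = None):
    """Per-trial ensemble-weight curves from a streaming session."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    weights = [w for w in state.weight_log]
    m = state.n_models
    trials = np.arange(1, len(weights) + 1)
    traj = np.full((len(weights), m), np.nan)
    for t, w in enumerate(weights):
        if w is not None:
            traj[t] = w
    ids = [mod.subject_id or f"clf{i}" for i, mod in enumerate(state.models)]
    order = range(m)
    if top_k is not None:
        final = np.nan_to_num(traj[-1], nan=-np.inf)
        order = np.argsort(final)[::-1][:top_k]
    for i in order:
        ax.plot(trials, traj[:, i], label=ids[i], lw=1)
    ax.set_xlabel("trial")
    ax.set_ylabel("spectral weight")
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def plot_weight_vs_transfer(diag, ax=None):
    """Scatter of spectral weight against true direct-transfer accuracy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    t = diag.table
    ax.scatter(t["weight"], t["transfer_balanced_accuracy"], s=18)
    ax.set_xlabel("spectral weight")
    ax.set_ylabel("direct-transfer balanced accuracy")
    if np.isfinite(diag.correlation):
        ax.set_title(f"Pearson r = {diag.correlation:.3f}")
    return ax
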