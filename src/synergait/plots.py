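"""Minimal figure helpers: synergy weightings/activations and divergence
curves. Figures are returned, not shown, so callers control the backend."""

from __future__ import annotations

import numpy as np

from .synergy import SynergyModel
from .stability import StabilityResult


def plot_synergies(model: SynergyModel, samples_per_stride: int = 100):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    k = model.k
    fig, axes = plt.subplots(k, 2, figsize=(9, 2.0 * k), squeeze=False)
    x = np.arange(model.W.shape[0])
    mean_profiles = model.activation_strides(samples_per_stride).mean(axis=1)
    for j in range(k):
        axes[j][0].bar(x, model.W[:, j])
        axes[j][0].set_xticks(x)
        axes[j][0].set_xticklabels(model.muscles or x, rotation=90, fontsize=6)
        axes[j][0].set_ylabel(f"synergy {j + 1}")
        axes[j][1].plot(np.linspace(0, 100, samples_per_stride,
                                    endpoint=False), mean_profiles[j])
        axes[j][1].set_xlabel("% gait cycle")
    fig.suptitle(f"VAF = {model.vaf:.3f}")
    fig.tight_layout()
    return fig


def plot_divergence(result: StabilityResult):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.divergence, lw=1.2)
    w = min(result.fit_window, result.divergence.size)
    xs = np.arange(w)
    coef = np.polyfit(xs, result.divergence[:w], 1)
    ax.plot(xs, np.polyval(coef, xs), "r--",
            label=f"LDE = {result.lde:.3f} ln/stride")
    ax.set_xlabel("offset (samples)")
    ax.set_ylabel("mean ln divergence")
    ax.legend()
    fig.tight_layout()
    return fig
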