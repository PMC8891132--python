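"""Trace and posterior-density plots for MCMC runs."""

from __future__ import annotations

import numpy as np

from .mcmc import PosteriorDraws


def plot_trace(draws: PosteriorDraws, parameters=None, axes=None):
    """Per-chain trace plots, one panel per parameter."""
    import matplotlib.pyplot as plt

    names = list(parameters) if parameters is not None else draws.param_names
    if axes is None:
        _, axes = plt.subplots(len(names), 1, figsize=(8, 2.2 * len(names)), squeeze=False)
        axes = axes[:, 0]
    for ax, name in zip(axes, names):
        idx = draws.index(name)
        for c in range(draws.n_chains):
            ax.plot(draws.draws[c, :, idx], lw=0.3, alpha=0.8)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("stored iteration")
    return axes


def plot_posterior(draws: PosteriorDraws, parameter: str, transform=None, ax=None, bins=80):
    """Histogram of one parameter's pooled posterior draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    values = draws.stacked(parameter)
    if transform == "exp":
        values = np.exp(values)
        parameter = f"exp({parameter})"
    elif callable(transform):
        values = transform(values)
    ax.hist(values, bins=bins, density=True, alpha=0.8)
    ax.set_xlabel(parameter)
    ax.set_ylabel("posterior density")
    return ax
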