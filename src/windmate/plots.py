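"""Report figures: fitness gain curves by size and inbreeding scenario."""

from __future__ import annotations

import numpy as np

from .selection import SelectionFit, SizeLevels

__all__ = ["plot_fitness_curves"]


def plot_fitness_curves(
    fits: dict[str, SelectionFit],
    size_levels: SizeLevels,
    deltas=(0.0, 1.0),
    path=None,
):
    """Predicted relative fitness vs gender for each component and size level.

    Curves are drawn from the fitted gender polynomial at each size level
    and delta scenario (other covariates at their pooled baseline), the
    shape comparison the gradient table summarizes. Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = np.linspace(0, 1, 101)
    levels = size_levels.as_dict()
    fig, axes = plt.subplots(
        len(fits), len(levels), figsize=(3.2 * len(levels), 2.8 * len(fits)), squeeze=False
    )
    for i, (component, fit) in enumerate(fits.items()):
        for j, (name, s) in enumerate(levels.items()):
            ax = axes[i][j]
            for d in deltas:
                lin, _ = fit.gradient("linear", s, d)
                quad, _ = fit.gradient("quad", s, d)
                # curve shape about the population-mean gender of 0.5;
                # vertical placement is arbitrary for a shape plot
                y = lin * (g - 0.5) + quad * (g**2 - 0.25) + 1.0
                ax.plot(g, y, label=f"$\\delta$={d:g}")
            ax.set_title(f"{component}, {name}")
            if i == len(fits) - 1:
                ax.set_xlabel("gender (maleness)")
            if j == 0:
                ax.set_ylabel("relative fitness")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
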