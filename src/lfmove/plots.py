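"""Figure helpers: null-count histograms, RSS forest plots, context estimates."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["context_plot", "forest_plot", "null_histograms"]


def null_histograms(results, path=None):
    """Histogram grid of null feature counts with the observed count marked."""
    sexes = sorted({r.sex for r in results})
    features = sorted({r.feature for r in results})
    fig, axes = plt.subplots(
        len(features), len(sexes), figsize=(4 * len(sexes), 2.6 * len(features)), squeeze=False
    )
    by_key = {(r.feature, r.sex): r for r in results}
    for i, feature in enumerate(features):
        for j, sex in enumerate(sexes):
            ax = axes[i][j]
            r = by_key.get((feature, sex))
            if r is None:
                ax.set_visible(False)
                continue
            ax.hist(r.null_counts, bins=30, color="0.6")
            ax.axvline(r.observed, color="black", lw=2)
            ax.set_title(f"{sex} {feature}  P={r.p_i:.3f}", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def forest_plot(fits, path=None):
    """Log-RSS point-and-interval plot per sex (one panel per fit)."""
    fits = list(fits)
    fig, axes = plt.subplots(1, len(fits), figsize=(4.2 * len(fits), 3.2), squeeze=False)
    for ax, fit in zip(axes[0], fits):
        names = list(fit.covariates)
        ys = np.arange(len(names))[::-1]
        for y, name in zip(ys, names):
            ax.plot([fit.ci_lower[name], fit.ci_upper[name]], [y, y], color="black")
            ax.plot(fit.beta[name], y, "ko")
        ax.axvline(0.0, ls="--", color="0.5")
        ax.set_yticks(ys)
        ax.set_yticklabels(names, fontsize=8)
        ax.set_xlabel("log RSS")
        ax.set_title(fit.sex or "")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def context_plot(fits: dict, path=None):
    """Movement probability inside vs. outside each habitat, with intervals."""
    fig, axes = plt.subplots(1, len(fits), figsize=(3.6 * len(fits), 3.2), squeeze=False)
    for ax, (label, fit) in zip(axes[0], fits.items()):
        for x, (est, lo, hi), name in ((0, fit.p_out, "outside"), (1, fit.p_in, "inside")):
            ax.plot([x, x], [lo, hi], color="black")
            ax.plot(x, est, "ko")
        ax.set_xticks([0, 1])
        ax.set_xticklabels(["outside", "inside"])
        ax.set_ylim(0, 1)
        ax.set_ylabel("P(move)")
        ax.set_title(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
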