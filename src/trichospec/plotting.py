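"""Minimal matplotlib views: score scatter with the Hotelling ellipse, and
the contribution bar plot with flagged variables highlighted."""

from __future__ import annotations

import numpy as np

from .diagnostics import ContributionProfile, EllipseSpec


def score_plot(scores: np.ndarray, labels, ellipse: EllipseSpec | None = None,
               path=None, axis_names=("t[1]", "to[1]")):
    """2-D score scatter colored by class, with the T-squared ellipse."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = list(labels)
    for lab in dict.fromkeys(labels):
        mask = np.array([l == lab for l in labels])
        ax.scatter(scores[mask, 0], scores[mask, 1], s=14, label=str(lab))
    if ellipse is not None:
        theta = np.linspace(0, 2 * np.pi, 400)
        ax.plot(ellipse.half_axis_lengths[0] * np.cos(theta),
                ellipse.half_axis_lengths[1] * np.sin(theta),
                "k--", lw=1, label=f"Hotelling T² ({100 * (1 - ellipse.alpha):.0f}%)")
    ax.set_xlabel(axis_names[0])
    ax.set_ylabel(axis_names[1])
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def contribution_plot(grid: np.ndarray, profile: ContributionProfile,
                      path=None):
    """Per-wavenumber contribution bars; flagged variables (outside the
    +/-3 SD limits) in orange."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    colors = np.where(profile.flagged, "orange", "steelblue")
    ax.bar(grid, profile.bars, width=np.median(np.diff(grid)), color=colors)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("contribution (1/$\\sqrt{SD}$ units)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
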