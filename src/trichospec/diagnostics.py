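"""Model diagnostics: Hotelling's T-squared ellipse for score plots,
group contribution profiles, and variable importance in projection (VIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .opls import OplsModel, pareto_apply

__all__ = ["EllipseSpec", "ContributionProfile", "hotelling_limit",
           "contribution", "vip"]


@dataclass
class EllipseSpec:
    """Hotelling's T-squared acceptance region on a set of score axes.

    ``half_axis_lengths[j] = sd_j * sqrt(T2_crit)``; a point is inside when
    sum_j (t_j / sd_j)^2 <= T2_crit.  With two axes this is the familiar
    95% confidence ellipse drawn on score scatter plots.
    """

    axes: tuple
    half_axis_lengths: np.ndarray
    alpha: float
    t2_crit: float
    sds: np.ndarray

    def contains(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        z = scores / self.sds
        return (z ** 2).sum(axis=1) <= self.t2_crit


def hotelling_limit(scores: np.ndarray, alpha: float = 0.05,
                    axes: tuple | None = None) -> EllipseSpec:
    """Hotelling T-squared limit for m score axes at confidence 1 - alpha.

    T2_crit = m (n-1)(n+1) / (n (n-m)) * F_{1-alpha}(m, n-m); for the usual
    two-axis score plot this is 2(n-1)(n+1)/(n(n-2)) * F(2, n-2).  Scores
    are assumed centered (as PLS/OPLS scores are); per-axis standard
    deviations set the ellipse orientation along the score axes.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, m = scores.shape
    if axes is None:
        axes = tuple(range(m))
    if n <= m:
        raise ValueError(f"need more than {m} observations, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    f_crit = stats.f.ppf(1.0 - alpha, m, n - m)
    t2_crit = m * (n - 1) * (n + 1) / (n * (n - m)) * f_crit
    sds = scores.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance score axis")
    return EllipseSpec(axes=tuple(axes), half_axis_lengths=sds * np.sqrt(t2_crit),
                       alpha=alpha, t2_crit=float(t2_crit), sds=sds)


@dataclass
class ContributionProfile:
    """Per-variable explanation of why a group of observations deviates
    from a reference (the model average, or another group) in scaled X
    space.  ``bars`` are in the scaling's 1/sqrt(sd) units; positive means
    the group exceeds the reference.  ``flagged`` marks variables whose
    scaled deviation exceeds three column standard deviations."""

    reference: str
    bars: np.ndarray
    flagged: np.ndarray
    scaled_difference: np.ndarray


def contribution(model: OplsModel, group: np.ndarray,
                 reference: np.ndarray | None = None) -> ContributionProfile:
    """Group-vs-reference contribution profile.

    Both groups are scaled and centered with the model's training scaler;
    the bar for variable j is the model weight times the difference of the
    scaled group means.  Model weights are the absolute predictive
    loadings averaged over components and normalized to a maximum of 1.
    With ``reference=None`` the reference is the model average, whose
    scaled-centered mean is the zero vector.  Variables are flagged where
    the scaled difference exceeds +/-3 column standard deviations of the
    scaled training data (global, not per class).
    """
    group = np.atleast_2d(np.asarray(group, dtype=float))
    if group.size == 0:
        raise ValueError("empty group")
    if model.scaler is None:
        raise ValueError("model has no scaler; fit with fit_oplsda")
    g_mean = pareto_apply(model.scaler, group).mean(axis=0)
    if reference is None:
        r_mean = np.zeros_like(g_mean)
        ref_name = "model_average"
    else:
        reference = np.atleast_2d(np.asarray(reference, dtype=float))
        if reference.size == 0:
            raise ValueError("empty reference group")
        r_mean = pareto_apply(model.scaler, reference).mean(axis=0)
        ref_name = "other_group"
    diff = g_mean - r_mean
    if model.P.shape[1] == 0:
        raise ValueError("model has no predictive components")
    weights = np.abs(model.P).mean(axis=1)
    wmax = weights.max()
    if wmax > 0:
        weights = weights / wmax
    # scaled training columns have sd = sqrt(original sd) under Pareto
    col_sd = np.sqrt(model.scaler.sds)
    with np.errstate(invalid="ignore"):
        flagged = np.abs(diff) > 3.0 * col_sd
    flagged &= col_sd > 0
    return ContributionProfile(reference=ref_name, bars=weights * diff,
                               flagged=flagged, scaled_difference=diff)


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( J * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a the Y sum of squares captured by component a; the mean of VIP^2
    over variables is exactly 1.
    """
    if model.W.shape[1] == 0:
        raise ValueError("model has no predictive components")
    J = model.W.shape[0]
    w_unit = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    ssy = np.einsum("ia,ia->a", model.T, model.T) * (model.C ** 2).sum(axis=0)
    if ssy.sum() == 0:
        ssy = np.ones_like(ssy)
    return np.sqrt(J * (w_unit ** 2 @ ssy) / ssy.sum())
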