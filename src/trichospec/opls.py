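"""Pareto scaling and OPLS-DA (orthogonal projections to latent
structures discriminant analysis) fitted by NIPALS.

OPLS-DA splits the predictor variation into a part correlated with class
membership (predictive components ``t``) and a part orthogonal to it
(``to``), which for spectra absorbs within-class intensity structure such
as residual baseline and trichome-to-trichome brightness.  Fitting follows
the classical two-stage recipe: each orthogonal component is derived from a
NIPALS PLS component by removing the part of its loading that lies along
the predictive weight, the component is deflated from X, and plain NIPALS
PLS is then run on the filtered matrix.

Variance bookkeeping (R2X per component, cumulative R2Y) is referred to the
sum of squares of the scaled, centered X; Q2 comes from stratified k-fold
cross-validation in which the scaler and model are refit on every training
split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParetoScaler",
    "DummyY",
    "OplsModel",
    "CvConfig",
    "CvResult",
    "AutofitResult",
    "pareto_fit",
    "pareto_apply",
    "build_dummy",
    "nipals_component",
    "fit_opls",
    "fit_oplsda",
    "predict",
    "cross_validate",
    "autofit",
]


# ---------------------------------------------------------------------------
# Pareto scaling

@dataclass
class ParetoScaler:
    """Column-wise Pareto scaling: subtract the mean, multiply by
    1/sqrt(sd).  Scaled columns have standard deviation sqrt(sd), a
    compromise between raw and unit-variance scaling that keeps large bands
    dominant without letting them swamp the model.  Constant columns get
    weight 0 (and are flagged)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    @property
    def constant_columns(self) -> np.ndarray:
        return np.flatnonzero(self.weights == 0)


def pareto_fit(matrix: np.ndarray) -> ParetoScaler:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        weights = np.where(sds > 0, 1.0 / np.sqrt(sds), 0.0)
    n_const = int((sds == 0).sum())
    if n_const:
        logger.info("Pareto scaling: %d constant column(s) given weight 0", n_const)
    return ParetoScaler(means, sds, weights)


def pareto_apply(scaler: ParetoScaler, matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-1] != scaler.means.size:
        raise ValueError(
            f"matrix has {matrix.shape[-1]} variables, scaler expects {scaler.means.size}"
        )
    return (matrix - scaler.means) * scaler.weights


# ---------------------------------------------------------------------------
# Dummy response

@dataclass
class DummyY:
    """Class-indicator response: one column per class, 1 for the row's own
    class (each raw row sums to 1), then column mean-centered."""

    class_order: list
    matrix: np.ndarray     # centered indicators, n x k
    means: np.ndarray      # column means of the raw indicators


def build_dummy(labels: Sequence, class_order: Sequence | None = None) -> DummyY:
    labels = list(labels)
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    index = {c: i for i, c in enumerate(class_order)}
    unknown = [l for l in labels if l not in index]
    if unknown:
        raise ValueError(f"labels not in class_order: {sorted(set(map(str, unknown)))}")
    raw = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        raw[i, index[lab]] = 1.0
    means = raw.mean(axis=0)
    return DummyY(list(class_order), raw - means, means)


# ---------------------------------------------------------------------------
# NIPALS

def nipals_component(X: np.ndarray, Y: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 2000):
    """One NIPALS PLS2 component on centered X (n x p) and Y (n x k).

    Alternates w = X'u/(u'u) (normalized), t = Xw, c = Y't/(t't),
    u = Yc/(c'c) until the score vector t stabilizes.  Returns
    (w, t, p, c) with p = X't/(t't).  With a single Y column the loop
    converges in one pass (w is the normalized X'y direction).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not u.any():
        raise ValueError("Y has no variance; cannot extract a component")
    t_old = None
    for it in range(1, max_iter + 1):
        w = X.T @ u / (u @ u)
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            raise ValueError("X'u vanished: X has no covariance with Y")
        w /= w_norm
        t = X @ w
        tt = t @ t
        if tt == 0:
            raise ValueError("zero score vector: X is rank-deficient here")
        c = Y.T @ t / tt
        u = Y @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
            break
        t_old = t
    else:
        raise RuntimeError(f"NIPALS did not converge in {max_iter} iterations")
    p = X.T @ t / tt
    return w, t, p, c


# ---------------------------------------------------------------------------
# OPLS model

@dataclass
class OplsModel:
    """Fitted OPLS-DA decomposition.

    W/P/T/C hold the predictive weights, loadings, scores and Y-loadings
    (columns = components); Wo/Po/To the orthogonal ones.  ``r2x_pred`` and
    ``r2x_orth`` give each component's fraction of the initial (scaled,
    centered) X sum of squares; ``r2y_cum`` the fraction of Y sum of
    squares captured; ``q2_cum`` is filled in by cross-validation.
    """

    n_pred: int
    n_orth: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    C: np.ndarray
    Wo: np.ndarray
    Po: np.ndarray
    To: np.ndarray
    r2x_pred: np.ndarray
    r2x_orth: np.ndarray
    r2y_cum: float
    class_order: list = field(default_factory=list)
    scaler: ParetoScaler | None = None
    y_means: np.ndarray | None = None
    q2_cum: float | None = None

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x_pred.sum() + self.r2x_orth.sum())

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a).tolist()
        payload = {
            "n_pred": self.n_pred, "n_orth": self.n_orth,
            "W": arr(self.W), "P": arr(self.P), "T": arr(self.T), "C": arr(self.C),
            "Wo": arr(self.Wo), "Po": arr(self.Po), "To": arr(self.To),
            "r2x_pred": arr(self.r2x_pred), "r2x_orth": arr(self.r2x_orth),
            "r2y_cum": self.r2y_cum, "q2_cum": self.q2_cum,
            "class_order": list(self.class_order),
            "scaler": None if self.scaler is None else {
                "means": arr(self.scaler.means), "sds": arr(self.scaler.sds),
                "weights": arr(self.scaler.weights)},
            "y_means": None if self.y_means is None else arr(self.y_means),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "OplsModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        scaler = None
        if d["scaler"] is not None:
            scaler = ParetoScaler(*(np.array(d["scaler"][k]) for k in ("means", "sds", "weights")))
        return cls(
            n_pred=d["n_pred"], n_orth=d["n_orth"],
            W=np.array(d["W"]), P=np.array(d["P"]), T=np.array(d["T"]), C=np.array(d["C"]),
            Wo=np.array(d["Wo"]), Po=np.array(d["Po"]), To=np.array(d["To"]),
            r2x_pred=np.array(d["r2x_pred"]), r2x_orth=np.array(d["r2x_orth"]),
            r2y_cum=d["r2y_cum"], class_order=d["class_order"], scaler=scaler,
            y_means=None if d["y_means"] is None else np.array(d["y_means"]),
            q2_cum=d["q2_cum"],
        )


def fit_opls(X: np.ndarray, Y: np.ndarray, n_pred: int = 1, n_orth: int = 1,
             class_order: Sequence | None = None,
             scaler: ParetoScaler | None = None,
             y_means: np.ndarray | None = None) -> OplsModel:
    """Fit OPLS on already scaled/centered X and centered Y.

    Each orthogonal round extracts a NIPALS component and strips from its
    loading p the part lying in the Y-covariance subspace: with B an
    orthonormal basis of span(X'Y), w_o = p - B B'p (normalized), then
    t_o = X w_o, p_o = X't_o/(t_o't_o) and X is deflated.  For a
    single-column (or two-class, rank-one) response this is the familiar
    w_o = p - (w'p/w'w) w; projecting against the full subspace is the
    multi-response generalization and keeps the orthogonal filter from
    removing variation predictive of classes beyond the first weight.
    The predictive components are then ordinary NIPALS PLS2 components of
    the filtered X (with X and Y deflation).  R2X fractions are taken
    against the initial X sum of squares.  Raises when the requested
    components exceed the rank of X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p_vars = X.shape
    ss_x = float((X ** 2).sum())
    if ss_x == 0:
        raise ValueError("X has zero sum of squares")
    ss_y = float((Y ** 2).sum())
    Xd = X.copy()

    def _rank_guard(stage):
        if float((Xd ** 2).sum()) <= 1e-12 * ss_x:
            raise ValueError(
                f"requested components exceed the rank of X (at {stage})"
            )

    Wo, To, Po, r2x_orth = [], [], [], []
    for j in range(n_orth):
        _rank_guard(f"orthogonal component {j + 1}")
        w, t, p, c = nipals_component(Xd, Y)
        cov = Xd.T @ Y
        u_basis, sv, _ = np.linalg.svd(cov, full_matrices=False)
        basis = u_basis[:, sv > 1e-10 * sv[0]] if sv.size else u_basis[:, :0]
        wo = p - basis @ (basis.T @ p)
        wo_norm = np.linalg.norm(wo)
        if wo_norm <= 1e-12 * np.linalg.norm(p):
            raise ValueError(
                f"no orthogonal variation left at orthogonal component {j + 1}"
            )
        wo /= wo_norm
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        Wo.append(wo); To.append(to); Po.append(po)
        r2x_orth.append((to @ to) * (po @ po) / ss_x)

    W, T, P, C, r2x_pred, r2y = [], [], [], [], [], 0.0
    Yd = Y.copy()
    for a in range(n_pred):
        _rank_guard(f"predictive component {a + 1}")
        w, t, p, c = nipals_component(Xd, Yd)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        W.append(w); T.append(t); P.append(p); C.append(c)
        r2x_pred.append((t @ t) * (p @ p) / ss_x)
        r2y += (t @ t) * (c @ c) / ss_y if ss_y else 0.0

    def cols(vs, nrow):
        return np.column_stack(vs) if vs else np.empty((nrow, 0))

    return OplsModel(
        n_pred=n_pred, n_orth=n_orth,
        W=cols(W, p_vars), P=cols(P, p_vars), T=cols(T, n), C=cols(C, Y.shape[1]),
        Wo=cols(Wo, p_vars), Po=cols(Po, p_vars), To=cols(To, n),
        r2x_pred=np.array(r2x_pred), r2x_orth=np.array(r2x_orth),
        r2y_cum=float(r2y),
        class_order=list(class_order) if class_order is not None else [],
        scaler=scaler, y_means=y_means,
    )


def fit_oplsda(X_raw: np.ndarray, labels: Sequence, n_pred: int = 1,
               n_orth: int = 1, class_order: Sequence | None = None) -> OplsModel:
    """Convenience wrapper on raw intensities: fit the Pareto scaler, build
    the centered dummy response, and fit OPLS."""
    scaler = pareto_fit(X_raw)
    dummy = build_dummy(labels, class_order)
    return fit_opls(pareto_apply(scaler, X_raw), dummy.matrix,
                    n_pred=n_pred, n_orth=n_orth,
                    class_order=dummy.class_order, scaler=scaler,
                    y_means=dummy.means)


def predict(model: OplsModel, X_new: np.ndarray, scaled: bool = False):
    """Predict new observations.

    Applies the training scaler (unless ``scaled``), sequentially removes
    the orthogonal components with Wo/Po, projects the filtered matrix onto
    the predictive components for scores, and forms Y_hat = T_new C' plus
    the class-mean offsets.  The predicted class is the argmax over Y_hat
    columns (ties resolve to the lowest class index).

    Returns ``(scores_pred, scores_orth, Y_hat, class_labels)``.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p_vars = model.W.shape[0]
    if X_new.shape[1] != p_vars:
        raise ValueError(
            f"X_new has {X_new.shape[1]} variables, model expects {p_vars}"
        )
    Xf = X_new if scaled or model.scaler is None else pareto_apply(model.scaler, X_new)
    Xf = Xf.copy()
    to_new = np.empty((Xf.shape[0], model.n_orth))
    for j in range(model.n_orth):
        t_o = Xf @ model.Wo[:, j]
        Xf -= np.outer(t_o, model.Po[:, j])
        to_new[:, j] = t_o
    t_new = np.empty((Xf.shape[0], model.n_pred))
    for a in range(model.n_pred):
        t = Xf @ model.W[:, a]
        Xf -= np.outer(t, model.P[:, a])
        t_new[:, a] = t
    y_hat = t_new @ model.C.T
    if model.y_means is not None:
        y_hat = y_hat + model.y_means
    idx = np.argmax(y_hat, axis=1)
    if model.class_order:
        labels = [model.class_order[i] for i in idx]
    else:
        labels = list(idx)
    return t_new, to_new, y_hat, labels


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CvConfig:
    """k-fold cross-validation settings.  ``k = n`` reproduces
    leave-one-out; folds are stratified by class by default and assigned
    deterministically from ``seed``.  ``max_components`` caps
    n_pred + n_orth during autofit (fewer than five latent variables)."""

    k: int = 7
    stratified: bool = True
    seed: int = 0
    max_components: int = 4


@dataclass
class CvResult:
    q2: float
    predictions: list            # held-out class prediction per row
    folds: np.ndarray            # fold id per row
    press: float
    ss_y: float


def _fold_assignment(labels: Sequence, cv: CvConfig) -> np.ndarray:
    n = len(labels)
    k = min(cv.k, n)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(cv.seed)
    folds = np.empty(n, dtype=int)
    if k >= n:
        folds[:] = np.arange(n)       # leave-one-out
        return folds
    if cv.stratified:
        arr = np.asarray(labels, dtype=object)
        counts = {}
        for lab in dict.fromkeys(labels):
            idx = np.flatnonzero(arr == lab)
            if idx.size < 2:
                raise ValueError(f"class {lab!r} has fewer than 2 members")
            counts[lab] = idx
        offset = 0
        for lab, idx in counts.items():
            perm = rng.permutation(idx)
            folds[perm] = (np.arange(idx.size) + offset) % k
            offset += idx.size        # stagger so small classes spread evenly
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
    return folds


def cross_validate(X_raw: np.ndarray, labels: Sequence, n_pred: int,
                   n_orth: int, cv: CvConfig | None = None,
                   class_order: Sequence | None = None) -> CvResult:
    """Q2 and held-out predictions by k-fold cross-validation.

    Scaler and model are refit on each training split only; PRESS and the
    response sum of squares accumulate over held-out rows (dummy responses
    centered with the training-split class means), giving
    Q2 = 1 - PRESS/SS(Y).
    """
    cv = cv or CvConfig()
    X_raw = np.asarray(X_raw, dtype=float)
    labels = list(labels)
    n = len(labels)
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    folds = _fold_assignment(labels, cv)
    press = ss_y = 0.0
    predictions: list = [None] * n
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        train_labels = [labels[i] for i in np.flatnonzero(train)]
        scaler = pareto_fit(X_raw[train])
        dummy = build_dummy(train_labels, class_order)
        model = fit_opls(pareto_apply(scaler, X_raw[train]), dummy.matrix,
                         n_pred=n_pred, n_orth=n_orth,
                         class_order=dummy.class_order, scaler=scaler,
                         y_means=dummy.means)
        _, _, y_hat, pred = predict(model, X_raw[test])
        test_dummy = np.zeros((int(test.sum()), len(class_order)))
        for r, i in enumerate(np.flatnonzero(test)):
            test_dummy[r, class_order.index(labels[i])] = 1.0
            predictions[i] = pred[r]
        press += float(((test_dummy - y_hat) ** 2).sum())
        ss_y += float(((test_dummy - dummy.means) ** 2).sum())
    q2 = 1.0 - press / ss_y if ss_y else float("nan")
    return CvResult(q2=q2, predictions=predictions, folds=folds,
                    press=press, ss_y=ss_y)


@dataclass
class AutofitResult:
    n_pred: int
    n_orth: int
    q2: float

    def __iter__(self):
        return iter((self.n_pred, self.n_orth))


def autofit(X_raw: np.ndarray, labels: Sequence, cv: CvConfig | None = None,
            class_order: Sequence | None = None,
            q2_threshold: float = 0.01) -> AutofitResult:
    """Choose component counts by greedy cross-validated search.

    Starting from one predictive component, repeatedly evaluates adding one
    predictive or one orthogonal component and accepts the better move only
    if it improves Q2 by more than ``q2_threshold`` (0.01, the usual
    autofit rule), keeping n_pred + n_orth <= ``max_components``.
    """
    cv = cv or CvConfig()

    def q2_of(np_, no_):
        try:
            return cross_validate(X_raw, labels, np_, no_, cv, class_order).q2
        except (ValueError, RuntimeError):
            return -np.inf

    n_pred, n_orth = 1, 0
    q2 = q2_of(n_pred, n_orth)
    while n_pred + n_orth < cv.max_components:
        moves = [(n_pred + 1, n_orth), (n_pred, n_orth + 1)]
        scored = [(q2_of(a, b), a, b) for a, b in moves]
        best_q2, best_a, best_b = max(scored)
        if best_q2 > q2 + q2_threshold:
            n_pred, n_orth, q2 = best_a, best_b, best_q2
        else:
            break
    return AutofitResult(n_pred=n_pred, n_orth=n_orth, q2=float(q2))
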