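"""Classifier evaluation: confusion matrices and Fisher's exact
probability of the actual-by-predicted table.

The Fisher probability of an r x c table is the total probability, under
the multiple hypergeometric distribution with the observed margins fixed,
of all tables at most as probable as the observed one (Freeman-Halton
generalization of Fisher's exact test; for 2 x 2 it reduces to the
classical two-sided test).  Small problems are solved by exact recursive
enumeration; when the enumeration would exceed a configurable cap the
probability is estimated by Monte Carlo over margin-preserving tables
(Patefield sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["ConfusionMatrix", "confusion", "fisher_2x2", "fisher_rxc"]

#: relative tolerance when comparing table probabilities for "at most as
#: probable as observed" (guards against floating-point ties)
_REL_TOL = 1e-9


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted count table (rows = actual classes)."""

    class_order: list
    counts: np.ndarray
    fisher_p: float | None = None
    notes: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("accuracy defined only for square tables")
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")

    def to_text(self) -> str:
        """Render the table as rows = actual, columns = predicted, with
        margins and the Fisher probability."""
        names = [str(c) for c in self.class_order]
        width = max(len(n) for n in names + ["Actual", "Sum"]) + 2
        lines = ["".join(s.rjust(width) for s in ["Actual \\ Predicted"] + names + ["Sum"])]
        for i, name in enumerate(names):
            cells = [str(int(v)) for v in self.counts[i]] + [str(int(self.row_sums[i]))]
            lines.append("".join(s.rjust(width) for s in [name] + cells))
        cells = [str(int(v)) for v in self.col_sums] + [str(self.total)]
        lines.append("".join(s.rjust(width) for s in ["Sum"] + cells))
        lines.append(f"Accuracy: {100 * self.accuracy:.1f}%")
        if self.fisher_p is not None:
            lines.append(f"Fisher's probability: {self.fisher_p:.2f} ({self.fisher_p:.3e})")
        for note in self.notes:
            lines.append(f"Note: {note}")
        return "\n".join(lines)


def confusion(actual: Sequence, predicted: Sequence,
              class_order: Sequence | None = None) -> ConfusionMatrix:
    """Count actual-by-predicted pairs into a confusion matrix."""
    actual, predicted = list(actual), list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted differ in length")
    if class_order is None:
        class_order = list(dict.fromkeys(list(actual) + list(predicted)))
    index = {c: i for i, c in enumerate(class_order)}
    unknown = [l for l in set(actual) | set(predicted) if l not in index]
    if unknown:
        raise ValueError(f"labels not in class_order: {sorted(map(str, unknown))}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(list(class_order), counts)


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    """log multiple-hypergeometric probability of a table with its margins."""
    return log_margin_const - sum(lgamma(v + 1) for v in table.flat)


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _log_margin_const(row_sums, col_sums, total) -> float:
    return (
        sum(lgamma(r + 1) for r in row_sums)
        + sum(lgamma(c + 1) for c in col_sums)
        - lgamma(total + 1)
    )


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact probability of a 2 x 2 table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those at most as probable as the
    observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_2x2 expects a 2x2 table")
    if np.any(table < 0):
        raise ValueError("negative cells")
    r1, r2 = table.sum(axis=1)
    c1, _ = table.sum(axis=0)
    n = table.sum()
    if n == 0:
        return 1.0
    dist = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(table[0, 0])
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_TOL)].sum()))


def _enumerate_p(table: np.ndarray, cap: int) -> float | None:
    """Exact Freeman-Halton p by recursive enumeration of all tables with
    the observed margins; returns None if more than ``cap`` tables would be
    visited."""
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    total = int(table.sum())
    if total == 0:
        return 1.0
    const = _log_margin_const(row_sums, col_sums, total)
    logp_obs = _log_table_prob(table, const)
    r, c = table.shape
    visited = 0
    acc = 0.0
    work = np.zeros((r, c), dtype=int)

    def rec(i, j, rows_left, cols_left, log_acc):
        nonlocal visited, acc
        if visited > cap:
            raise OverflowError
        if i == r - 1:
            # last row forced by column margins
            last = cols_left.copy()
            if np.any(last < 0) or last.sum() != rows_left[i]:
                return
            visited += 1
            logp = log_acc - sum(lgamma(v + 1) for v in last)
            if logp <= logp_obs + _REL_TOL * abs(logp_obs) + 1e-12:
                acc += np.exp(logp)
            return
        if j == c - 1:
            v = rows_left[i]
            if v < 0 or v > cols_left[j]:
                return
            cols_left[j] -= v
            rows_left_i = rows_left[i]
            rows_left[i] = 0
            rec(i + 1, 0, rows_left, cols_left, log_acc - lgamma(v + 1))
            rows_left[i] = rows_left_i
            cols_left[j] += v
            return
        hi = min(rows_left[i], cols_left[j])
        for v in range(hi + 1):
            rows_left[i] -= v
            cols_left[j] -= v
            rec(i, j + 1, rows_left, cols_left, log_acc - lgamma(v + 1))
            rows_left[i] += v
            cols_left[j] += v

    try:
        rec(0, 0, row_sums.astype(int).copy(), col_sums.astype(int).copy(), const)
    except OverflowError:
        return None
    return float(min(1.0, acc))


def fisher_rxc(table, method: str = "auto", n_mc: int = 1_000_000,
               seed: int = 0, max_tables: int = 10_000_000) -> float:
    """Fisher/Freeman-Halton exact probability of an r x c table.

    ``method`` is ``"exact"``, ``"mc"`` or ``"auto"`` (exact enumeration
    when at most ``max_tables`` tables fit the margins, Monte Carlo with
    ``n_mc`` Patefield-sampled margin-preserving tables otherwise).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2:
        raise ValueError("expected a 2-D table")
    if np.any(table < 0):
        raise ValueError("negative cells")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    total = int(table.sum())
    if total == 0 or min(table.shape) == 1:
        return 1.0  # margins admit exactly one table
    if method not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "exact"):
        # upper bound on the table count: every column sum composed into r
        # parts (and the transposed bound); enumerate only when tractable
        r, c = table.shape
        log_bound = min(
            sum(_log_comb(cs + r - 1, r - 1) for cs in col_sums),
            sum(_log_comb(rs + c - 1, c - 1) for rs in row_sums),
        )
        if method == "exact" or log_bound <= np.log(max_tables):
            p = _enumerate_p(table, max_tables if method == "auto" else 10 ** 12)
            if p is not None:
                return p
            if method == "exact":
                raise ValueError("exact enumeration exceeded the table cap")
    # Monte Carlo over tables with the observed margins: permuting the
    # row labels of the N observations against fixed column blocks samples
    # exactly from the multiple hypergeometric null.
    rng = np.random.default_rng(seed)
    const = _log_margin_const(row_sums, col_sums, total)
    logp_obs = _log_table_prob(table, const)
    r, c = table.shape
    row_labels = np.repeat(np.arange(r, dtype=np.int16), row_sums)
    col_of = np.repeat(np.arange(c), col_sums)      # column block per slot
    codes_offset = col_of * r                       # encode (row, col) pairs
    hits = 0
    done = 0
    batch = max(1, min(100_000, int(2e7 // max(total, 1))))
    while done < n_mc:
        m = min(batch, n_mc - done)
        mat = np.broadcast_to(row_labels, (m, total)).copy()
        rng.permuted(mat, axis=1, out=mat)
        codes = mat + codes_offset
        codes += (np.arange(m, dtype=np.int64) * (r * c))[:, None]
        counts = np.bincount(codes.ravel(), minlength=m * r * c).reshape(m, r * c)
        logp = const - gammaln(counts + 1.0).sum(axis=1)
        hits += int((logp <= logp_obs + _REL_TOL * abs(logp_obs) + 1e-12).sum())
        done += m
    return hits / n_mc
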