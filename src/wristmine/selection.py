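"""Correlation-based feature-subset selection (CFS), from scratch.

Numeric features are first discretized with the supervised entropy/MDL
recursion (recursive binary splits accepted only when the information gain
beats the minimum-description-length criterion). Feature-class and
feature-feature association is measured by symmetric uncertainty
``SU = 2 I(x;y) / (H(x) + H(y))`` on the discretized codes, and subsets are
scored by the CFS merit

    merit(S) = k * mean_SU(feature, class) / sqrt(k + k (k-1) * mean_SU(feature, feature))

searched with forward best-first expansion that stops after five consecutive
non-improving expansions. The whole stack is deterministic: ties break on
input column order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Best-first search stops after this many consecutive non-improving
#: node expansions.
SEARCH_TERMINATION = 5


@dataclass
class SelectionResult:
    """Outcome of a CFS run: the chosen subset and the search trace."""

    selected_feature_names: list[str]
    merit: float
    search_trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_entropy(codes: np.ndarray) -> float:
    return _entropy_from_counts(np.bincount(codes))


def discretize_mdl(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Supervised entropy-based discretization with the MDL stop rule.

    Returns the sorted cut points (possibly empty). A candidate binary split
    is accepted iff its information gain exceeds
    ``(log2(N-1) + log2(3^c - 2) - (c H(S) - c1 H(S1) - c2 H(S2))) / N``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    _, y = np.unique(labels, return_inverse=True)
    n_classes_total = y.max() + 1

    order = np.argsort(values, kind="stable")
    v, yy = values[order], y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        seg_y = yy[lo:hi]
        n = hi - lo
        if n < 2:
            return
        counts = np.bincount(seg_y, minlength=n_classes_total)
        h_s = _entropy_from_counts(counts)
        if h_s == 0.0:
            return
        # Candidate cuts: midpoints between adjacent distinct values.
        seg_v = v[lo:hi]
        change = np.nonzero(np.diff(seg_v) > 0)[0]  # split after index i
        if change.size == 0:
            return
        # Cumulative class counts for vectorized split evaluation.
        onehot = np.zeros((n, n_classes_total))
        onehot[np.arange(n), seg_y] = 1.0
        cum = np.cumsum(onehot, axis=0)
        left = cum[change]
        right = counts[None, :] - left
        n_left = left.sum(axis=1)
        n_right = n - n_left

        def ent(rows: np.ndarray, totals: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = rows / totals[:, None]
                terms = np.where(p > 0, p * np.log2(p), 0.0)
            return -terms.sum(axis=1)

        weighted = (n_left * ent(left, n_left) + n_right * ent(right, n_right)) / n
        best = int(np.argmin(weighted))
        gain = h_s - weighted[best]

        c = int((counts > 0).sum())
        c1 = int((left[best] > 0).sum())
        c2 = int((right[best] > 0).sum())
        h1 = _entropy_from_counts(left[best].astype(int))
        h2 = _entropy_from_counts(right[best].astype(int))
        delta = np.log2(3.0**c - 2.0) - (c * h_s - c1 * h1 - c2 * h2)
        threshold = (np.log2(n - 1.0) + delta) / n
        if gain <= threshold:
            return
        split_at = change[best] + 1  # first index of the right part
        cuts.append(float((seg_v[split_at - 1] + seg_v[split_at]) / 2.0))
        recurse(lo, lo + split_at)
        recurse(lo + split_at, hi)

    recurse(0, values.size)
    return np.sort(np.asarray(cuts))


def apply_cuts(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Map numeric values to interval codes given sorted cut points."""
    return np.digitize(np.asarray(values, dtype=float), np.asarray(cuts))


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized mutual information of two discrete vectors, in [0, 1].

    Defined as 0 when either variable is constant (zero entropy).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("length mismatch between the two vectors")
    if x.size == 0:
        raise ValueError("empty input")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _entropy_from_counts(joint.ravel())
    mi = hx + hy - hxy
    return float(max(0.0, 2.0 * mi / (hx + hy)))


def cfs_merit(
    subset: Sequence[str],
    feature_class_su: Mapping[str, float],
    feature_feature_su: Mapping[frozenset, float],
) -> float:
    """CFS merit ``k r_cf / sqrt(k + k (k-1) r_ff)``; empty subset -> 0."""
    k = len(subset)
    if k == 0:
        return 0.0
    try:
        r_cf = float(np.mean([feature_class_su[f] for f in subset]))
    except KeyError as err:
        raise ValueError(f"missing feature-class correlation for {err.args[0]!r}") from err
    if k == 1:
        return r_cf
    pair_sum = 0.0
    n_pairs = 0
    for i, a in enumerate(subset):
        for b in subset[i + 1 :]:
            key = frozenset((a, b))
            if key not in feature_feature_su:
                raise ValueError(f"missing feature-feature correlation for {a!r}/{b!r}")
            pair_sum += feature_feature_su[key]
            n_pairs += 1
    r_ff = pair_sum / n_pairs
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def best_first_select(
    feature_table: pd.DataFrame,
    labels: Sequence,
    stop: int = SEARCH_TERMINATION,
) -> SelectionResult:
    """Forward best-first CFS over the columns of ``feature_table``.

    Numeric columns are MDL-discretized against the class before computing
    symmetric uncertainties; feature-feature correlations are computed
    lazily. Deterministic for a fixed input (ties broken by column order).
    """
    if feature_table.shape[1] < 2:
        raise ValueError("need at least two features to select from")
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("class vector is constant; selection is undefined")

    names = list(feature_table.columns)
    codes: dict[str, np.ndarray] = {}
    for name in names:
        col = feature_table[name].to_numpy()
        if np.issubdtype(col.dtype, np.number):
            codes[name] = apply_cuts(col, discretize_mdl(col, y))
        else:
            _, codes[name] = np.unique(col, return_inverse=True)

    f_c = {name: symmetric_uncertainty(codes[name], y) for name in names}
    f_f: dict[frozenset, float] = {}

    def pair_su(a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in f_f:
            f_f[key] = symmetric_uncertainty(codes[a], codes[b])
        return f_f[key]

    def merit_of(subset: tuple[str, ...]) -> float:
        for i, a in enumerate(subset):
            for b in subset[i + 1 :]:
                pair_su(a, b)
        return cfs_merit(subset, f_c, f_f)

    start: tuple[str, ...] = ()
    best_subset, best_merit = start, 0.0
    counter = 0
    open_heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, counter, start)]
    seen = {frozenset(start)}
    trace: list[tuple[tuple[str, ...], float]] = [(start, 0.0)]
    stall = 0
    while open_heap and stall < stop:
        _, _, node = heapq.heappop(open_heap)
        improved = False
        for name in names:
            if name in node:
                continue
            child = tuple(f for f in names if f in node or f == name)
            key = frozenset(child)
            if key in seen:
                continue
            seen.add(key)
            m = merit_of(child)
            trace.append((child, m))
            counter += 1
            heapq.heappush(open_heap, (-m, counter, child))
            if m > best_merit + 1e-10:
                best_subset, best_merit = child, m
                improved = True
        stall = 0 if improved else stall + 1
    return SelectionResult(
        selected_feature_names=list(best_subset),
        merit=best_merit,
        search_trace=trace,
    )
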