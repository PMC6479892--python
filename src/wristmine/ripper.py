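"""A compact RIPPER-style propositional rule learner.

Sequential covering in the RIPPER tradition: classes are handled from rarest
to most frequent, each learning an ordered list of conjunctive rules over
numeric threshold tests. Every rule is grown greedily by FOIL information
gain on a grow split and then pruned back on a held-out prune split
(maximizing ``(p - n) / (p + n)``); rule addition stops for a class when a
new rule's prune-set precision no longer beats the class prior. Prediction
fires the first matching rule; uncovered instances fall back to the majority
class. Deterministic given ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

MAX_CONDITIONS = 8
MAX_RULES_PER_CLASS = 16
N_THRESHOLD_CANDIDATES = 24


@dataclass(frozen=True)
class Condition:
    feature: int
    op: str  # "<=" or ">"
    threshold: float

    def holds(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.feature]
        return col <= self.threshold if self.op == "<=" else col > self.threshold


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    target: int

    def covers(self, X: np.ndarray) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for cond in self.conditions:
            mask &= cond.holds(X)
        return mask


def _foil_gain(p0: int, n0: int, p1: int, n1: int) -> float:
    if p1 == 0:
        return -np.inf
    before = np.log2(p0 / (p0 + n0)) if p0 > 0 else -np.inf
    after = np.log2(p1 / (p1 + n1))
    return p1 * (after - before)


class RipperClassifier(BaseEstimator, ClassifierMixin):
    """Ordered rule-list classifier in the RIPPER family."""

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def _grow_rule(
        self, X: np.ndarray, pos: np.ndarray, target: int
    ) -> tuple[Condition, ...]:
        conditions: list[Condition] = []
        covered = np.ones(len(X), dtype=bool)
        while len(conditions) < MAX_CONDITIONS:
            p0 = int((covered & pos).sum())
            n0 = int((covered & ~pos).sum())
            if p0 == 0 or n0 == 0:
                break
            best_gain, best_cond, best_mask = 0.0, None, None
            for j in range(X.shape[1]):
                col = X[covered, j]
                lo, hi = col.min(), col.max()
                if hi <= lo:
                    continue
                qs = np.quantile(col, np.linspace(0.0, 1.0, N_THRESHOLD_CANDIDATES))
                for thr in np.unique(qs):
                    below = X[:, j] <= thr
                    for op, mask in (("<=", below), (">", ~below)):
                        m = covered & mask
                        gain = _foil_gain(
                            p0, n0, int((m & pos).sum()), int((m & ~pos).sum())
                        )
                        if gain > best_gain + 1e-12:
                            best_gain = gain
                            best_cond = Condition(j, op, float(thr))
                            best_mask = m
            if best_cond is None:
                break
            conditions.append(best_cond)
            covered = best_mask
        return tuple(conditions)

    def _prune_rule(
        self, conditions: tuple[Condition, ...], X: np.ndarray, pos: np.ndarray
    ) -> tuple[Condition, ...]:
        def score(conds: tuple[Condition, ...]) -> float:
            mask = np.ones(len(X), dtype=bool)
            for c in conds:
                mask &= c.holds(X)
            p = int((mask & pos).sum())
            n = int((mask & ~pos).sum())
            return (p - n) / (p + n) if p + n > 0 else -1.0

        best = conditions
        best_score = score(conditions)
        trimmed = conditions
        while len(trimmed) > 1:
            trimmed = trimmed[:-1]
            s = score(trimmed)
            if s >= best_score:
                best, best_score = trimmed, s
        return best

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        counts = np.bincount(y_enc, minlength=len(self.classes_))
        # Rarest classes first; the most frequent class (last in the learning
        # order, for which no rules are grown) is the default.
        class_order = sorted(
            range(len(self.classes_)), key=lambda c: (counts[c], c)
        )
        self.default_class_ = int(class_order[-1])
        rules: list[Rule] = []
        active = np.ones(len(X), dtype=bool)
        for target in class_order[:-1]:
            for _ in range(MAX_RULES_PER_CLASS):
                idx = np.nonzero(active)[0]
                if idx.size == 0 or (y_enc[idx] == target).sum() < 2:
                    break
                perm = rng.permutation(idx)
                n_grow = max(int(round(2 * idx.size / 3)), 1)
                grow_idx, prune_idx = perm[:n_grow], perm[n_grow:]
                pos_grow = y_enc[grow_idx] == target
                if pos_grow.sum() == 0:
                    break
                conds = self._grow_rule(X[grow_idx], pos_grow, target)
                if not conds:
                    break
                if prune_idx.size:
                    conds = self._prune_rule(conds, X[prune_idx], y_enc[prune_idx] == target)
                rule = Rule(conds, target)
                cov = rule.covers(X) & active
                p = int((y_enc[cov] == target).sum())
                n = int(cov.sum()) - p
                prior = (y_enc[active] == target).mean()
                if p < 2 or p / max(p + n, 1) <= max(prior, 0.5):
                    break
                rules.append(rule)
                active &= ~cov
        self.rules_ = rules
        return self

    def predict(self, X):
        check_is_fitted(self, "rules_")
        X = np.asarray(X, dtype=float)
        out = np.full(len(X), self.default_class_, dtype=int)
        unassigned = np.ones(len(X), dtype=bool)
        for rule in self.rules_:
            hit = rule.covers(X) & unassigned
            out[hit] = rule.target
            unassigned &= ~hit
        return self.classes_[out]
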