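"""The three classifier families used in the incremental feature sweep.

All three hide behind one fit/predict contract over a probe-subset matrix
and a label set:

* ``svm`` — one-vs-rest maximum-margin classifiers with a polynomial kernel
  (default degree 1, i.e. linear) and C = 1, solved by scikit-learn's SVC.
  Beta values already live in [0, 1], so no internal rescaling is applied.
* ``random_forest`` — 10 unpruned trees, each on a bootstrap of samples with
  floor(sqrt(#features)) candidate features per split, majority vote
  (scikit-learn RandomForestClassifier).
* ``rule_learner`` — a sequential-covering rule inducer in the RIPPER
  family: classes are processed from rarest to most frequent; per class,
  conjunctive threshold rules are grown on a 2/3 grow split by maximizing
  FOIL information gain, pruned on the remaining 1/3 by deleting trailing
  conditions while the pruning-set worth (p - n) / (p + n) improves, and
  rule addition stops once a new rule's pruning-set error exceeds 50%. The
  most frequent class is the unconditioned fall-through default. The
  post-induction global optimization passes of full RIPPER are not
  implemented.

One-vs-rest score ties resolve to the lowest class index (classes are kept
in lexicographic order), and every fit is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .data_io import LabelSet, MethylationMatrix
from .exceptions import ConfigError, ValidationError

FAMILIES = ("svm", "random_forest", "rule_learner")

_ALIASES = {
    "svm": "svm",
    "rf": "random_forest",
    "random_forest": "random_forest",
    "rules": "rule_learner",
    "ripper": "rule_learner",
    "rule_learner": "rule_learner",
}

_PARAM_SCHEMA = {
    "svm": {"degree", "C"},
    "random_forest": {"n_estimators", "max_features"},
    "rule_learner": {"grow_fraction", "max_rules_per_class"},
}


def canonical_family(name: str) -> str:
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown classifier family {name!r}; choose from {FAMILIES}"
        ) from None


@dataclass
class ClassifierSpec:
    """Family name, family-specific parameters and a seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = canonical_family(self.family)
        unknown = set(self.params) - _PARAM_SCHEMA[self.family]
        if unknown:
            raise ConfigError(
                f"unknown params for {self.family}: {sorted(unknown)}"
            )


@dataclass
class FittedModel:
    """Opaque trained state plus the feature/class vocabulary it expects."""

    family: str
    feature_ids: list[str]
    classes: list[str]
    state: object


# ---------------------------------------------------------------------------
# Rule learner
# ---------------------------------------------------------------------------

@dataclass
class Rule:
    """Conjunction of threshold conditions implying one class."""

    #: (feature_row, op, threshold) with op one of "<=" or ">"
    conditions: list[tuple[int, str, float]]
    target: str

    def covers(self, X: np.ndarray) -> np.ndarray:
        """Boolean coverage over columns of a features x samples matrix."""
        mask = np.ones(X.shape[1], dtype=bool)
        for fi, op, thr in self.conditions:
            mask &= (X[fi] <= thr) if op == "<=" else (X[fi] > thr)
        return mask

    def render(self, feature_ids: Sequence[str]) -> str:
        if not self.conditions:
            return f"IF TRUE THEN {self.target}"
        conds = " AND ".join(
            f"{feature_ids[fi]} {op} {thr:.6g}" for fi, op, thr in self.conditions
        )
        return f"IF {conds} THEN {self.target}"


@dataclass
class RuleList:
    rules: list[Rule]
    default: str

    def predict_codes(self, X: np.ndarray, class_index: dict[str, int]) -> np.ndarray:
        out = np.full(X.shape[1], class_index[self.default], dtype=int)
        unassigned = np.ones(X.shape[1], dtype=bool)
        for rule in self.rules:
            hit = unassigned & rule.covers(X)
            out[hit] = class_index[rule.target]
            unassigned &= ~hit
        return out

    def render(self, feature_ids: Sequence[str]) -> str:
        lines = [r.render(feature_ids) for r in self.rules]
        lines.append(f"ELSE {self.default}")
        return "\n".join(lines)


def _foil_gain(p1: float, n1: float, p0: float, n0: float) -> float:
    """FOIL information gain of specializing a rule (p0,n0) -> (p1,n1)."""
    if p1 == 0:
        return -np.inf
    return p1 * (np.log2(p1 / (p1 + n1)) - np.log2(p0 / (p0 + n0)))


def _best_condition(
    X: np.ndarray, pos: np.ndarray, covered: np.ndarray
) -> tuple[tuple[int, str, float], float] | None:
    """The (feature, op, threshold) maximizing FOIL gain on the grow set.

    ``pos`` and ``covered`` are boolean masks over samples; candidates are
    midpoints between consecutive distinct values among covered samples.
    """
    idx = np.flatnonzero(covered)
    if idx.size == 0:
        return None
    p0 = float(pos[idx].sum())
    n0 = float(idx.size - p0)
    if p0 == 0:
        return None
    best: tuple[tuple[int, str, float], float] | None = None
    for fi in range(X.shape[0]):
        x = X[fi, idx]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ps = pos[idx][order].astype(float)
        cum_p = np.cumsum(ps)
        distinct = xs[1:] > xs[:-1]
        if not distinct.any():
            continue
        cut = np.flatnonzero(distinct)          # last index of the left block
        thr = 0.5 * (xs[cut] + xs[cut + 1])
        p_le = cum_p[cut]
        n_le = (cut + 1) - p_le
        p_gt = p0 - p_le
        n_gt = n0 - n_le
        for j in range(cut.size):
            for op, p1, n1 in (("<=", p_le[j], n_le[j]), (">", p_gt[j], n_gt[j])):
                g = _foil_gain(p1, n1, p0, n0)
                if g > 0 and (best is None or g > best[1]):
                    best = ((fi, op, float(thr[j])), g)
    return best


def _grow_rule(X: np.ndarray, pos: np.ndarray, target: str) -> Rule:
    """Greedily add conditions until no negatives remain or no gain."""
    rule = Rule(conditions=[], target=target)
    covered = np.ones(X.shape[1], dtype=bool)
    while True:
        idx = np.flatnonzero(covered)
        if idx.size == 0 or not (~pos[idx]).any():
            break  # pure (or empty) coverage
        found = _best_condition(X, pos, covered)
        if found is None:
            break
        cond, _ = found
        rule.conditions.append(cond)
        fi, op, thr = cond
        covered &= (X[fi] <= thr) if op == "<=" else (X[fi] > thr)
    return rule


def _worth(rule: Rule, X: np.ndarray, pos: np.ndarray) -> float:
    """(p - n) / (p + n) on a pruning set; -1 when the rule covers nothing."""
    cov = rule.covers(X)
    p = float((cov & pos).sum())
    n = float((cov & ~pos).sum())
    if p + n == 0:
        return -1.0
    return (p - n) / (p + n)


def _prune_rule(rule: Rule, X: np.ndarray, pos: np.ndarray) -> Rule:
    """Delete trailing conditions while the pruning-set worth improves."""
    best = Rule(conditions=list(rule.conditions), target=rule.target)
    while best.conditions:
        shorter = Rule(conditions=best.conditions[:-1], target=rule.target)
        if _worth(shorter, X, pos) > _worth(best, X, pos):
            best = shorter
        else:
            break
    return best


def learn_rules(
    matrix: MethylationMatrix,
    labels: LabelSet,
    params: dict | None = None,
    seed: int = 0,
) -> RuleList:
    """Sequential-covering rule induction, rarest class first.

    Ties in class frequency break lexicographically (the lexicographically
    earlier class is treated as rarer). See the module docstring for the
    grow/prune protocol.
    """
    params = params or {}
    grow_fraction = float(params.get("grow_fraction", 2.0 / 3.0))
    max_rules = int(params.get("max_rules_per_class", 50))
    X = matrix.values
    y = labels.y(matrix.sample_ids)
    counts = labels.class_counts()
    if len(labels.categories) < 2:
        raise ValidationError("rule learning needs at least 2 classes")
    order = sorted(labels.categories, key=lambda c: (counts[c], c))
    default = order[-1]
    class_index = {c: i for i, c in enumerate(labels.categories)}

    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    remaining = np.ones(X.shape[1], dtype=bool)
    rules: list[Rule] = []
    for cat in order[:-1]:
        code = class_index[cat]
        for _ in range(max_rules):
            idx = np.flatnonzero(remaining)
            pos_mask = y[idx] == code
            if not pos_mask.any():
                break
            # stratified 2/3 grow / 1/3 prune split of the remaining samples
            grow_sel = np.zeros(idx.size, dtype=bool)
            for is_pos in (True, False):
                part = np.flatnonzero(pos_mask == is_pos)
                if part.size == 0:
                    continue
                k = max(1, int(round(grow_fraction * part.size)))
                grow_sel[rng.permutation(part)[:k]] = True
            grow_idx = idx[grow_sel]
            prune_idx = idx[~grow_sel]

            rule = _grow_rule(X[:, grow_idx], y[grow_idx] == code, cat)
            if not rule.conditions:
                break
            if prune_idx.size:
                rule = _prune_rule(rule, X[:, prune_idx], y[prune_idx] == code)
                if not rule.conditions:
                    break
                cov = rule.covers(X[:, prune_idx])
                covered_n = cov.sum()
                if covered_n:
                    err = float((cov & (y[prune_idx] != code)).sum()) / covered_n
                else:
                    err = 1.0
                if err > 0.5:
                    break
            rules.append(rule)
            remaining[np.flatnonzero(remaining)[rule.covers(X[:, idx])]] = False
    return RuleList(rules=rules, default=default)


# ---------------------------------------------------------------------------
# Unified fit / predict
# ---------------------------------------------------------------------------

def fit(
    spec: ClassifierSpec,
    matrix: MethylationMatrix,
    labels: LabelSet,
) -> FittedModel:
    """Train one classifier on a (probe-subset) matrix.

    Samples are the matrix columns; the label set must cover all of them.
    """
    y = labels.restrict(matrix.sample_ids)
    classes = y.categories
    if len(classes) < 2:
        raise ValidationError("fit needs at least 2 classes")
    X = matrix.values.T  # samples x features
    codes = y.y(matrix.sample_ids)

    if spec.family == "svm":
        counts = np.bincount(codes, minlength=len(classes))
        if (counts < 2).any():
            small = [classes[i] for i in np.flatnonzero(counts < 2)]
            raise ValidationError(f"svm needs >= 2 samples per class; short: {small}")
        est = OneVsRestClassifier(
            SVC(
                kernel="poly",
                degree=int(spec.params.get("degree", 1)),
                C=float(spec.params.get("C", 1.0)),
                gamma=1.0,
                coef0=0.0,
            )
        )
        est.fit(X, codes)
        state = est
    elif spec.family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=int(spec.params.get("n_estimators", 10)),
            max_features=spec.params.get("max_features", "sqrt"),
            random_state=spec.seed % (2**31),
        )
        est.fit(X, codes)
        state = est
    else:  # rule_learner
        state = learn_rules(matrix, y, spec.params, seed=spec.seed)

    return FittedModel(
        family=spec.family,
        feature_ids=list(matrix.probe_ids),
        classes=list(classes),
        state=state,
    )


def predict(model: FittedModel, matrix: MethylationMatrix) -> dict[str, str]:
    """Predict one category per sample; features are order-normalized."""
    missing = set(model.feature_ids) - set(matrix.probe_ids)
    if missing:
        raise ValidationError(
            f"matrix lacks {len(missing)} model feature(s): "
            f"{sorted(missing)[:5]}"
        )
    sub = matrix.subset_probes(model.feature_ids)
    if model.family == "rule_learner":
        class_index = {c: i for i, c in enumerate(model.classes)}
        codes = model.state.predict_codes(sub.values, class_index)
    elif model.family == "svm":
        # explicit argmax of one-vs-rest scores: ties -> lowest class index
        scores = model.state.decision_function(sub.values.T)
        if scores.ndim == 1:  # two classes: positive score = class 1
            codes = (scores > 0).astype(int)
        else:
            codes = np.argmax(scores, axis=1)
        codes = np.asarray(model.state.classes_)[codes]
    else:
        codes = model.state.predict(sub.values.T)
    return {
        s: model.classes[int(c)] for s, c in zip(sub.sample_ids, codes)
    }
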