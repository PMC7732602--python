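"""Incremental feature selection (IFS) over a ranked probe list.

Given a feature ranking, nested top-k prefixes are formed in steps of 10
(the i-th candidate subset holds 10*i features; a final partial prefix of
all M features is appended when M is not a multiple of the step). Each
prefix is scored for each classifier family by stratified 10-fold
cross-validation, pooling the fold predictions into one confusion matrix
and summarizing it with the multiclass Matthews correlation coefficient
(MCC) and the overall accuracy (trace over total). Per family, the optimal
subset is the prefix with maximal MCC, ties going to the smaller subset.

The multiclass MCC is the K-category correlation coefficient of the
confusion matrix C with row sums t (truth) and column sums p (prediction),
total s and trace c:

    MCC = (c*s - p.t) / sqrt((s^2 - p.p) * (s^2 - t.t))

which reduces to the classical binary MCC for K = 2 and is defined as 0
when either variance term vanishes (e.g. a constant predictor).

Note the ranking is computed once on the full training set before
cross-validation — faithful to the common published protocol, but the CV
estimates are therefore optimistically biased relative to a pipeline that
re-ranks inside each fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, FittedModel, fit, predict
from .data_io import LabelSet, MethylationMatrix
from .exceptions import ValidationError
from .mcfs import FeatureRanking

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Confusion matrix and scores
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K count matrix, entry (i, j) = true class i predicted as j."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"confusion counts shape {self.counts.shape} != ({k}, {k})"
            )
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls,
        truth: dict[str, str],
        predicted: dict[str, str],
        classes: Sequence[str],
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for sample, t in truth.items():
            counts[index[t], index[predicted[sample]]] += 1
        return cls(classes=list(classes), counts=counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def mcc_multiclass(cm: ConfusionMatrix) -> float:
    """K-category Matthews correlation of a confusion matrix, in [-1, 1]."""
    counts = cm.counts.astype(float)
    s = counts.sum()
    if s <= 0:
        raise ValidationError("empty confusion matrix")
    c = np.trace(counts)
    t = counts.sum(axis=1)  # truth (row) sums
    p = counts.sum(axis=0)  # prediction (column) sums
    cov = c * s - p @ t
    var_p = s * s - p @ p
    var_t = s * s - t @ t
    if var_p <= 0 or var_t <= 0:
        return 0.0
    return float(cov / np.sqrt(var_p * var_t))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total count."""
    if cm.total <= 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall; the class-balanced alternative summary."""
    counts = cm.counts.astype(float)
    rows = counts.sum(axis=1)
    present = rows > 0
    return float(np.mean(np.diag(counts)[present] / rows[present]))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(
    labels: LabelSet, sample_ids: Sequence[str], folds: int, seed: int
) -> list[list[str]]:
    """Per class, shuffle samples by seed and deal them round-robin.

    Handles classes smaller than the fold count (they are simply absent
    from some folds, with a warning).
    """
    if folds < 2:
        raise ValidationError("folds must be at least 2")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    by_class: dict[str, list[str]] = {c: [] for c in labels.categories}
    for s in sample_ids:
        by_class[labels.assignments[s]].append(s)
    assignment: list[list[str]] = [[] for _ in range(folds)]
    for cat in labels.categories:
        members = sorted(by_class[cat])
        if 0 < len(members) < folds:
            warnings.warn(
                f"class {cat!r} has {len(members)} samples for {folds} folds; "
                "it will be missing from some training folds' test parts",
                stacklevel=2,
            )
        perm = rng.permutation(len(members))
        for pos, mi in enumerate(perm):
            assignment[pos % folds].append(members[mi])
    return assignment


def cross_validate(
    matrix: MethylationMatrix,
    labels: LabelSet,
    subset: Sequence[str],
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
) -> ConfusionMatrix:
    """Stratified k-fold CV of one classifier on one probe prefix.

    Every sample is predicted exactly once, by a model never trained on it;
    the per-fold predictions pool into a single confusion matrix.
    """
    sub = matrix.subset_probes(subset)
    fold_samples = stratified_folds(labels, sub.sample_ids, folds, seed)
    truth = {s: labels.assignments[s] for s in sub.sample_ids}
    predicted: dict[str, str] = {}
    for f, test_ids in enumerate(fold_samples):
        if not test_ids:
            continue
        train_ids = [s for s in sub.sample_ids if s not in set(test_ids)]
        model = fit(
            ClassifierSpec(spec.family, dict(spec.params), seed=spec.seed + f),
            sub.subset_samples(train_ids),
            labels.restrict(train_ids),
        )
        fold_pred = predict(model, sub.subset_samples(test_ids))
        for s, lab in fold_pred.items():
            predicted[s] = lab
    missing = set(truth) - set(predicted)
    if missing:  # pragma: no cover - defensive
        raise ValidationError(f"samples never predicted: {sorted(missing)[:5]}")
    return ConfusionMatrix.from_predictions(truth, predicted, labels.categories)


# ---------------------------------------------------------------------------
# The sweep
# ---------------------------------------------------------------------------

def make_subsets(
    ranking: FeatureRanking, step: int = 10, max_features: int | None = None
) -> list[list[str]]:
    """Nested top-k prefixes: sizes step, 2*step, ..., plus a final partial.

    ``max_features`` caps the sweep (None sweeps the whole ranking).
    """
    if step < 1:
        raise ValidationError("step must be at least 1")
    if len(ranking) == 0:
        raise ValidationError("empty ranking")
    M = len(ranking)
    limit = M if max_features is None else min(max_features, M)
    sizes = list(range(step, limit + 1, step))
    if not sizes or sizes[-1] != limit:
        sizes.append(limit)
    probes = ranking.probe_ids
    return [probes[:k] for k in sizes]


@dataclass
class IFSResult:
    """Per-subset-size scores and the optimal point per classifier family."""

    step: int
    #: rows of (n_features, {family: mcc}, {family: accuracy})
    rows: list[tuple[int, dict[str, float], dict[str, float]]]
    #: family -> (n_features, mcc) at the maximum (ties -> smaller size)
    optimal: dict[str, tuple[int, float]] = field(default_factory=dict)

    def families(self) -> list[str]:
        return sorted(self.rows[0][1]) if self.rows else []

    def to_frame(self) -> pd.DataFrame:
        records = []
        for n, mccs, accs in self.rows:
            rec = {"n_features": n}
            for fam in sorted(mccs):
                rec[f"mcc_{fam}"] = mccs[fam]
                rec[f"accuracy_{fam}"] = accs[fam]
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ifs_sweep(
    matrix: MethylationMatrix,
    labels: LabelSet,
    ranking: FeatureRanking,
    specs: Sequence[ClassifierSpec],
    step: int = 10,
    folds: int = 10,
    seed: int = 0,
    max_features: int | None = None,
) -> IFSResult:
    """Score every (prefix, family) pair and select the optimum per family."""
    if set(ranking.probe_ids) != set(matrix.probe_ids):
        raise ValidationError("ranking must cover exactly the matrix probes")
    subsets = make_subsets(ranking, step=step, max_features=max_features)
    rows: list[tuple[int, dict[str, float], dict[str, float]]] = []
    for subset in subsets:
        mccs: dict[str, float] = {}
        accs: dict[str, float] = {}
        for spec in specs:
            cm = cross_validate(matrix, labels, subset, spec, folds=folds, seed=seed)
            mccs[spec.family] = mcc_multiclass(cm)
            accs[spec.family] = overall_accuracy(cm)
        rows.append((len(subset), mccs, accs))
        logger.info(
            "IFS n=%d: %s",
            len(subset),
            ", ".join(f"{f}={v:.3f}" for f, v in sorted(mccs.items())),
        )
    optimal: dict[str, tuple[int, float]] = {}
    for spec in specs:
        fam = spec.family
        best_n, best_mcc = None, -np.inf
        for n, mccs, _ in rows:
            if mccs[fam] > best_mcc:  # strict: first (smallest n) wins ties
                best_n, best_mcc = n, mccs[fam]
        optimal[fam] = (int(best_n), float(best_mcc))
    return IFSResult(step=step, rows=rows, optimal=optimal)


def evaluate_independent(
    matrix_train: MethylationMatrix,
    labels_train: LabelSet,
    matrix_test: MethylationMatrix,
    labels_test: LabelSet,
    subset: Sequence[str],
    spec: ClassifierSpec,
) -> ConfusionMatrix:
    """Fit once on the full training cohort, score on the independent one."""
    model = fit(spec, matrix_train.subset_probes(subset), labels_train)
    pred = predict(model, matrix_test.subset_probes(subset))
    truth = {s: labels_test.assignments[s] for s in matrix_test.sample_ids}
    return ConfusionMatrix.from_predictions(truth, pred, labels_train.categories)


def plot_ifs_curves(result: IFSResult, path: str | Path) -> None:
    """MCC vs number of features per family, maxima marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ns = [n for n, _, _ in result.rows]
    for fam in result.families():
        ys = [mccs[fam] for _, mccs, _ in result.rows]
        (line,) = ax.plot(ns, ys, marker=".", label=fam)
        bn, bm = result.optimal[fam]
        ax.plot([bn], [bm], marker="*", markersize=14, color=line.get_color())
        ax.annotate(
            f"{fam}: MCC={bm:.3f}\n@ {bn} features",
            (bn, bm),
            textcoords="offset points",
            xytext=(6, -12),
            fontsize=8,
            color=line.get_color(),
        )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated MCC")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
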