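"""Monte Carlo feature selection (MCFS) for beta-value matrices.

MCFS ranks features by aggregating their split contributions over a large
ensemble of decision trees grown on random feature projections. With ``M``
probes, ``s`` random subsets ("projections") of ``m << M`` probes are drawn;
on each, ``t`` trees are grown, each on a stratified bootstrap of the
samples, giving ``s * t`` trees in total. A probe ``g`` then receives the
relative importance

    RI_g = sum over trees tau of
           wAcc(tau)^u * sum over nodes of tau splitting on g of
           IG(node) * (n_node / n_tau)^v

where ``IG`` is the information gain of the split (entropy, bits),
``n_node`` the number of training samples reaching the node, ``n_tau`` the
number of training samples of the tree, and ``wAcc`` the tree's weighted
accuracy — the unweighted mean of per-class recalls on the samples the
bootstrap held out. The exponents ``u`` and ``v`` default to 1. Features
are ranked by decreasing RI; probes never chosen for a split score 0.

Trees are grown with binary splits on midpoint thresholds between
consecutive distinct beta values, chosen to maximize information gain;
growth stops at pure nodes, the minimum leaf size, or zero best gain, with
no pruning. All ties (equal gains, equal RI) break lexicographically on
probe ID, and all randomness derives from one master seed through a
counter-indexed seed tree, so rankings are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .data_io import LabelSet, MethylationMatrix
from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------

@dataclass
class MCFSConfig:
    """Ensemble-size and tree-growth parameters.

    ``m`` may be given directly or left None to use ``ceil(m_fraction * M)``
    at run time. ``u`` and ``v`` are the exponents on the tree-quality and
    node-fraction terms of the RI sum.
    """

    s: int = 1000
    m: int | None = None
    m_fraction: float = 0.05
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 2.0 / 3.0
    min_leaf: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ConfigError("s and t must be positive")
        if self.m is not None and self.m < 1:
            raise ConfigError("m must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be at least 1")

    def resolve_m(self, n_features: int) -> int:
        m = self.m if self.m is not None else ceil(self.m_fraction * n_features)
        if m > n_features:
            raise ConfigError(f"m={m} exceeds feature count M={n_features}")
        return max(1, m)


@dataclass
class TreeRecord:
    """Bookkeeping of one grown tree: quality plus per-node split terms."""

    tree_id: int
    wacc: float
    n_total: int
    #: (split probe_id, information gain in bits, samples reaching the node)
    nodes: list[tuple[str, float, int]] = field(default_factory=list)


@dataclass
class FeatureRanking:
    """Probes ordered by decreasing relative importance."""

    #: (probe_id, ri, rank) with rank starting at 1
    entries: list[tuple[str, float, int]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> list[str]:
        return [p for p, _, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.probe_ids[:k]

    def ri(self) -> dict[str, float]:
        return {p: r for p, r, _ in self.entries}


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def sample_projections(M: int, config: MCFSConfig) -> list[np.ndarray]:
    """Draw ``s`` feature-index subsets of size ``m`` without replacement."""
    m = config.resolve_m(M)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    return [
        np.sort(rng.choice(M, size=m, replace=False)) for _ in range(config.s)
    ]


# ---------------------------------------------------------------------------
# Tree induction
# ---------------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits of count vectors along ``axis``."""
    n = counts.sum(axis=axis, keepdims=True)
    safe_n = np.where(n > 0, n, 1.0)
    h = np.log2(safe_n) - xlogy(counts, counts).sum(
        axis=axis, keepdims=True
    ) / (safe_n * np.log(2))
    h = np.where(n > 0, h, 0.0)
    return np.squeeze(h, axis=axis)


def _best_split(
    X: np.ndarray, onehot: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature_row, threshold, gain) for a node, or None.

    ``X`` is features x samples for the node, rows already ordered so that
    np.argmax's first-hit rule realizes lexicographic probe-ID tie-breaking;
    within a feature, the smallest qualifying threshold wins ties.
    """
    m, n = X.shape
    if n < 2 * min_leaf:
        return None
    counts = onehot.sum(axis=0)
    h_parent = _entropy_bits(counts)
    if h_parent <= 0.0:
        return None

    order = np.argsort(X, axis=1, kind="stable")
    xs = np.take_along_axis(X, order, axis=1)
    cum = np.cumsum(onehot[order], axis=1)            # (m, n, K) left counts
    left = cum[:, :-1, :]
    right = counts[None, None, :] - left
    n_left = np.arange(1, n)[None, :]
    n_right = n - n_left

    valid = (xs[:, 1:] > xs[:, :-1]) & (n_left >= min_leaf) & (n_right >= min_leaf)
    if not valid.any():
        return None
    gain = h_parent - (
        n_left / n * _entropy_bits(left) + n_right / n * _entropy_bits(right)
    )
    gain = np.where(valid, gain, -np.inf)
    flat = int(np.argmax(gain))
    fi, pos = divmod(flat, n - 1)
    best_gain = float(gain[fi, pos])
    if best_gain <= 0.0:
        return None
    thr = 0.5 * (xs[fi, pos] + xs[fi, pos + 1])
    return fi, float(thr), best_gain


@dataclass
class _Node:
    feature: int = -1        # row index into the projection; -1 for leaves
    threshold: float = 0.0
    gain: float = 0.0
    n: int = 0
    prediction: int = 0      # majority class code (leaves and internals)
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    min_leaf: int = 2,
) -> _Node:
    """Grow an information-gain binary tree on (features x samples) data.

    Rows of ``X`` must already be sorted by probe ID so gain ties resolve
    lexicographically. ``y`` holds integer class codes.
    """
    onehot = np.zeros((y.size, n_classes))
    onehot[np.arange(y.size), y] = 1.0

    def grow(idx: np.ndarray) -> _Node:
        counts = onehot[idx].sum(axis=0)
        node = _Node(n=idx.size, prediction=int(np.argmax(counts)))
        split = _best_split(X[:, idx], onehot[idx], min_leaf)
        if split is None:
            return node
        fi, thr, gain = split
        mask = X[fi, idx] <= thr
        node.feature, node.threshold, node.gain = fi, thr, gain
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return grow(np.arange(y.size))


def _walk_internal(node: _Node):
    if node.is_leaf:
        return
    yield node
    yield from _walk_internal(node.left)
    yield from _walk_internal(node.right)


def predict_tree(root: _Node, X: np.ndarray) -> np.ndarray:
    """Class codes for each column of a features x samples matrix."""
    out = np.empty(X.shape[1], dtype=int)
    for j in range(X.shape[1]):
        node = root
        while not node.is_leaf:
            node = node.left if X[node.feature, j] <= node.threshold else node.right
        out[j] = node.prediction
    return out


def _stratified_bootstrap(
    y: np.ndarray, n_classes: int, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class draw with replacement to ~fraction of the class size.

    Returns (train indices incl. multiplicity, held-out indices). Samples
    never drawn form the held-out evaluation set.
    """
    train: list[np.ndarray] = []
    drawn = np.zeros(y.size, dtype=bool)
    for c in range(n_classes):
        members = np.flatnonzero(y == c)
        if members.size == 0:
            continue
        k = max(1, int(round(fraction * members.size)))
        take = rng.choice(members, size=k, replace=True)
        train.append(take)
        drawn[take] = True
    train_idx = np.sort(np.concatenate(train))
    return train_idx, np.flatnonzero(~drawn)


def weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Unweighted mean of per-class recalls over classes present in y_true."""
    recalls = []
    for c in range(n_classes):
        mask = y_true == c
        if mask.any():
            recalls.append(float(np.mean(y_pred[mask] == c)))
    return max(0.0, float(np.mean(recalls))) if recalls else 0.0


def grow_tree(
    matrix: MethylationMatrix,
    labels: LabelSet,
    config: MCFSConfig,
    split_seed: int,
    tree_id: int = 0,
) -> TreeRecord:
    """Grow one tree on a projected matrix and record its RI bookkeeping.

    The matrix must already be restricted to one projection. Samples are
    split into a stratified bootstrap training portion and its complement;
    the tree is grown on the former, wAcc measured on the latter.
    """
    probe_order = np.argsort(np.array(matrix.probe_ids, dtype=object))
    probes_sorted = [matrix.probe_ids[i] for i in probe_order]
    X = matrix.values[probe_order, :]
    y = labels.y(matrix.sample_ids)
    n_classes = len(labels.categories)
    if np.unique(y).size < 2:
        raise ValidationError("grow_tree needs at least 2 classes of samples")

    rng = np.random.default_rng(np.random.SeedSequence(split_seed))
    train_idx, eval_idx = _stratified_bootstrap(
        y, n_classes, config.train_fraction, rng
    )
    if np.unique(y[train_idx]).size < 2:
        # degenerate bootstrap: single-leaf tree
        root = _Node(n=train_idx.size, prediction=int(np.bincount(y[train_idx]).argmax()))
    else:
        root = build_tree(X[:, train_idx], y[train_idx], n_classes, config.min_leaf)

    if eval_idx.size:
        wacc = weighted_accuracy(
            y[eval_idx], predict_tree(root, X[:, eval_idx]), n_classes
        )
    else:  # bootstrap covered every sample; no held-out evidence of quality
        wacc = 0.0

    nodes = [
        (probes_sorted[nd.feature], nd.gain, nd.n) for nd in _walk_internal(root)
    ]
    return TreeRecord(
        tree_id=tree_id, wacc=wacc, n_total=int(train_idx.size), nodes=nodes
    )


# ---------------------------------------------------------------------------
# Relative importance and the full run
# ---------------------------------------------------------------------------

def relative_importance(
    trees: Sequence[TreeRecord],
    config: MCFSConfig,
    all_probes: Sequence[str],
) -> FeatureRanking:
    """Aggregate per-node gains into the RI score and rank all probes.

    RI_g = sum_tau wAcc^u * sum_{nodes on g} IG * (n_node/n_tau)^v; probes
    absent from every tree keep RI 0. Ties break lexicographically.
    """
    if not trees:
        raise ValidationError("relative_importance needs at least one tree")
    ri: dict[str, float] = {p: 0.0 for p in all_probes}
    for rec in trees:
        w = rec.wacc ** config.u
        for probe, ig, n_node in rec.nodes:
            if not (0 < n_node <= rec.n_total):
                raise ValidationError(
                    f"node sample count {n_node} outside (0, {rec.n_total}]"
                )
            ri[probe] = ri.get(probe, 0.0) + w * ig * (n_node / rec.n_total) ** config.v
    ordered = sorted(ri.items(), key=lambda kv: (-kv[1], kv[0]))
    return FeatureRanking(
        entries=[(p, v, rank) for rank, (p, v) in enumerate(ordered, start=1)]
    )


def run_mcfs(
    matrix: MethylationMatrix,
    labels: LabelSet,
    config: MCFSConfig,
) -> FeatureRanking:
    """The full MCFS pass: projections -> trees -> RI ranking."""
    if set(matrix.sample_ids) != set(labels.assignments):
        raise ValidationError("matrix and labels must share sample IDs")
    if len(labels.categories) < 2:
        raise ValidationError("MCFS needs at least 2 classes")
    M = matrix.n_probes
    projections = sample_projections(M, config)
    trees: list[TreeRecord] = []
    tree_id = 0
    for pi, proj in enumerate(projections):
        sub = MethylationMatrix(
            probe_ids=[matrix.probe_ids[i] for i in proj],
            sample_ids=list(matrix.sample_ids),
            values=matrix.values[proj, :],
        )
        for ti in range(config.t):
            # counter-indexed child seeds: independent of execution order
            split_seed = np.random.SeedSequence(
                (config.seed, 1, pi, ti)
            ).generate_state(1)[0] % (2**31)
            trees.append(
                grow_tree(sub, labels, config, int(split_seed), tree_id=tree_id)
            )
            tree_id += 1
    logger.info("MCFS grew %d trees over %d projections", len(trees), len(projections))
    return relative_importance(trees, config, matrix.probe_ids)


def write_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    """TSV with columns rank, probe_id, RI at full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tprobe_id\tRI\n")
        for probe, ri, rank in ranking.entries:
            fh.write(f"{rank}\t{probe}\t{ri!r}\n")


def read_ranking(path: str | Path) -> FeatureRanking:
    entries: list[tuple[str, float, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank"):
            raise ValidationError(f"unrecognized ranking header in {path}")
        for line in fh:
            rank, probe, ri = line.rstrip("\n").split("\t")
            entries.append((probe, float(ri), int(rank)))
    return FeatureRanking(entries=entries)
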