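"""Hypergeometric over-representation analysis with BH-FDR control.

A query gene list (the genes targeted by the optimal probes) is tested
against user-supplied term -> gene-set collections (GMT files). For a
universe of N genes, a term annotating K of them and a query of n genes
overlapping the term in k, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric(N, K, n) distribution, computed by exact
log-space summation so it stays accurate for array-scale universes.
P-values are adjusted per namespace (BP / CC / MF / pathway) with the
Benjamini-Hochberg step-up procedure; terms with FDR below ``alpha``
(default 0.05) are reported significant, sorted by p.

No ontology-graph propagation is performed: terms are tested exactly as
annotated in the supplied collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """One namespace worth of term -> (name, gene set) annotations."""

    namespace: str
    sets: dict[str, tuple[str, frozenset]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")


@dataclass
class EnrichmentResult:
    """Per-term overlap counts, hypergeometric p and BH-FDR."""

    namespace: str
    table: pd.DataFrame  # term_id, term_name, k, K, n, N, p, fdr
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        sig = self.table[self.table["fdr"] < self.alpha]
        return sig.sort_values(["p", "term_id"]).reset_index(drop=True)

    def write(self, path: str | Path, mode: str = "w", header: bool = True) -> None:
        out = self.table.copy()
        out.insert(0, "namespace", self.namespace)
        out.to_csv(path, sep="\t", index=False, mode=mode, header=header)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ hypergeometric(N, K, n).

    Summed in log space over the support [k, min(K, n)], so it remains
    stable for array-scale N where individual terms underflow.
    """
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    js = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, js) + _log_comb(N - K, n - js) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


# ---------------------------------------------------------------------------
# Enrichment proper
# ---------------------------------------------------------------------------

def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Test every term of one collection against a query gene list.

    Genes outside the universe are dropped (with a logged count); counts
    k, K, n are all taken within the universe. FDR is adjusted across the
    terms of this collection only (per-namespace control).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty gene universe")
    query = set(query_genes)
    dropped = len(query - universe_set)
    if dropped:
        logger.info(
            "%d query gene(s) outside the universe dropped", dropped
        )
    query &= universe_set
    if not query:
        raise ValidationError("query is empty after intersecting the universe")

    records = []
    for term_id in sorted(collection.sets):
        name, genes = collection.sets[term_id]
        term_in_universe = genes & universe_set
        K = len(term_in_universe)
        k = len(term_in_universe & query)
        p = (
            hypergeometric_pvalue(k, K, len(query), len(universe_set))
            if K
            else 1.0
        )
        records.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": len(query),
                "N": len(universe_set),
                "p": p,
            }
        )
    table = pd.DataFrame.from_records(records)
    table["fdr"] = bh_fdr(table["p"].tolist())
    return EnrichmentResult(namespace=collection.namespace, table=table, alpha=alpha)


def enrich_collections(
    query_genes: Iterable[str],
    collections: Sequence[GeneSetCollection],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    universe = set(universe)
    query = set(query_genes)
    return [enrich(query, coll, universe, alpha=alpha) for coll in collections]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, namespace: str | None = None) -> GeneSetCollection:
    """Read a GMT file (term_id TAB term_name TAB gene ...)."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs >= 3 fields")
            term_id, term_name, *genes = parts
            if term_id in sets:
                raise ValidationError(f"{path}: duplicate term {term_id!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise ValidationError(f"{path}:{ln}: term {term_id!r} has no genes")
            sets[term_id] = (term_name, members)
    return GeneSetCollection(namespace=namespace or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.sets):
            name, genes = collection.sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")
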