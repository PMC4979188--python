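"""Hypergeometric functional enrichment of gene sets against a background.

Given a flat gene -> term annotation map (GO terms or pathway
identifiers), each term is scored with the upper-tail hypergeometric
probability of drawing at least ``k`` annotated genes when ``n`` genes
are sampled from a background of ``N`` genes of which ``K`` carry the
term:

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

computed in log space.  q-values are Benjamini-Hochberg across all
tested terms of the namespace and a term is significant when
``q <= 0.05`` by default.  No ontology-graph propagation is performed;
annotations are taken as given flat assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .de import bh_adjust

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich",
    "go_category_counts",
]


@dataclass
class AnnotationMap:
    """Bidirectional gene <-> term association for one namespace."""

    namespace: str
    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]] = field(default=None)

    def __post_init__(self) -> None:
        if self.term_to_genes is None:
            inverse: dict[str, set[str]] = {}
            for gene, terms in self.gene_to_terms.items():
                for term in terms:
                    inverse.setdefault(term, set()).add(gene)
            self.term_to_genes = {t: frozenset(g) for t, g in inverse.items()}
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            for gene in genes:
                if term not in self.gene_to_terms.get(gene, frozenset()):
                    raise ValueError(
                        f"inverse map inconsistent at gene {gene!r}, term {term!r}"
                    )

    @classmethod
    def from_pairs(cls, pairs, namespace: str = "GO") -> "AnnotationMap":
        forward: dict[str, set[str]] = {}
        for gene, term in pairs:
            forward.setdefault(gene, set()).add(term)
        return cls(
            namespace=namespace,
            gene_to_terms={g: frozenset(t) for g, t in forward.items()},
        )

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene_to_terms)

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)


def _log_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_pvalue(k, n: int, K: int, N: int):
    """Upper-tail probability of >= ``k`` term-annotated genes in the draw.

    ``k`` may be a scalar or an array of overlap counts for the same
    (n, K, N); the array form returns one tail probability per entry,
    accumulated from the smallest terms upward for relative accuracy.
    """
    if n > N or K > N or n < 0 or K < 0:
        raise ValueError(f"require 0 <= n, K <= N; got n={n}, K={K}, N={N}")
    m = min(n, K)
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > m):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if k_arr.ndim == 0 and k_arr == 0:
        return 1.0
    i = np.arange(0, m + 1, dtype=np.float64)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    log_tails = np.logaddexp.accumulate(log_terms[::-1])[::-1]
    p = np.clip(np.exp(log_tails[k_arr]), 5e-324, 1.0)
    if k_arr.ndim == 0:
        return float(p)
    p[k_arr == 0] = 1.0
    return p


@dataclass
class EnrichmentResult:
    """Per-term enrichment records plus bookkeeping of dropped genes."""

    namespace: str
    records: pd.DataFrame
    n_query: int
    n_dropped: int

    @property
    def significant_terms(self) -> list[str]:
        return list(self.records.loc[self.records["significant"], "term"])


def enrich(
    gene_set: set[str],
    annotation: AnnotationMap,
    background: set[str] | None = None,
    q_threshold: float = 0.05,
) -> EnrichmentResult:
    """Score every term with background support against ``gene_set``.

    The background defaults to all genes carrying at least one
    annotation in the namespace ("genome background"); query genes
    outside the background are dropped with a logged count.  Terms with
    zero annotated background genes are skipped rather than diluting the
    FDR.  Records are sorted by (q, p, term).
    """
    if background is None:
        background = annotation.annotated_genes
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    query = set(gene_set) & background
    n_dropped = len(set(gene_set)) - len(query)
    n = len(query)
    N = len(background)

    rows = []
    for term in sorted(annotation.terms):
        term_bg = annotation.term_to_genes[term] & background
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & query)
        rows.append((term, k, n, K, N, hypergeom_pvalue(k, n, K, N)))
    records = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_value"]
    )
    if len(records):
        records["q_value"] = bh_adjust(records["p_value"].to_numpy())
        records["significant"] = records["q_value"] <= q_threshold
        records = records.sort_values(
            ["q_value", "p_value", "term"], kind="stable"
        ).reset_index(drop=True)
    else:
        records["q_value"] = []
        records["significant"] = []
    return EnrichmentResult(
        namespace=annotation.namespace,
        records=records,
        n_query=n,
        n_dropped=n_dropped,
    )


def go_category_counts(
    gene_sets: dict[str, set[str]],
    slim_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-set, per-category annotation counts and within-set percentages.

    ``slim_map`` maps gene -> categories (a gene may carry several; it
    is counted once per category).  Percentages are relative to the
    number of annotated members of each set.
    """
    categories = sorted({c for cats in slim_map.values() for c in cats})
    rows = []
    for name, genes in gene_sets.items():
        annotated = [g for g in genes if slim_map.get(g)]
        denom = len(annotated)
        for cat in categories:
            count = sum(1 for g in annotated if cat in slim_map[g])
            rows.append(
                {
                    "set": name,
                    "category": cat,
                    "count": count,
                    "percent": 100.0 * count / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["set", "category", "count", "percent"])
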