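"""Hypergeometric term enrichment against a background universe with BH FDR."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats


@dataclass
class AnnotationMap:
    """gene id -> term ids, plus term metadata (namespace, label)."""

    gene_terms: Dict[str, Set[str]]
    term_info: Dict[str, Tuple[str, str]]  # term -> (namespace, label)

    def namespace(self, term: str) -> str:
        return self.term_info.get(term, ("default", term))[0]

    def genes_with_term(self, term: str) -> Set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


@dataclass
class EnrichmentResult:
    term: str
    namespace: str
    label: str
    k: int  # study hits
    n: int  # study size
    M: int  # background hits
    N: int  # background size
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def hypergeom_tail(k: int, n: int, M: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, M, n)."""
    if not (0 <= k <= n <= N and 0 <= M <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} M={M} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def enrich(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """One upper-tail hypergeometric test per term with >= 1 study hit.

    q-values are computed by BH within each namespace; results are sorted by
    p-value.  Significant iff q <= alpha.
    """
    study = set(study_genes)
    background = set(background_genes)
    missing = sorted(study - background)
    if missing:
        raise ValueError(f"study genes absent from background: {missing}")
    N = len(background)
    n = len(study)

    term_hits: Dict[str, Set[str]] = {}
    for gene in background:
        for term in annotation.gene_terms.get(gene, ()):
            term_hits.setdefault(term, set()).add(gene)

    results: List[EnrichmentResult] = []
    for term in sorted(term_hits):
        hits = term_hits[term]
        k = len(hits & study)
        if k == 0:
            continue
        M = len(hits)
        ns, label = annotation.term_info.get(term, ("default", term))
        results.append(
            EnrichmentResult(term, ns, label, k, n, M, N, hypergeom_tail(k, n, M, N))
        )
    # BH within each namespace
    by_ns: Dict[str, List[EnrichmentResult]] = {}
    for r in results:
        by_ns.setdefault(r.namespace, []).append(r)
    for rs in by_ns.values():
        qs = bh_fdr([r.p_value for r in rs])
        for r, q in zip(rs, qs):
            r.q_value = q
            r.significant = q <= alpha
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
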