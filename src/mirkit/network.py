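"""miRNA -> TF-mRNA -> metabolite correlation network over tissue profiles.

miRNA-mRNA edges use Spearman rank correlation and are kept when rho is at
most a (negative) ceiling; mRNA-metabolite edges use Pearson correlation and
are kept when |r| clears a floor.  Both require a p-value below alpha.  A
regulatory triplet is any miRNA--mRNA--metabolite path whose mRNA carries a
transcription-factor family annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats


@dataclass
class CorrelationEdge:
    source: str
    target: str
    kind: str  # "mirna-mrna" | "mrna-metabolite"
    coefficient: float
    p_value: float
    method: str  # "spearman" | "pearson"


@dataclass
class Triplet:
    mirna: str
    mrna: str
    tf_family: str
    metabolite: str
    mirna_mrna: CorrelationEdge
    mrna_metabolite: CorrelationEdge


def tf_annotate(
    gene_ids: Sequence[str], tf_table: Mapping[str, str]
) -> Dict[str, str]:
    """Annotate genes with TF families by lookup; unlisted genes are skipped."""
    return {g: tf_table[g] for g in gene_ids if g in tf_table}


def load_tf_table(rows: Sequence[Tuple[str, str]]) -> Dict[str, str]:
    """Build gene -> family from (gene, family) rows; conflicting duplicates fail."""
    table: Dict[str, str] = {}
    for gene, family in rows:
        if gene in table and table[gene] != family:
            raise ValueError(
                f"gene {gene} mapped to conflicting TF families "
                f"{table[gene]!r} and {family!r}"
            )
        table[gene] = family
    return table


def pearson_edge(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r and its two-sided t-transform p-value (n-2 df)."""
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance profile")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def spearman_edge(
    x: Sequence[float], y: Sequence[float], method: str = "approx"
) -> Tuple[float, float]:
    """Spearman rho with a t-approximation or exhaustive-permutation p-value.

    ``method="exact"`` enumerates all orderings of y's ranks (cheap at n=5)
    and reports the two-sided tail P(|rho_perm| >= |rho|).
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance profile")
    rho, p_approx = stats.spearmanr(xv, yv)
    rho = float(rho)
    if method == "approx":
        return rho, float(p_approx)
    if method != "exact":
        raise ValueError(f"unknown Spearman p-value method {method!r}")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    observed = abs(rho)
    hits = total = 0
    for perm in permutations(ry):
        r = stats.pearsonr(rx, np.asarray(perm)).statistic
        if abs(r) >= observed - 1e-12:
            hits += 1
        total += 1
    return rho, hits / total


def mrna_metabolite_edges(
    mrna_profiles: Mapping[str, Sequence[float]],
    metabolite_profiles: Mapping[str, Sequence[float]],
    r_min: float = 0.9,
    alpha: float = 0.05,
) -> List[CorrelationEdge]:
    """Pearson edges kept iff |r| > r_min and p < alpha; constant profiles skipped."""
    edges = []
    for gene in sorted(mrna_profiles):
        for met in sorted(metabolite_profiles):
            try:
                r, p = pearson_edge(mrna_profiles[gene], metabolite_profiles[met])
            except ValueError:
                continue
            if abs(r) > r_min and p < alpha:
                edges.append(CorrelationEdge(gene, met, "mrna-metabolite", r, p, "pearson"))
    return edges


def mirna_mrna_edges(
    mirna_profiles: Mapping[str, Sequence[float]],
    mrna_profiles: Mapping[str, Sequence[float]],
    rho_max: float = -0.5,
    alpha: float = 0.05,
    p_method: str = "approx",
) -> List[CorrelationEdge]:
    """Spearman edges kept iff rho <= rho_max and p < alpha."""
    edges = []
    for mirna in sorted(mirna_profiles):
        for gene in sorted(mrna_profiles):
            try:
                rho, p = spearman_edge(
                    mirna_profiles[mirna], mrna_profiles[gene], p_method
                )
            except ValueError:
                continue
            if rho <= rho_max and p < alpha:
                edges.append(CorrelationEdge(mirna, gene, "mirna-mrna", rho, p, "spearman"))
    return edges


def extract_triplets(
    mirna_mrna: Sequence[CorrelationEdge],
    mrna_metabolite: Sequence[CorrelationEdge],
    tf_annotations: Mapping[str, str],
) -> Tuple[List[Triplet], nx.Graph]:
    """Join the two edge layers through TF-annotated mRNAs.

    Returns the triplet list and a typed graph carrying every edge (TF or
    not) with correlation coefficients as weights.
    """
    graph = nx.Graph()
    by_mrna: Dict[str, List[CorrelationEdge]] = {}
    for e in mrna_metabolite:
        by_mrna.setdefault(e.source, []).append(e)
        graph.add_node(e.source, kind="mrna", tf_family=tf_annotations.get(e.source, ""))
        graph.add_node(e.target, kind="metabolite")
        graph.add_edge(
            e.source, e.target, kind=e.kind, weight=e.coefficient, p_value=e.p_value
        )
    triplets = []
    for e in mirna_mrna:
        graph.add_node(e.source, kind="mirna")
        graph.add_node(e.target, kind="mrna", tf_family=tf_annotations.get(e.target, ""))
        graph.add_edge(
            e.source, e.target, kind=e.kind, weight=e.coefficient, p_value=e.p_value
        )
        family = tf_annotations.get(e.target)
        if family is None:
            continue
        for down in by_mrna.get(e.target, []):
            triplets.append(
                Triplet(
                    mirna=e.source,
                    mrna=e.target,
                    tf_family=family,
                    metabolite=down.target,
                    mirna_mrna=e,
                    mrna_metabolite=down,
                )
            )
    return triplets, graph


def write_graph(graph: nx.Graph, graphml_path: Optional[str] = None,
                sif_path: Optional[str] = None) -> None:
    """Export the network as GraphML and/or a simple SIF-like TSV."""
    if graphml_path:
        nx.write_graphml(graph, graphml_path)
    if sif_path:
        with open(sif_path, "w") as fh:
            fh.write("source\tinteraction\ttarget\tweight\n")
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\t{data.get('weight', '')}\n")
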