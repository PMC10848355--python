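"""Ontology over-representation and semantic-similarity clustering.

Hypergeometric ORA over a true-path-closed annotation DAG, Resnik
information-content similarity (IC of the most informative common
ancestor, normalized to [0, 1] by the corpus maximum IC), greedy redundancy
pruning at a similarity threshold, recursive binary-cut clustering of the
similarity matrix, and export of the layout tables behind treemap,
word-cloud and ridge displays.  No figures are rendered here; the tables
are plain DataFrames ready for any plotting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "OntologyDAG",
    "EnrichmentResult",
    "TermClusterSet",
    "ora",
    "information_content",
    "resnik",
    "prune_redundant",
    "binary_cut",
    "display_tables",
]

ORA_P_MAX = 0.1  # raw-p retention threshold for enriched terms
SIM_THRESHOLD = 0.7  # redundancy-pruning similarity cutoff
BINARY_CUT_HOMOGENEITY = 0.85


@dataclass
class OntologyDAG:
    """Rooted acyclic is_a ontology with true-path-closed annotations.

    ``graph`` holds child -> parent edges; ``annotations`` maps each term to
    the full gene set of the term and all its descendants (true-path rule).
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]]
    root: str
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph has a cycle")
        roots = [t for t in self.graph if self.graph.out_degree(t) == 0]
        if self.root not in roots:
            raise ValueError(f"declared root {self.root!r} has parents")

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        direct_annotations: dict[str, set[str]],
        names: dict[str, str] | None = None,
    ) -> "OntologyDAG":
        """Build from child->parent edges and direct (unpropagated) annotations."""
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for t in direct_annotations:
            g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a edges form a cycle")
        roots = [t for t in g if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {roots}")
        closed: dict[str, set[str]] = {t: set(direct_annotations.get(t, set())) for t in g}
        for t in nx.topological_sort(g):  # children before parents
            for parent in g.successors(t):
                closed[parent] |= closed[t]
        return cls(
            graph=g,
            annotations={t: frozenset(s) for t, s in closed.items()},
            root=roots[0],
            names=dict(names or {}),
        )

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """Ancestors of ``term`` including the term itself."""
        return {term} | nx.descendants(self.graph, term)


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics."""

    term: str
    k: int  # query hits in the term
    K: int  # term genes in the universe
    n: int  # query size
    N: int  # universe size
    p: float
    members: frozenset[str]  # query genes annotated to the term
    mean_log2fc: float = float("nan")


@dataclass
class TermClusterSet:
    """A partition of retained terms with a representative per cluster."""

    clusters: list[frozenset[str]]
    representatives: list[str]
    tile_size: dict[str, int]

    def labels(self) -> dict[str, int]:
        return {t: i for i, members in enumerate(self.clusters) for t in members}


def information_content(dag: OntologyDAG) -> dict[str, float]:
    """IC(t) = -log(|genes(t)| / |genes(root)|); unannotated terms excluded."""
    corpus = dag.annotations[dag.root]
    if not corpus:
        raise ValueError("root term has no annotations; corpus is empty")
    ic: dict[str, float] = {}
    for t in dag.graph:
        k = len(dag.annotations.get(t, frozenset()))
        if k > 0:
            ic[t] = -math.log(k / len(corpus))
    return ic


def resnik(
    dag: OntologyDAG,
    t1: str,
    t2: str,
    ic: dict[str, float] | None = None,
    normalize: bool = True,
) -> float:
    """Resnik similarity: IC of the most informative common ancestor.

    A term counts among its own ancestors, so resnik(t, t) is IC(t).  With
    ``normalize`` the value is divided by the corpus maximum IC, mapping it
    to [0, 1]; terms whose only shared ancestor is the root score 0.
    """
    if ic is None:
        ic = information_content(dag)
    if t1 not in ic or t2 not in ic:
        raise ValueError(f"term without defined IC: {t1 if t1 not in ic else t2!r}")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = {t for t in common if t in ic}
    if not common:
        return 0.0
    raw = max(ic[t] for t in common)
    if not normalize:
        return raw
    max_ic = max(ic.values())
    return raw / max_ic if max_ic > 0 else 0.0


def similarity_matrix(dag: OntologyDAG, terms: list[str], normalize: bool = True) -> pd.DataFrame:
    """Pairwise normalized Resnik similarity over ``terms``."""
    ic = information_content(dag)
    n = len(terms)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = resnik(dag, terms[i], terms[j], ic=ic, normalize=normalize)
            sim[i, j] = sim[j, i] = s
    return pd.DataFrame(sim, index=terms, columns=terms)


def ora(
    query: set[str],
    universe: set[str],
    dag: OntologyDAG,
    p_max: float = ORA_P_MAX,
    log2fc: dict[str, float] | None = None,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each term.

    ``p = P(X >= k)`` with X hypergeometric(N, K, n); terms with k = 0 or
    p >= p_max are dropped.  The p-values are deliberately unadjusted (the
    retention rule is a raw p threshold); callers wanting an FDR column can
    apply :func:`bpomics.stats.bh_adjust` to the returned p's.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if not query:
        return []
    N, n = len(universe), len(query)
    results = []
    for term in dag.terms:
        genes = dag.annotations.get(term, frozenset()) & universe
        K = len(genes)
        if K == 0:
            continue
        members = genes & query
        k = len(members)
        if k == 0:
            continue
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        if p < p_max:
            mean_lfc = (
                float(np.mean([log2fc[g] for g in members if g in log2fc]))
                if log2fc
                else float("nan")
            )
            results.append(
                EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=p, members=frozenset(members),
                                 mean_log2fc=mean_lfc)
            )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def prune_redundant(
    term_p: dict[str, float],
    sim: pd.DataFrame,
    threshold: float = SIM_THRESHOLD,
) -> list[str]:
    """Greedy redundancy pruning at a similarity threshold.

    Terms are visited by ascending p (ties broken by term id); a term is
    kept iff its similarity to every already-kept term is below
    ``threshold``.  Deterministic and order-independent by construction.
    """
    kept: list[str] = []
    for term in sorted(term_p, key=lambda t: (term_p[t], t)):
        if all(sim.loc[term, other] < threshold for other in kept):
            kept.append(term)
    return kept


def _binary_cut_recurse(
    sim: np.ndarray, idx: np.ndarray, homogeneity: float, min_size: int
) -> list[np.ndarray]:
    if idx.size < min_size:
        return [idx]
    block = sim[np.ix_(idx, idx)]
    off = block[~np.eye(idx.size, dtype=bool)]
    if off.size == 0 or off.mean() >= homogeneity:
        return [idx]
    dist = squareform(np.clip(1.0 - block, 0.0, None), checks=False)
    z = hierarchy.linkage(dist, method="average")
    split = hierarchy.fcluster(z, t=2, criterion="maxclust")
    left, right = idx[split == 1], idx[split == 2]
    if left.size == 0 or right.size == 0:  # degenerate linkage: stop
        return [idx]
    return _binary_cut_recurse(sim, left, homogeneity, min_size) + _binary_cut_recurse(
        sim, right, homogeneity, min_size
    )


def binary_cut(
    sim: pd.DataFrame,
    homogeneity: float = BINARY_CUT_HOMOGENEITY,
    min_size: int = 3,
    term_p: dict[str, float] | None = None,
    term_size: dict[str, int] | None = None,
) -> TermClusterSet:
    """Binary-cut clustering of a semantic-similarity matrix.

    The average-linkage dendrogram of 1 - sim is bipartitioned recursively;
    a block becomes a cluster once its mean off-diagonal similarity reaches
    ``homogeneity`` or it holds fewer than ``min_size`` terms.  The
    representative of each cluster is its smallest-p member (term id as the
    tie-break, or plain lexicographic order when no p's are given).
    """
    terms = list(sim.index)
    if sim.shape[0] != sim.shape[1] or list(sim.columns) != terms:
        raise ValueError("similarity matrix must be square with matching labels")
    mat = sim.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    if len(terms) == 0:
        return TermClusterSet(clusters=[], representatives=[], tile_size={})
    # stable order: sort terms so a permuted input yields the same partition
    order = np.argsort(np.array(terms))
    mat = mat[np.ix_(order, order)]
    terms = [terms[i] for i in order]
    blocks = _binary_cut_recurse(mat, np.arange(len(terms)), homogeneity, min_size)
    clusters = [frozenset(terms[i] for i in b) for b in blocks]
    clusters.sort(key=lambda c: min(c))
    reps = []
    for members in clusters:
        if term_p:
            reps.append(min(members, key=lambda t: (term_p.get(t, 1.0), t)))
        else:
            reps.append(min(members))
    sizes = {t: (term_size or {}).get(t, 0) for t in sim.index}
    return TermClusterSet(clusters=clusters, representatives=reps, tile_size=sizes)


def display_tables(
    results: list[EnrichmentResult],
    clusters: TermClusterSet,
    log2fc: dict[str, float],
) -> dict[str, pd.DataFrame]:
    """Layout tables for treemap, word-cloud and ridge displays.

    treemap: one row per clustered term — tile size is the term's gene
    count in the universe, cluster area its cluster's term count.
    words: one row per gene of any enriched term — frequency is the number
    of enriched terms containing it, sign follows its log2 fold change.
    ridge: one row per enriched term with its members' fold changes and
    their mean.
    """
    by_term = {r.term: r for r in results}
    labels = clusters.labels()
    treemap_rows = []
    for term, cl in labels.items():
        r = by_term.get(term)
        treemap_rows.append(
            {
                "term": term,
                "cluster": cl,
                "representative": clusters.representatives[cl],
                "tile_size": r.K if r else clusters.tile_size.get(term, 0),
                "cluster_area": len(clusters.clusters[cl]),
            }
        )
    treemap = pd.DataFrame(treemap_rows)

    freq: dict[str, int] = {}
    for r in results:
        for g in r.members:
            freq[g] = freq.get(g, 0) + 1
    words = pd.DataFrame(
        [
            {
                "gene": g,
                "frequency": f,
                "sign": "up" if log2fc.get(g, 0.0) > 0 else "down",
                "log2fc": log2fc.get(g, float("nan")),
            }
            for g, f in sorted(freq.items())
        ]
    )

    ridge = pd.DataFrame(
        [
            {
                "term": r.term,
                "members": ",".join(sorted(r.members)),
                "log2fc_values": ",".join(f"{log2fc[g]:.6g}" for g in sorted(r.members) if g in log2fc),
                "mean_log2fc": float(np.mean([log2fc[g] for g in r.members if g in log2fc]))
                if any(g in log2fc for g in r.members)
                else float("nan"),
            }
            for r in results
        ]
    )
    return {"treemap": treemap, "words": words, "ridge": ridge}
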