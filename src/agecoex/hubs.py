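"""Hub gene ranking by Maximal Clique Centrality (MCC).

MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.  Scores
are exact arbitrary-precision integers — a node sitting in a single clique
of size c scores exactly (c - 1)!, which overflows floats quickly.  Clique
enumeration uses Bron-Kerbosch with pivoting (via networkx) and is guarded
by a node-count ceiling because it is exponential in the worst case.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

log = logging.getLogger("agecoex")

#: Default ceiling on graph size for clique enumeration.
MAX_CLIQUE_NODES = 2000


def induced_subgraph(g: nx.Graph, genes) -> nx.Graph:
    """Subgraph on the given genes; absent genes are ignored with a warning."""
    genes = list(genes)
    present = [x for x in genes if x in g]
    absent = len(genes) - len(present)
    if absent:
        log.warning("induced_subgraph: %d of %d genes absent from graph", absent, len(genes))
    if not present:
        raise ValueError("no requested genes present in the graph")
    return nx.Graph(g.subgraph(present))


def maximal_cliques(g: nx.Graph) -> list[tuple]:
    """All maximal cliques, canonicalized (members sorted, cliques sorted).

    Isolated nodes yield singleton cliques.
    """
    if any(g.has_edge(v, v) for v in g):
        raise ValueError("graph must be simple (self-loop found)")
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


def mcc_scores(g: nx.Graph, isolated_score: int = 1, max_nodes: int = MAX_CLIQUE_NODES) -> dict:
    """Exact-integer MCC score for every node.

    ``isolated_score`` sets the convention for nodes in no edge (their only
    maximal clique is the singleton, (1-1)! = 1 by default; 0 available).
    """
    if g.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes, above the clique-enumeration "
            f"ceiling {max_nodes}; raise max_nodes explicitly if intended"
        )
    scores: dict = {v: 0 for v in g.nodes}
    for clique in maximal_cliques(g):
        if len(clique) == 1:
            scores[clique[0]] += isolated_score
        else:
            w = math.factorial(len(clique) - 1)
            for v in clique:
                scores[v] += w
    return scores


def top_hubs(scores: dict, g: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Top-k genes by (MCC desc, degree desc, gene ID asc); deterministic.

    Returns a frame with gene, mcc (exact integer), log10_mcc, degree.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        log.warning("top_hubs: k=%d exceeds node count %d; returning all", k, len(scores))
        k = len(scores)
    ranked = sorted(scores, key=lambda v: (-scores[v], -g.degree(v), str(v)))[:k]
    rows = [
        {
            "gene": v,
            "mcc": scores[v],
            "log10_mcc": math.log10(scores[v]) if scores[v] > 0 else float("-inf"),
            "degree": g.degree(v),
        }
        for v in ranked
    ]
    return pd.DataFrame(rows)


def rank_module_hubs(g: nx.Graph, genes, k: int = 5) -> pd.DataFrame:
    """Convenience: induce the module subnetwork and rank its hubs."""
    sub = induced_subgraph(g, genes)
    return top_hubs(mcc_scores(sub), sub, k)
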