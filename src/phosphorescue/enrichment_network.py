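"""Gene-set enrichment and dense-module (MCODE) detection.

Enrichment is the upper-tail hypergeometric test of a query gene set against
each term of a GMT collection, with Benjamini–Hochberg adjustment across
terms.  Module detection follows the published MCODE scheme: each node is
weighted by the product of the highest k-core number of its closed
neighbourhood and that core's density, then seeds are expanded in descending
weight order, admitting neighbours whose weight is within ``1 -
node_score_cutoff`` of the seed's.  Ties are broken by node identifier so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    terms: dict[str, tuple[str, frozenset]]  # term_id -> (name, members)
    universe: frozenset

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None):
        terms = {}
        members_union = set()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            term_id, name, members = parts[0], parts[1], frozenset(parts[2:])
            terms[term_id] = (name, members)
            members_union |= members
        uni = frozenset(universe) if universe is not None else frozenset(members_union)
        return cls.restrict(cls(terms, uni), uni)

    @staticmethod
    def restrict(collection: "GeneSetCollection", universe: frozenset):
        terms = {}
        for term_id, (name, members) in collection.terms.items():
            restricted = members & universe
            if restricted:
                terms[term_id] = (name, restricted)
        return GeneSetCollection(terms, universe)


@dataclass
class EnrichmentRow:
    term_id: str
    name: str
    k_overlap: int
    n_query: int
    K_term: int
    N_universe: int
    p_hypergeom: float
    p_adjusted: float
    fold: float


@dataclass
class NetworkModule:
    nodes: frozenset
    seed: str
    density: float
    mcode_score: float


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_term_size: int = 1,
    max_term_size: int | None = None,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment with BH adjustment.

    Query genes outside the universe are dropped (with the drop reflected in
    ``n_query``).  Rows sorted by (p, term_id).
    """
    query_set = set(query) & set(collection.universe)
    if not query_set:
        return []
    N = len(collection.universe)
    n = len(query_set)
    rows = []
    for term_id in sorted(collection.terms):
        name, members = collection.terms[term_id]
        K = len(members)
        if K < min_term_size or (max_term_size is not None and K > max_term_size):
            continue
        k = len(query_set & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if K else 0.0
        rows.append(
            EnrichmentRow(term_id, name, k, n, K, N, p, float("nan"), fold)
        )
    if not rows:
        return []
    adjusted = multipletests([r.p_hypergeom for r in rows], method="fdr_bh")[1]
    for row, adj in zip(rows, adjusted):
        row.p_adjusted = float(adj)
    rows.sort(key=lambda r: (r.p_hypergeom, r.term_id))
    return rows


def _graph_density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_weight(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weights: highest-core number x highest-core density of
    the closed neighbourhood.  Nodes with degree below ``degree_cutoff``
    weigh 0 (they can still join modules, but never seed them)."""
    weights = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = set(graph.neighbors(v)) | {v}
        sub = graph.subgraph(nbhd)
        core = nx.core_number(sub)
        kmax = max(core.values())
        if kmax == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core.items() if c >= kmax]
        weights[v] = kmax * _graph_density(graph.subgraph(core_nodes))
    return weights


def mcode_find_modules(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    degree_cutoff: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
    min_module_size: int = 3,
) -> list[NetworkModule]:
    """Detect densely connected modules by greedy seed expansion.

    Seeds are processed in descending weight (node id breaks ties); BFS
    admits a neighbour when its weight is at least ``(1 - node_score_cutoff)``
    times the seed weight and it is not already claimed.  ``haircut``
    removes singly connected nodes from each module.  Modules smaller than
    ``min_module_size`` after trimming are discarded (their nodes stay
    claimed, as in the published algorithm).
    """
    if not 0.0 <= node_score_cutoff < 1.0:
        raise ValueError("node_score_cutoff must be in [0, 1)")
    if degree_cutoff < 0 or max_depth < 1:
        raise ValueError("invalid degree_cutoff or max_depth")
    if nx.number_of_selfloops(graph):
        raise ValueError("graph must not contain self-loops")
    weights = mcode_weight(graph, degree_cutoff)
    visited: set = set()
    modules: list[NetworkModule] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            node, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for nb in sorted(graph.neighbors(node), key=str):
                if nb in visited or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    frontier.append((nb, depth + 1))
        visited |= members
        sub = graph.subgraph(members).copy()
        if haircut:
            to_drop = [v for v in sub.nodes if sub.degree(v) < 2]
            sub.remove_nodes_from(to_drop)
        if fluff:
            fringe = set()
            for v in list(sub.nodes):
                for nb in graph.neighbors(v):
                    if nb not in sub and nb not in visited:
                        nbhd = set(graph.neighbors(nb)) | {nb}
                        if _graph_density(graph.subgraph(nbhd)) >= 0.5:
                            fringe.add(nb)
            sub = graph.subgraph(set(sub.nodes) | fringe).copy()
        if sub.number_of_nodes() < min_module_size:
            continue
        density = _graph_density(sub)
        modules.append(
            NetworkModule(
                nodes=frozenset(sub.nodes),
                seed=seed,
                density=density,
                mcode_score=density * sub.number_of_nodes(),
            )
        )
    return modules


def annotate_modules(
    modules: Sequence[NetworkModule],
    collection: GeneSetCollection,
    node_to_gene: Mapping[str, str] | None = None,
) -> list[tuple[NetworkModule, EnrichmentRow | None]]:
    """Top enrichment term per module (adjusted p, then raw p, then term id)."""
    out = []
    for module in modules:
        genes = (
            {node_to_gene.get(n, n) for n in module.nodes}
            if node_to_gene
            else set(module.nodes)
        )
        if not genes & set(collection.universe):
            out.append((module, None))
            continue
        rows = hypergeom_enrich(genes, collection)
        if not rows:
            out.append((module, None))
            continue
        rows.sort(key=lambda r: (r.p_adjusted, r.p_hypergeom, r.term_id))
        out.append((module, rows[0]))
    return out


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV edge list -> simple undirected graph (self-loops dropped)."""
    graph = nx.Graph()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path} line {i}: expected two tab-separated columns")
        a, b = parts[0].strip(), parts[1].strip()
        if a != b:
            graph.add_edge(a, b)
    return graph


def enrichment_to_table(rows: Sequence[EnrichmentRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "overlap": r.k_overlap,
                "query_size": r.n_query,
                "term_size": r.K_term,
                "universe_size": r.N_universe,
                "p_hypergeom": r.p_hypergeom,
                "p_adjusted": r.p_adjusted,
                "fold": r.fold,
            }
            for r in rows
        ],
        columns=[
            "term_id",
            "name",
            "overlap",
            "query_size",
            "term_size",
            "universe_size",
            "p_hypergeom",
            "p_adjusted",
            "fold",
        ],
    )
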