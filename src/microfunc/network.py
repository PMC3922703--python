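"""Co-presence networks of core and non-core functional genes.

Core networks link genes whose normalized signal intensities are positively
correlated across a host group's samples (Pearson).  Non-core sub-networks
are restricted to a metabolic pathway group (Carbon-, AA- or
Nitrogen-associated) and link genes whose 0/1 presence profiles are
positively associated (phi coefficient, i.e. Pearson on binary profiles).
Only positive associations at or above the threshold become edges; modules
are connected components by default, with greedy modularity communities as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import PATHWAY_GROUPS

__all__ = [
    "CoPresenceNetwork",
    "NetworkSummary",
    "build_core_network",
    "build_noncore_subnetwork",
    "detect_modules",
    "summarize_network",
    "largest_module_overlap",
]

DEFAULT_MIN_CORR = 0.8


@dataclass
class CoPresenceNetwork:
    """An undirected gene graph with positive-association edges.

    ``graph`` nodes carry ``kind`` ("core"/"noncore") and ``category``
    attributes; edges carry ``score`` (the association value).  ``modules``
    maps gene -> module id once :func:`detect_modules` has run (isolated
    nodes are left unassigned).
    """

    graph: nx.Graph
    group: str | None = None
    kind: str = "core"
    pathway_scope: str | None = None
    min_score: float = DEFAULT_MIN_CORR
    modules: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "score": d["score"],
                "module": self.modules.get(a, 0),
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "module"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "kind": d.get("kind", ""),
                "category": d.get("category", ""),
                "degree": self.graph.degree(g),
                "module": self.modules.get(g, 0),
            }
            for g, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene", "kind", "category", "degree", "module"])


def _positive_edges(values: np.ndarray, genes, min_score: float):
    """Edges (i, j, r) with Pearson r >= min_score and r > 0.

    Rows with zero variance get no edges (their correlation is undefined).
    """
    sd = values.std(axis=1)
    ok = sd > 0
    edges = []
    if ok.sum() >= 2:
        sub = values[ok]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        idx = np.flatnonzero(ok)
        iu, ju = np.triu_indices(len(idx), k=1)
        keep = (corr[iu, ju] >= min_score) & (corr[iu, ju] > 0)
        for i, j in zip(iu[keep], ju[keep]):
            edges.append((genes[idx[i]], genes[idx[j]], float(corr[i, j])))
    return edges


def build_core_network(
    normalized: pd.DataFrame,
    core_genes,
    group_samples,
    annotation: pd.DataFrame | None = None,
    min_abs_corr: float = DEFAULT_MIN_CORR,
    group: str | None = None,
) -> CoPresenceNetwork:
    """Co-presence network of core genes from normalized intensities.

    An edge links two core genes whose intensity profiles across the
    group's samples have Pearson correlation >= ``min_abs_corr`` (positive
    associations only).  Constant-profile genes stay as isolated nodes.
    """
    group_samples = list(group_samples)
    if len(group_samples) < 3:
        raise ValueError("need at least 3 samples to correlate profiles")
    core_genes = pd.Index(core_genes)
    if len(core_genes) == 0:
        raise ValueError("core gene set is empty")
    values = np.asarray(normalized.loc[core_genes, group_samples], dtype=float)
    G = nx.Graph()
    for g in core_genes:
        cat = annotation.loc[g, "category"] if annotation is not None else ""
        G.add_node(g, kind="core", category=cat)
    G.add_weighted_edges_from(
        _positive_edges(values, list(core_genes), min_abs_corr), weight="score"
    )
    return CoPresenceNetwork(G, group=group, kind="core", min_score=min_abs_corr)


def build_noncore_subnetwork(
    noncore_binary: pd.DataFrame,
    annotation: pd.DataFrame,
    pathway_group: str,
    group_samples,
    min_abs_corr: float = DEFAULT_MIN_CORR,
    group: str | None = None,
) -> CoPresenceNetwork:
    """Pathway-scoped co-presence network of non-core genes (phi edges).

    Nodes are the non-core genes whose functional category belongs to the
    requested pathway group (``"Carbon"``, ``"AA"`` or ``"Nitrogen"``).
    Association is the phi coefficient of the 0/1 presence profiles over
    the group's samples; only positive phi >= threshold becomes an edge.
    Genes present in all or none of the group's samples are isolated.
    """
    if pathway_group not in PATHWAY_GROUPS:
        raise ValueError(
            f"unknown pathway group {pathway_group!r}; expected one of "
            f"{sorted(PATHWAY_GROUPS)}"
        )
    cats = PATHWAY_GROUPS[pathway_group]
    genes = [
        g
        for g in noncore_binary.index
        if annotation.loc[g, "category"] in cats
    ]
    if not genes:
        raise ValueError(f"no non-core genes in pathway group {pathway_group!r}")
    group_samples = list(group_samples)
    values = np.asarray(noncore_binary.loc[genes, group_samples], dtype=float)
    G = nx.Graph()
    for g in genes:
        G.add_node(g, kind="noncore", category=annotation.loc[g, "category"])
    G.add_weighted_edges_from(
        _positive_edges(values, genes, min_abs_corr), weight="score"
    )
    return CoPresenceNetwork(
        G,
        group=group,
        kind="noncore",
        pathway_scope=pathway_group,
        min_score=min_abs_corr,
    )


def detect_modules(
    network: CoPresenceNetwork, method: str = "components"
) -> dict:
    """Assign module ids to the network's connected (non-isolated) nodes.

    ``method="components"`` (default) takes connected components of the
    thresholded graph; ``method="greedy_modularity"`` refines them with
    networkx greedy modularity communities.  Isolated nodes get no module.
    Ids are 1-based, ordered by decreasing module size with ties broken by
    the lexicographically smallest member gene, so the labeling is stable
    under node reordering.
    """
    G = network.graph
    connected = [n for n in G.nodes if G.degree(n) > 0]
    sub = G.subgraph(connected)
    if method == "components":
        groups = [set(c) for c in nx.connected_components(sub)]
    elif method == "greedy_modularity":
        groups = (
            [set(c) for c in nx.community.greedy_modularity_communities(sub)]
            if sub.number_of_edges()
            else []
        )
    else:
        raise ValueError(f"unknown module method: {method!r}")
    groups.sort(key=lambda c: (-len(c), min(map(str, c))))
    modules = {}
    for mid, members in enumerate(groups, start=1):
        for g in members:
            modules[g] = mid
    network.modules = modules
    return modules


@dataclass
class NetworkSummary:
    n_modules: int
    n_nodes: int
    n_edges: int
    largest_module_nodes: int
    largest_module_edges: int
    top_categories: list

    def as_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "largest_module_nodes": self.largest_module_nodes,
            "largest_module_edges": self.largest_module_edges,
            "top_categories": list(self.top_categories),
        }


def summarize_network(network: CoPresenceNetwork) -> NetworkSummary:
    """Module counts, largest-module size and top-five categories.

    Nodes are counted over the whole scoped graph; module statistics cover
    the connected nodes only.  ``top_categories`` lists the five most
    frequent node categories (count-descending, name as tie-break).
    """
    if not network.modules and network.n_edges:
        detect_modules(network)
    mods = network.modules
    n_modules = len(set(mods.values())) if mods else 0
    largest_nodes = largest_edges = 0
    if n_modules:
        members = [g for g, m in mods.items() if m == 1]
        largest_nodes = len(members)
        largest_edges = network.graph.subgraph(members).number_of_edges()
    cats = pd.Series(
        [d.get("category", "") for _, d in network.graph.nodes(data=True)]
    )
    counts = cats.value_counts()
    top = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[:5]
    return NetworkSummary(
        n_modules=n_modules,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        largest_module_nodes=largest_nodes,
        largest_module_edges=largest_edges,
        top_categories=[c for c, _ in top],
    )


def largest_module_overlap(net_a: CoPresenceNetwork, net_b: CoPresenceNetwork) -> float:
    """Shared-gene percentage between two largest modules.

    Reported relative to the smaller of the two modules (100 * |A∩B| /
    min(|A|, |B|)).
    """
    for net in (net_a, net_b):
        if not net.modules:
            detect_modules(net)
    a = {g for g, m in net_a.modules.items() if m == 1}
    b = {g for g, m in net_b.modules.items() if m == 1}
    if not a or not b:
        raise ValueError("both networks need a nonempty largest module")
    return 100.0 * len(a & b) / min(len(a), len(b))
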