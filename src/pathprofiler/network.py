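"""Focus-protein interaction networks.

Differentially expressed (focus) proteins are overlaid on a curated
protein-protein interaction graph and connected subnetworks are grown
greedily so as to include as many focus proteins as possible, adding
non-focus connector proteins only where connectivity requires them.  Each
network is scored as -log10 of the right-tail hypergeometric probability
of containing that many focus nodes by chance; a score of 6 or greater
(p < 1e-6) flags a significant network.  Nodes of degree <= 1 within a
network are "hanging": swept up via a single link without forming a loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .enrichment import ContingencyTable, bh_adjust, fisher_right_tail

SCORE_CUTOFF = 6.0
DEFAULT_MAX_SIZE = 35


@dataclass
class FocusNetwork:
    """A connected focus subnetwork of the interaction graph."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    focus_nodes: set[str]
    max_size: int = DEFAULT_MAX_SIZE
    score: float = 0.0
    p_value: float = 1.0

    @property
    def hanging(self) -> set[str]:
        return classify_hanging(self)

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)


def _induced_edges(graph: nx.Graph, nodes: set[str]
                   ) -> set[tuple[str, str]]:
    return {tuple(sorted((a, b)))
            for a, b in graph.subgraph(nodes).edges()}


def grow_network(graph: nx.Graph, focus: set[str],
                 max_size: int = DEFAULT_MAX_SIZE) -> FocusNetwork:
    """Grow one connected network around the focus proteins.

    Seeding and growth are deterministic: the seed is the focus node with
    the most focus neighbors (ties to the first accession in sorted
    order).  Each step adds the neighbor of the current node set that
    (1) newly connects the most focus nodes (itself if focus, plus focus
    neighbors not yet included), then (2) has maximal degree into the
    set, then (3) is first in accession order.  When no neighbor adds
    focus connectivity but unreached focus nodes remain in the component,
    the step walks toward the nearest one.  Growth stops at ``max_size``
    or when every reachable focus node is included.
    """
    focus_in = set(focus) & set(graph.nodes)
    if not focus_in:
        raise ValueError("no focus protein maps onto the interaction graph")
    seed = min(focus_in,
               key=lambda f: (-sum(nb in focus_in
                                   for nb in graph.neighbors(f)), f))
    nodes = {seed}
    reachable = nx.node_connected_component(graph, seed) & focus_in
    while len(nodes) < max_size and not reachable <= nodes:
        frontier = {nb for n in nodes for nb in graph.neighbors(n)} - nodes
        if not frontier:
            break

        def gain(v: str) -> int:
            new = int(v in focus_in)
            new += sum(nb in focus_in and nb not in nodes
                       for nb in graph.neighbors(v))
            return new

        best_gain = max(gain(v) for v in frontier)
        if best_gain > 0:
            pick = min(frontier,
                       key=lambda v: (-gain(v),
                                      -sum(nb in nodes
                                           for nb in graph.neighbors(v)),
                                      v))
        else:
            # steer toward the nearest unreached focus node
            dist = nx.multi_source_dijkstra_path_length(
                graph, reachable - nodes)
            pick = min(frontier,
                       key=lambda v: (dist.get(v, math.inf),
                                      -sum(nb in nodes
                                           for nb in graph.neighbors(v)),
                                      v))
        nodes.add(pick)
    return FocusNetwork(nodes=nodes, edges=_induced_edges(graph, nodes),
                        focus_nodes=nodes & focus_in, max_size=max_size)


def score_from_p(p: float) -> float:
    """Network significance score: -log10 of the enrichment p-value."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return -math.log10(p)


def score_network(network: FocusNetwork, total_focus: int,
                  graph_size: int) -> FocusNetwork:
    """Score a network against the whole interaction graph.

    The p-value is the right-tail hypergeometric probability of drawing
    at least the observed number of focus nodes in a uniform sample of
    the network's size from a graph with ``total_focus`` focus nodes
    among ``graph_size``; the score is -log10(p).  Score >= 6 (p < 1e-6)
    is the conventional significance cutoff.  Fills ``p_value`` and
    ``score`` in place and returns the network.
    """
    table = ContingencyTable(k=len(network.focus_nodes),
                             n=len(network.nodes),
                             K=total_focus, N=graph_size)
    network.p_value = fisher_right_tail(table)
    network.score = score_from_p(network.p_value)
    return network


def classify_hanging(network: FocusNetwork) -> set[str]:
    """Nodes connected to at most one other node within the network."""
    return {n for n in network.nodes if network.degree(n) <= 1}


def extract_networks(graph: nx.Graph, focus: set[str],
                     max_size: int = DEFAULT_MAX_SIZE
                     ) -> list[FocusNetwork]:
    """Emit successive networks until the focus set is exhausted.

    After each network its focus nodes are retired and growth repeats on
    the remainder; each network is scored against the full graph, and the
    p-values are Benjamini-Hochberg adjusted across the emitted networks
    (the adjusted p replaces ``p_value`` and the score is recomputed).
    """
    total_focus = len(set(focus) & set(graph.nodes))
    graph_size = graph.number_of_nodes()
    remaining = set(focus) & set(graph.nodes)
    networks: list[FocusNetwork] = []
    while remaining:
        net = grow_network(graph, remaining, max_size)
        score_network(net, total_focus, graph_size)
        networks.append(net)
        remaining -= net.focus_nodes
    if networks:
        adjusted = bh_adjust([n.p_value for n in networks])
        for net, q in zip(networks, adjusted):
            net.p_value = float(q)
            net.score = score_from_p(net.p_value)
    networks.sort(key=lambda n: (-n.score, -len(n.focus_nodes)))
    return networks


def network_summary(networks: list[FocusNetwork]) -> pd.DataFrame:
    """Summary table: one row per network with size, focus count, score
    and significance at the score >= 6 convention."""
    return pd.DataFrame(
        [{"network_id": i + 1, "size": len(n.nodes),
          "focus_count": len(n.focus_nodes), "score": n.score,
          "significant": n.score >= SCORE_CUTOFF,
          "n_hanging": len(n.hanging)}
         for i, n in enumerate(networks)])


def node_attributes(network: FocusNetwork) -> pd.DataFrame:
    """Per-node attribute table (accession, is_focus, degree, hanging)."""
    hanging = network.hanging
    return pd.DataFrame(
        [{"accession": n, "is_focus": n in network.focus_nodes,
          "degree": network.degree(n), "hanging": n in hanging}
         for n in sorted(network.nodes)])
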