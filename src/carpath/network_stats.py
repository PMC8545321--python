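"""Graph-theoretical diagnostics of the pair network.

Statistics are computed on the thresholded, unweighted view of the
network (edges with CAR strictly above the cutoff): node/edge counts,
number of disjoint components, size and diameter of the biggest
component, and a connectivity pre-check that warns when a source and
target compound sit in different components -- a search between them
cannot yield an atom-conserving route at that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx

from carpath.graph_model import PairGraph, threshold_subgraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkReport:
    """Summary statistics of a thresholded pair network.

    ``n_directed_arcs`` counts each undirected edge twice (the directed-
    graph convention some tools report).  Fractions are percentages of
    the thresholded graph's node/edge totals.
    """

    n_nodes: int
    n_edges: int
    n_directed_arcs: int
    car_threshold: float
    n_components: int
    biggest_component_nodes: int
    biggest_component_edges: int
    node_fraction: float
    edge_fraction: float
    diameter: int

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"nodes: {self.n_nodes}\n"
            f"edges: {self.n_edges} ({self.n_directed_arcs} directed arcs)\n"
            f"CAR threshold: {self.car_threshold}\n"
            f"components: {self.n_components}\n"
            f"biggest component: {self.biggest_component_nodes} nodes "
            f"({self.node_fraction:.0f}%), {self.biggest_component_edges} edges "
            f"({self.edge_fraction:.0f}%)\n"
            f"diameter: {self.diameter}"
        )


def analyze_network(graph: PairGraph, car_threshold: float) -> NetworkReport:
    """Compute :class:`NetworkReport` on the thresholded view of ``graph``.

    The biggest component is selected by node count (ties broken by edge
    count, then smallest node id); its diameter is the exact longest
    shortest path in hops, via all-pairs BFS.
    """
    tg = threshold_subgraph(graph, car_threshold).graph
    n_nodes = tg.number_of_nodes()
    n_edges = tg.number_of_edges()
    if n_nodes == 0:
        logger.warning("thresholded network is empty at CAR > %s", car_threshold)
        return NetworkReport(0, 0, 0, car_threshold, 0, 0, 0, 0.0, 0.0, 0)
    components = sorted(
        (tg.subgraph(c) for c in nx.connected_components(tg)),
        key=lambda sg: (-sg.number_of_nodes(), -sg.number_of_edges(), min(sg)),
    )
    biggest = components[0]
    bc_nodes = biggest.number_of_nodes()
    bc_edges = biggest.number_of_edges()
    diameter = nx.diameter(biggest) if bc_nodes > 1 else 0
    return NetworkReport(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_directed_arcs=2 * n_edges,
        car_threshold=car_threshold,
        n_components=len(components),
        biggest_component_nodes=bc_nodes,
        biggest_component_edges=bc_edges,
        node_fraction=100.0 * bc_nodes / n_nodes,
        edge_fraction=100.0 * bc_edges / n_edges if n_edges else 0.0,
        diameter=diameter,
    )


@dataclass(frozen=True)
class ConnectivityResult:
    connected: bool
    message: str


def connectivity_check(
    graph: PairGraph, source: str, target: str, car_threshold: float
) -> ConnectivityResult:
    """Warn when source and target are disconnected at the given threshold.

    The full weighted search may still be attempted, but no route whose
    every step exceeds the CAR cutoff can exist.  Unknown ids raise
    ``KeyError``.
    """
    s = graph.resolve(source)
    t = graph.resolve(target)
    tg = threshold_subgraph(graph, car_threshold).graph
    if s in tg and t in tg and nx.has_path(tg, s, t):
        return ConnectivityResult(True, "source and target are connected")
    msg = (
        f"{source} and {target} lie in different components at "
        f"CAR > {car_threshold}; no atom-conserving route exists at this threshold"
    )
    logger.warning(msg)
    return ConnectivityResult(False, msg)
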