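"""k-shortest loop-less pathway search on the CAR-weighted pair graph.

The search enumerates simple paths in order of total CAR-derived distance
(Yen's k-shortest loop-less paths, via networkx) and ranks them by
pathway score -- the sum of per-step distances.  Lower scores mean
shorter, more atom-conserving routes.  The average CAR over the steps
summarizes pathway quality on the original [0, 1] scale.

A two-sided breadth-first mode on a thresholded, unweighted view of the
graph serves as a fast benchmark: paths are ranked purely by hop count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from carpath.graph_model import PairGraph, transform_distance

logger = logging.getLogger(__name__)

#: score difference below which two pathways are treated as tied
SCORE_TOL = 1e-9


@dataclass(frozen=True)
class Pathway:
    """One loop-less route from source to target.

    ``reaction_sequence`` keeps the full set of reactions supporting each
    step; reports print one representative (the smallest id).
    """

    node_sequence: tuple[str, ...]
    reaction_sequence: tuple[frozenset[str], ...]
    step_cars: tuple[float, ...]
    step_distances: tuple[float, ...]
    score: float
    average_car: float
    rank: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.node_sequence) - 1

    def representative_reactions(self) -> tuple[str, ...]:
        return tuple(min(step) for step in self.reaction_sequence)


@dataclass(frozen=True)
class SearchQuery:
    source: str
    target: str
    k: int = 10
    max_length: int = 100
    transform: str = "default"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")


def score_pathway(
    edge_cars: Sequence[float], transform: str = "default"
) -> tuple[float, float]:
    """Pathway score and average CAR from the per-step CARs.

    score = sum of transformed distances; average_car = arithmetic mean.
    """
    if len(edge_cars) == 0:
        raise ValueError("a pathway must have at least one step")
    distances = [transform_distance(c, transform) for c in edge_cars]
    return sum(distances), sum(edge_cars) / len(edge_cars)


def _path_record(graph: PairGraph, nodes: Sequence[str]) -> Pathway:
    g = graph.graph
    cars, dists, rxns = [], [], []
    for a, b in zip(nodes[:-1], nodes[1:]):
        data = g.edges[a, b]
        cars.append(data["car"])
        dists.append(data["distance"])
        rxns.append(data["reaction_ids"])
    return Pathway(
        node_sequence=tuple(nodes),
        reaction_sequence=tuple(rxns),
        step_cars=tuple(cars),
        step_distances=tuple(dists),
        score=sum(dists),
        average_car=sum(cars) / len(cars),
    )


def _sorted_ranked(paths: list[Pathway], k: int) -> list[Pathway]:
    """Deterministic ordering: score, then length, then lexicographic nodes.

    Scores within SCORE_TOL of each other count as tied.
    """
    paths = sorted(paths, key=lambda p: p.score)
    out: list[Pathway] = []
    i = 0
    while i < len(paths):
        j = i
        while j + 1 < len(paths) and paths[j + 1].score - paths[j].score <= SCORE_TOL:
            j += 1
        out.extend(
            sorted(paths[i:j + 1], key=lambda p: (p.length, p.node_sequence))
        )
        i = j + 1
    return [replace(p, rank=r) for r, p in enumerate(out[:k], start=1)]


def _enumerate(
    graph: PairGraph, query: SearchQuery, weight: Optional[str]
) -> list[Pathway]:
    source = graph.resolve(query.source)
    target = graph.resolve(query.target)
    if not nx.has_path(graph.graph, source, target):
        logger.warning(
            "no route: %s and %s lie in different components of the network",
            query.source, query.target,
        )
        return []
    kept: list[Pathway] = []
    bound = None
    for nodes in nx.shortest_simple_paths(graph.graph, source, target, weight=weight):
        path = _path_record(graph, nodes)
        # generator yields non-decreasing scores: once k paths are kept and
        # the current candidate can no longer tie the k-th best, stop
        if bound is not None and path.score > bound + SCORE_TOL:
            break
        if path.length <= query.max_length:
            kept.append(path)
            if len(kept) >= query.k and bound is None:
                bound = sorted(p.score for p in kept)[query.k - 1]
    return _sorted_ranked(kept, query.k)


def yen_k_shortest(graph: PairGraph, query: SearchQuery) -> list[Pathway]:
    """Up to k loop-less pathways in non-decreasing pathway-score order.

    Candidate paths longer than ``query.max_length`` reaction steps are
    discarded without counting toward k.  Source/target compound ids are
    resolved through the stereoisomer merge table; an unknown id raises
    ``KeyError`` naming it.  A source and target in different components
    yield an empty result plus a connectivity warning.
    """
    return _enumerate(graph, query, weight="distance")


def two_sided_unweighted_search(
    graph: PairGraph, query: SearchQuery
) -> list[Pathway]:
    """Benchmark mode: rank pathways by hop count on an unweighted view.

    Expects a :func:`carpath.graph_model.threshold_subgraph` output (all
    distances 1).  A bidirectional BFS meeting in the middle decides
    reachability cheaply before path enumeration; ranking is by hop count,
    then lexicographic node sequence.
    """
    if graph.transform != "unweighted":
        logger.warning(
            "two-sided search expects an unweighted (thresholded) view; "
            "got transform %r", graph.transform,
        )
    source = graph.resolve(query.source)
    target = graph.resolve(query.target)
    try:
        nx.bidirectional_shortest_path(graph.graph, source, target)
    except nx.NetworkXNoPath:
        logger.warning(
            "no route: %s and %s lie in different components of the network",
            query.source, query.target,
        )
        return []
    return _enumerate(graph, query, weight=None)


def multi_source_search(
    graph: PairGraph,
    sources: Iterable[str],
    target: str,
    k: int = 10,
    max_length: int = 100,
    transform: str = "default",
) -> dict[str, list[Pathway]]:
    """Independent single-target searches for several source compounds.

    Results are identical to running :func:`yen_k_shortest` once per
    source; a failing source (unknown id, equal to target) is reported
    with a warning and mapped to an empty list without affecting the
    others.
    """
    results: dict[str, list[Pathway]] = {}
    for source in sources:
        try:
            query = SearchQuery(source=source, target=target, k=k,
                                max_length=max_length, transform=transform)
            results[source] = yen_k_shortest(graph, query)
        except (KeyError, ValueError) as exc:
            logger.warning("search from %s failed: %s", source, exc)
            results[source] = []
    return results
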