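"""Weighted reactant-product pair graph.

Metabolites are nodes, reactant-product pairs are undirected edges.  The
CAR of a pair is converted into an edge distance so that highly
atom-conserving partners lie close together:

    default:  d = 1 / CAR
    sqrt:     d = sqrt(1 / CAR)   (softens the atom-conservation penalty)
    exp:      d = e^(1/CAR) / e   (sharpens it; recommended for long routes)

All three equal 1 when CAR = 1.  Stereoisomers are merged into one node
via the 14-character InChIKey connectivity block.  Free Coenzyme A is
excluded from the network by default because its pairs score near-maximal
CARs and create biologically meaningless shortcuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from carpath.pair_weighting import ReactantProductPair

logger = logging.getLogger(__name__)

TRANSFORMS = ("default", "sqrt", "exp")

#: Free Coenzyme A (KEGG C00010); excluded from the pair network by default.
DEFAULT_EXCLUSIONS = frozenset({"C00010"})


def transform_distance(car: float, transform: str = "default") -> float:
    """CAR -> edge distance under the chosen transform (see module docs)."""
    if not 0.0 < car <= 1.0:
        raise ValueError(f"CAR must lie in (0, 1] to define a distance, got {car}")
    if transform == "default":
        return 1.0 / car
    if transform == "sqrt":
        return math.sqrt(1.0 / car)
    if transform == "exp":
        return math.exp(1.0 / car - 1.0)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def _valid_inchikey(key: object) -> bool:
    if not isinstance(key, str) or len(key) != 27:
        return False
    if key[14] != "-" or key[25] != "-":
        return False
    block = key[:14]
    return block.isalpha() and block.isupper()


def merge_stereoisomers(compounds: Optional[pd.DataFrame]) -> dict[str, str]:
    """Map each compound_id to its merged node_id.

    Compounds sharing the first fourteen InChIKey characters (the
    connectivity block, blind to stereochemistry/charge/isotopes) merge
    into one node whose id is the lexicographically smallest member.
    Compounds without a (valid) key map to themselves.
    """
    if compounds is None or len(compounds) == 0:
        return {}
    by_block: dict[str, list[str]] = {}
    mapping: dict[str, str] = {}
    keys = compounds["inchikey"] if "inchikey" in compounds.columns else None
    for i, cid in enumerate(compounds["compound_id"].astype(str)):
        key = keys.iloc[i] if keys is not None else None
        if key is not None and not pd.isna(key) and str(key).strip():
            key = str(key).strip()
            if _valid_inchikey(key):
                by_block.setdefault(key[:14], []).append(cid)
                continue
            logger.warning("malformed InChIKey %r for %s; treated as absent", key, cid)
        mapping[cid] = cid
    for block, members in by_block.items():
        rep = min(members)
        for cid in members:
            mapping[cid] = rep
    return mapping


@dataclass
class PairGraph:
    """Undirected CAR-weighted graph of merged compound nodes.

    ``graph`` is a :class:`networkx.Graph`; edges carry ``car``,
    ``distance`` and ``reaction_ids`` attributes, nodes carry
    ``member_ids``/``inchikey14``/``name``.  ``id_map`` resolves raw
    compound ids to merged node ids.
    """

    graph: nx.Graph
    transform: str = "default"
    id_map: dict[str, str] = field(default_factory=dict)
    excluded_nodes: frozenset[str] = frozenset()
    car_threshold: Optional[float] = None

    def resolve(self, compound_id: str) -> str:
        node = self.id_map.get(compound_id, compound_id)
        if node not in self.graph:
            raise KeyError(f"compound id {compound_id!r} is not a node of the network")
        return node

    def edge_car(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["car"]

    def set_transform(self, transform: str) -> None:
        """Recompute every edge distance under a new transform in place."""
        if transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {transform!r}")
        for _, _, data in self.graph.edges(data=True):
            data["distance"] = transform_distance(data["car"], transform)
        self.transform = transform

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(
    pairs: Iterable[ReactantProductPair],
    compounds: Optional[pd.DataFrame] = None,
    transform: str = "default",
    exclusions: Iterable[str] = DEFAULT_EXCLUSIONS,
) -> PairGraph:
    """Assemble the weighted pair graph.

    Pairs with ``car == 0`` are dropped (no atoms conserved, no edge);
    endpoints are mapped through :func:`merge_stereoisomers`; parallel
    pairs between the same node pair collapse into one edge carrying the
    maximum CAR and the union of supporting reaction ids; excluded
    compounds (free CoA by default) never enter the graph.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    pairs = list(pairs)
    if not pairs:
        logger.warning("empty pair list: building an empty graph")
    id_map = merge_stereoisomers(compounds)
    excluded = {id_map.get(x, x) for x in exclusions}

    g = nx.Graph()
    names: Mapping[str, str] = {}
    keys: Mapping[str, str] = {}
    if compounds is not None and len(compounds):
        cid = compounds["compound_id"].astype(str)
        if "name" in compounds.columns:
            names = dict(zip(cid, compounds["name"]))
        if "inchikey" in compounds.columns:
            keys = {
                c: str(k)[:14]
                for c, k in zip(cid, compounds["inchikey"])
                if _valid_inchikey(k)
            }

    def add_node(raw_id: str) -> str:
        node = id_map.get(raw_id, raw_id)
        if node not in g:
            g.add_node(node, member_ids={raw_id}, inchikey14=keys.get(raw_id),
                       name=names.get(raw_id))
        else:
            g.nodes[node]["member_ids"].add(raw_id)
        return node

    n_zero = 0
    for pair in pairs:
        if pair.car <= 0.0:
            n_zero += 1
            continue
        a_raw, b_raw = pair.substrate_id, pair.product_id
        if id_map.get(a_raw, a_raw) in excluded or id_map.get(b_raw, b_raw) in excluded:
            continue
        a, b = add_node(a_raw), add_node(b_raw)
        if a == b:
            logger.warning(
                "pair %s -> %s merges to a single node %s; self-edge dropped",
                a_raw, b_raw, a,
            )
            continue
        if g.has_edge(a, b):
            data = g.edges[a, b]
            data["reaction_ids"] = data["reaction_ids"] | {pair.reaction_id}
            if pair.car > data["car"]:
                data["car"] = pair.car
                data["distance"] = transform_distance(pair.car, transform)
        else:
            g.add_edge(
                a, b,
                car=pair.car,
                distance=transform_distance(pair.car, transform),
                reaction_ids=frozenset({pair.reaction_id}),
            )
    # drop nodes that lost all their edges to the exclusion/zero-CAR filters
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    if n_zero:
        logger.info("dropped %d zero-CAR pairs at graph build", n_zero)
    return PairGraph(
        graph=g,
        transform=transform,
        id_map=dict(id_map),
        excluded_nodes=frozenset(excluded),
    )


def threshold_subgraph(graph: PairGraph, car_threshold: float) -> PairGraph:
    """Unweighted view keeping only edges with CAR strictly above the cutoff.

    All retained edges get distance 1 (hop metric); nodes left without
    edges are dropped.  Used for network diagnostics and the two-sided
    unweighted search mode.
    """
    if not 0.0 <= car_threshold <= 1.0:
        raise ValueError(f"car_threshold must lie in [0, 1], got {car_threshold}")
    g = nx.Graph()
    for a, b, data in graph.graph.edges(data=True):
        if data["car"] > car_threshold:
            g.add_edge(a, b, car=data["car"], distance=1.0,
                       reaction_ids=data["reaction_ids"])
    for node in g:
        g.nodes[node].update(graph.graph.nodes[node])
    return PairGraph(
        graph=g,
        transform="unweighted",
        id_map={k: v for k, v in graph.id_map.items() if v in g},
        excluded_nodes=graph.excluded_nodes,
        car_threshold=car_threshold,
    )
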