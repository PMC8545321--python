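"""Deterministic synthetic networks and labeled pair sets.

These generators encode the study conditions every module is tested
under, without any external download:

* ``hub_shortcut`` -- a source and target joined both by a 2-step route
  through a low-CAR hub metabolite (CAR 0.2 per step, the CO2/ATP/H2O
  shortcut scenario) and by a 5-step chain conserving 90% of the atoms
  per step.  Ground-truth scores per transform come from closed-form
  arithmetic, independent of the search code.
* ``coa_case`` -- thioester reactions with a 48-atom shared CoA moiety,
  exercising the CoA-as-single-atom contraction.
* ``labeled_pairs`` -- main/non-main pair populations with Beta-
  distributed CARs emulating the empirical separation between principal
  biotransformations and cofactor/leaving-group pairs.
* ``random_graph`` -- seeded Erdos-Renyi networks for brute-force oracle
  tests.

Fixtures encode atom counts and map-index sets only; no chemically
valid molecules are simulated.  Same spec + seed => byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from carpath.graph_model import PairGraph, build_graph
from carpath.pair_weighting import (
    AtomMappedReaction,
    ReactantProductPair,
    ReactionParticipant,
    compute_car,
)
from carpath.rpair_validation import LabeledPair

FIXTURE_KINDS = ("linear_chain", "hub_shortcut", "coa_case", "labeled_pairs",
                 "random_graph")

#: default labeled-pair study conditions: population sizes match the
#: curated reference set (5148 main / 5599 non-main pairs); Beta shapes
#: chosen so the two CAR populations separate with theoretical AUC ~0.88
#: and a Youden-optimal cutoff near 0.34.
N_POS_DEFAULT = 5148
N_NEG_DEFAULT = 5599
POS_BETA_DEFAULT = (1.4, 1.2)
NEG_BETA_DEFAULT = (1.6, 7.5)

HUB_CAR = 0.2
CHAIN_CAR = 0.9
CHAIN_STEPS = 5


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


@dataclass
class NetworkFixture:
    pairs: list[ReactantProductPair]
    compounds: pd.DataFrame
    ground_truth: dict
    source: Optional[str] = None
    target: Optional[str] = None


def _weighted_pair(rid: str, a: str, b: str, car: float) -> ReactantProductPair:
    return ReactantProductPair(reaction_id=rid, substrate_id=a, product_id=b, car=car)


def make_hub_shortcut() -> NetworkFixture:
    """Hub-shortcut network: S--H--T (CAR 0.2) vs a 5-step chain (CAR 0.9).

    The ground truth ranks the two routes per transform from the
    closed-form distance sums: the exponential transform penalizes the
    low-CAR hub steps so strongly that the long chain wins, while the
    square-root transform favors the short hub route.
    """
    source, hub, target = "C00001", "C00002", "C00007"
    chain = [source, "C00003", "C00004", "C00005", "C00006", target]
    assert len(chain) - 1 == CHAIN_STEPS
    pairs = [
        _weighted_pair("R00001", source, hub, HUB_CAR),
        _weighted_pair("R00002", hub, target, HUB_CAR),
    ]
    for i, (a, b) in enumerate(zip(chain[:-1], chain[1:]), start=1):
        pairs.append(_weighted_pair(f"R{100 + i:05d}", a, b, CHAIN_CAR))
    compounds = pd.DataFrame({
        "compound_id": sorted({source, hub, target, *chain}),
        "name": ["source", "hub", "chain-1", "chain-2", "chain-3", "chain-4",
                 "target"],
    })

    def route_scores(transform: str) -> dict:
        if transform == "default":
            hub_d, chain_d = 1 / HUB_CAR, 1 / CHAIN_CAR
        elif transform == "sqrt":
            hub_d, chain_d = math.sqrt(1 / HUB_CAR), math.sqrt(1 / CHAIN_CAR)
        else:
            hub_d = math.exp(1 / HUB_CAR - 1)
            chain_d = math.exp(1 / CHAIN_CAR - 1)
        hub_score = 2 * hub_d
        chain_score = CHAIN_STEPS * chain_d
        return {
            "hub_route": {"nodes": [source, hub, target], "score": hub_score},
            "chain_route": {"nodes": chain, "score": chain_score},
            "rank1": "hub_route" if hub_score < chain_score else "chain_route",
        }

    ground_truth = {t: route_scores(t) for t in ("default", "sqrt", "exp")}
    return NetworkFixture(pairs=pairs, compounds=compounds,
                          ground_truth=ground_truth, source=source, target=target)


def make_linear_chain(n_steps: int = 3, car: float = CHAIN_CAR) -> NetworkFixture:
    nodes = [f"C{i + 1:05d}" for i in range(n_steps + 1)]
    pairs = [
        _weighted_pair(f"R{i + 1:05d}", a, b, car)
        for i, (a, b) in enumerate(zip(nodes[:-1], nodes[1:]))
    ]
    compounds = pd.DataFrame({"compound_id": nodes,
                              "name": [f"chain-{i}" for i in range(len(nodes))]})
    ground_truth = {"nodes": nodes, "n_steps": n_steps, "car": car}
    return NetworkFixture(pairs=pairs, compounds=compounds,
                          ground_truth=ground_truth,
                          source=nodes[0], target=nodes[-1])


COA_MOIETY_SIZE = 48


@dataclass
class CoaFixture:
    reactions: list[AtomMappedReaction]
    ground_truth: dict


def make_coa_case() -> CoaFixture:
    """Thioester fixture exercising the CoA contraction rule.

    Three synthetic reactions (acyl atoms are indices < 100, the 48-atom
    CoA moiety occupies 100..147):

    * RX0001 -- acetyl-CoA-like + C3 donor -> butyryl-CoA-like + leaving
      atom: the shared CoA scaffold masks the acyl chemistry without
      contraction.
    * RX0002 -- the same acyl chemistry on free acids (no CoA): the
      contraction flag must not touch it.
    * RX0003 -- complete acyl exchange between two CoA thioesters: with
      contraction only the CoA pseudo-atom is conserved and the CAR
      falls below the 0.34 main-pair cutoff.

    Ground-truth CARs with and without contraction are hand-counted from
    the index sets and evaluated through the closed-form CAR formula.
    """
    coa = frozenset(range(100, 100 + COA_MOIETY_SIZE))
    rx1 = AtomMappedReaction(
        "RX0001",
        reactants=(
            ReactionParticipant("X00001", frozenset({1, 2}) | coa, coa),
            ReactionParticipant("X00003", frozenset({3, 4, 5})),
        ),
        products=(
            ReactionParticipant("X00002", frozenset({1, 2, 3, 4}) | coa, coa),
            ReactionParticipant("X00004", frozenset({5})),
        ),
    )
    rx2 = AtomMappedReaction(
        "RX0002",
        reactants=(
            ReactionParticipant("Y00001", frozenset({1, 2})),
            ReactionParticipant("Y00003", frozenset({3, 4, 5})),
        ),
        products=(
            ReactionParticipant("Y00002", frozenset({1, 2, 3, 4})),
            ReactionParticipant("Y00004", frozenset({5})),
        ),
    )
    rx3 = AtomMappedReaction(
        "RX0003",
        reactants=(
            ReactionParticipant("Z00001", frozenset({1, 2}) | coa, coa),
            ReactionParticipant("Z00003", frozenset({200, 201})),
        ),
        products=(
            ReactionParticipant("Z00002", frozenset({200, 201}) | coa, coa),
            ReactionParticipant("Z00004", frozenset({1, 2})),
        ),
    )
    n = COA_MOIETY_SIZE
    ground_truth = {
        "without_contraction": {
            "RX0001:X00001->X00002": compute_car(2 + n, 2 + n, 4 + n),
            "RX0002:Y00001->Y00002": compute_car(2, 2, 4),
            "RX0003:Z00001->Z00002": compute_car(n, 2 + n, 2 + n),
        },
        "with_contraction": {
            "RX0001:X00001->X00002": compute_car(3, 3, 5),
            "RX0002:Y00001->Y00002": compute_car(2, 2, 4),
            "RX0003:Z00001->Z00002": compute_car(1, 3, 3),
        },
    }
    return CoaFixture(reactions=[rx1, rx2, rx3], ground_truth=ground_truth)


def make_labeled_pairs(
    n_pos: int = N_POS_DEFAULT,
    n_neg: int = N_NEG_DEFAULT,
    pos_beta_params: tuple[float, float] = POS_BETA_DEFAULT,
    neg_beta_params: tuple[float, float] = NEG_BETA_DEFAULT,
    seed: int = 0,
) -> list[LabeledPair]:
    """Labeled pair population with Beta-distributed CARs per class."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one pair per class")
    for a, b in (pos_beta_params, neg_beta_params):
        if a <= 0 or b <= 0:
            raise ValueError(f"invalid Beta parameters ({a}, {b})")
    rng = np.random.default_rng(seed)
    pos = rng.beta(*pos_beta_params, size=n_pos)
    neg = rng.beta(*neg_beta_params, size=n_neg)
    pairs = [
        LabeledPair(f"P{i + 1:05d}", f"Q{i + 1:05d}", float(c), True)
        for i, c in enumerate(pos)
    ]
    pairs += [
        LabeledPair(f"N{i + 1:05d}", f"M{i + 1:05d}", float(c), False)
        for i, c in enumerate(neg)
    ]
    return pairs


def make_random_graph(
    n_nodes: int = 12,
    edge_prob: float = 0.3,
    car_range: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
) -> PairGraph:
    """Seeded Erdos-Renyi pair graph for oracle-equivalence tests."""
    lo, hi = car_range
    if not 0.0 < lo <= hi <= 1.0:
        raise ValueError(f"car_range must satisfy 0 < lo <= hi <= 1, got {car_range}")
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=seed)
    rng = np.random.default_rng(seed)
    pairs = []
    for j, (a, b) in enumerate(sorted(g.edges())):
        car = float(rng.uniform(lo, hi))
        pairs.append(_weighted_pair(
            f"R{j + 1:05d}", f"C{a + 1:05d}", f"C{b + 1:05d}", car,
        ))
    return build_graph(pairs, compounds=None, exclusions=())


# -- file emission (CLI `fixtures` subcommand) ------------------------------

def emit_fixture(kind: str, out_dir: str | Path, seed: int = 0, **params) -> list[Path]:
    """Write a fixture's network/pair files plus its ground-truth JSON."""
    from carpath.io import write_pair_table, write_reaction_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump_json(name: str, obj: dict) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        written.append(path)

    if kind in ("hub_shortcut", "linear_chain"):
        fx = make_hub_shortcut() if kind == "hub_shortcut" else make_linear_chain(
            int(params.get("n_steps", 3)), float(params.get("car", CHAIN_CAR)))
        write_pair_table(fx.pairs, out / "pairs.tsv")
        fx.compounds.to_csv(out / "compounds.tsv", sep="\t", index=False)
        dump_json("ground_truth.json",
                  {"source": fx.source, "target": fx.target, **fx.ground_truth})
        written += [out / "pairs.tsv", out / "compounds.tsv"]
    elif kind == "coa_case":
        fx = make_coa_case()
        write_reaction_table(fx.reactions, out / "reactions.tsv")
        dump_json("ground_truth.json", fx.ground_truth)
        written.append(out / "reactions.tsv")
    elif kind == "labeled_pairs":
        pairs = make_labeled_pairs(
            n_pos=int(params.get("n_pos", N_POS_DEFAULT)),
            n_neg=int(params.get("n_neg", N_NEG_DEFAULT)),
            seed=seed,
        )
        df = pd.DataFrame({
            "substrate_id": [p.substrate_id for p in pairs],
            "product_id": [p.product_id for p in pairs],
            "car": [repr(p.car) for p in pairs],
            "is_main": [int(p.is_main) for p in pairs],
        })
        df.to_csv(out / "labeled_pairs.tsv", sep="\t", index=False)
        written.append(out / "labeled_pairs.tsv")
    elif kind == "random_graph":
        graph = make_random_graph(
            n_nodes=int(params.get("n_nodes", 12)),
            edge_prob=float(params.get("edge_prob", 0.3)),
            seed=seed,
        )
        from carpath.io import write_graph_dump

        write_graph_dump(graph, out / "edges.tsv")
        written.append(out / "edges.tsv")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
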