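"""Readers, writers and run configuration.

All tabular formats are UTF-8 TSV with a header row; extra columns are
ignored.  Pair tables come in two dialects:

* counts dialect -- ``reaction_id, substrate_id, product_id, n_c, n_r,
  n_p`` (CAR recomputed on load, cross-checked against an optional
  ``car`` column);
* weighted dialect -- ``reaction_id, substrate_id, product_id, car``
  (pre-calculated weights, counts absent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from carpath.graph_model import DEFAULT_EXCLUSIONS, PairGraph
from carpath.pair_weighting import (
    AtomMappedReaction,
    ReactantProductPair,
    ReactionParticipant,
    compute_car,
)
from carpath.pathway_search import Pathway

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("n_c", "n_r", "n_p")
PAIR_KEY_COLUMNS = ("reaction_id", "substrate_id", "product_id")


@dataclass
class RunConfig:
    """Defaults reproduce the recommended configuration: default distance
    transform, CAR threshold 0.34 (the Youden-optimal main-pair cutoff)
    and free CoA excluded from the network."""

    network: Optional[str] = None
    compounds: Optional[str] = None
    transform: str = "default"
    k: int = 10
    max_length: int = 100
    car_threshold: float = 0.34
    exclusions: list[str] = field(default_factory=lambda: sorted(DEFAULT_EXCLUSIONS))
    cofactors: Optional[str] = None
    out: Optional[str] = None
    seed: int = 0
    verbosity: int = 1


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def load_compound_table(path: str | Path) -> pd.DataFrame:
    """Compound table: compound_id plus optional inchikey/name/smiles/
    coa_carrier columns."""
    df = _read_tsv(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'compound_id'")
    if "coa_carrier" in df.columns:
        df["coa_carrier"] = (
            df["coa_carrier"].fillna("0").str.strip().isin(("1", "true", "True", "yes"))
        )
    return df


def load_pair_network(path: str | Path) -> list[ReactantProductPair]:
    """Load a pair table in either dialect (see module docs).

    Hard errors (with the offending line number) on missing required
    columns, non-numeric fields and CARs outside [0, 1]; a stored ``car``
    disagreeing with the counts by more than 1e-6 is only warned about,
    the recomputed value wins.
    """
    df = _read_tsv(path)
    missing = [c for c in PAIR_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_counts = all(c in df.columns for c in COUNT_COLUMNS)
    if not has_counts and "car" not in df.columns:
        raise ValueError(
            f"{path}: need either count columns {COUNT_COLUMNS} or a 'car' column"
        )
    pairs: list[ReactantProductPair] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        row_has_counts = has_counts and not any(
            pd.isna(row[c]) or str(row[c]).strip() == "" for c in COUNT_COLUMNS
        )
        if not row_has_counts and "car" not in df.columns:
            raise ValueError(f"{path}:{line}: incomplete atom counts")
        if row_has_counts:
            try:
                n_c, n_r, n_p = (int(row[c]) for c in COUNT_COLUMNS)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{line}: non-integer atom counts"
                ) from None
            try:
                pair = ReactantProductPair.from_counts(
                    str(row["reaction_id"]), str(row["substrate_id"]),
                    str(row["product_id"]), n_c, n_r, n_p,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{line}: {exc}") from None
            if "car" in df.columns and not pd.isna(row["car"]):
                stored = float(row["car"])
                if abs(stored - pair.car) > 1e-6:
                    logger.warning(
                        "%s:%d: stored car %s disagrees with counts "
                        "(recomputed %.6f); using the recomputed value",
                        path, line, stored, pair.car,
                    )
        else:
            try:
                car = float(row["car"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{line}: non-numeric car") from None
            if not 0.0 <= car <= 1.0:
                raise ValueError(f"{path}:{line}: car {car} outside [0, 1]")
            pair = ReactantProductPair(
                reaction_id=str(row["reaction_id"]),
                substrate_id=str(row["substrate_id"]),
                product_id=str(row["product_id"]),
                car=car,
            )
        pairs.append(pair)
    return pairs


def write_pair_table(pairs: Iterable[ReactantProductPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append({
            "reaction_id": p.reaction_id,
            "substrate_id": p.substrate_id,
            "product_id": p.product_id,
            "n_c": "" if p.n_c is None else p.n_c,
            "n_r": "" if p.n_r is None else p.n_r,
            "n_p": "" if p.n_p is None else p.n_p,
            "car_r": "" if p.car_r is None else repr(p.car_r),
            "car_p": "" if p.car_p is None else repr(p.car_p),
            "car": repr(p.car),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graph_dump(graph: PairGraph, path: str | Path) -> None:
    """Edge list TSV in deterministic (node_a, node_b) order."""
    rows = []
    for a, b, data in graph.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append({
            "node_a": a,
            "node_b": b,
            "car": repr(data["car"]),
            "distance": repr(data["distance"]),
            "reaction_ids": ";".join(sorted(data["reaction_ids"])),
        })
    rows.sort(key=lambda r: (r["node_a"], r["node_b"]))
    pd.DataFrame(rows, columns=["node_a", "node_b", "car", "distance",
                                "reaction_ids"]).to_csv(path, sep="\t", index=False)


PATHWAY_COLUMNS = ("index", "pathway_length", "intermediates", "reaction_ids",
                   "pathway_score", "average_car")


def format_pathway_table(
    pathways: Sequence[Pathway], mode: str = "report"
) -> pd.DataFrame:
    """Result table with one row per ranked pathway.

    ``report`` rounds score and average CAR to two decimals (round-half-
    even, the display precision used in publication-style tables);
    ``machine`` keeps full precision.
    """
    if mode not in ("report", "machine"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for p in pathways:
        if mode == "report":
            score, avg = format(p.score, ".2f"), format(p.average_car, ".2f")
        else:
            score, avg = repr(p.score), repr(p.average_car)
        rows.append({
            "index": p.rank,
            "pathway_length": p.length,
            "intermediates": "->".join(p.node_sequence),
            "reaction_ids": "->".join(p.representative_reactions()),
            "pathway_score": score,
            "average_car": avg,
        })
    return pd.DataFrame(rows, columns=PATHWAY_COLUMNS)


def write_pathway_table(
    pathways: Sequence[Pathway], path: str | Path, mode: str = "report"
) -> None:
    format_pathway_table(pathways, mode).to_csv(path, sep="\t", index=False)


def pathways_to_json(pathways: Sequence[Pathway]) -> list[dict]:
    """Machine dump with full reaction-id sets and per-step CARs/distances."""
    return [
        {
            "rank": p.rank,
            "nodes": list(p.node_sequence),
            "reactions": [sorted(step) for step in p.reaction_sequence],
            "step_cars": list(p.step_cars),
            "step_distances": list(p.step_distances),
            "score": p.score,
            "average_car": p.average_car,
            "length": p.length,
        }
        for p in pathways
    ]


# -- atom-mapped reaction tables (fixture dialect) --------------------------

REACTION_COLUMNS = ("reaction_id", "side", "compound_id", "atoms", "coa_atoms")


def _parse_atom_set(cell: object) -> frozenset[int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(","))


def load_reaction_table(path: str | Path) -> list[AtomMappedReaction]:
    """Atom-mapped reactions as one row per participant.

    Columns: reaction_id, side (r/p), compound_id, atoms (comma-joined
    map indices), coa_atoms (optional subset).
    """
    df = _read_tsv(path)
    missing = [c for c in REACTION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    reactions: list[AtomMappedReaction] = []
    for rid, group in df.groupby("reaction_id", sort=False):
        reactants, products = [], []
        for _, row in group.iterrows():
            part = ReactionParticipant(
                compound_id=str(row["compound_id"]),
                atoms=_parse_atom_set(row["atoms"]),
                coa_atoms=_parse_atom_set(row.get("coa_atoms")),
            )
            side = str(row["side"]).strip().lower()
            if side in ("r", "reactant"):
                reactants.append(part)
            elif side in ("p", "product"):
                products.append(part)
            else:
                raise ValueError(f"{path}: unknown side {row['side']!r}")
        reactions.append(AtomMappedReaction(str(rid), tuple(reactants), tuple(products)))
    return reactions


def write_reaction_table(
    reactions: Iterable[AtomMappedReaction], path: str | Path
) -> None:
    rows = []
    for rxn in reactions:
        for side, parts in (("r", rxn.reactants), ("p", rxn.products)):
            for part in parts:
                rows.append({
                    "reaction_id": rxn.reaction_id,
                    "side": side,
                    "compound_id": part.compound_id,
                    "atoms": ",".join(str(i) for i in sorted(part.atoms)),
                    "coa_atoms": ",".join(str(i) for i in sorted(part.coa_atoms)),
                })
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_labeled_pairs(path: str | Path):
    """Labeled pair TSV: substrate_id, product_id, car, is_main (0/1)."""
    from carpath.rpair_validation import LabeledPair

    df = _read_tsv(path)
    required = ("substrate_id", "product_id", "car", "is_main")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(LabeledPair(
                substrate_id=str(row["substrate_id"]),
                product_id=str(row["product_id"]),
                car=float(row["car"]),
                is_main=str(row["is_main"]).strip() in ("1", "true", "True"),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{idx + 2}: {exc}") from None
    return out
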