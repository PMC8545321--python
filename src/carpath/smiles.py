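"""Parse atom-mapped reaction SMILES into AtomMappedReaction records.

Requires RDKit (install the ``carpath[chem]`` extra).  Atom identity is
carried by the atom-map numbers; unmapped heavy atoms receive fresh
negative indices unique within the reaction so that index-set sizes
equal heavy-atom counts and cross-side intersections are unaffected.
Hydrogens never carry indices.

Compound ids are taken from optional ``reactant_ids``/``product_ids``
columns (semicolon-separated, in component order); otherwise the
14-character InChIKey connectivity block of the component is used.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from carpath.pair_weighting import AtomMappedReaction, ReactionParticipant

logger = logging.getLogger(__name__)

# Coenzyme A minus the thiol hydrogen; matched as a substructure to flag
# the CoA moiety of thioesters and of free CoA.
COA_SMARTS = (
    "SCCNC(=O)CCNC(=O)C(O)C(C)(C)COP(~O)(~O)OP(~O)(~O)OCC1OC(n2cnc3c(N)ncnc32)"
    "C(O)C1OP(~O)(~O)~O"
)


def _require_rdkit():
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reaction SMILES parsing requires rdkit; install carpath[chem]"
        ) from exc
    return Chem


def parse_reaction_smiles(
    reaction_id: str,
    smiles: str,
    reactant_ids: Optional[list[str]] = None,
    product_ids: Optional[list[str]] = None,
    detect_coa: bool = True,
) -> AtomMappedReaction:
    """One ``reactants>>products`` record with atom-map numbers."""
    Chem = _require_rdkit()
    parts = smiles.split(">")
    if len(parts) != 3:
        raise ValueError(f"reaction {reaction_id}: not a 'reactants>>products' SMILES")
    fresh = itertools.count(-1, -1)
    coa_query = Chem.MolFromSmarts(COA_SMARTS) if detect_coa else None

    def parse_side(side_smiles: str, ids: Optional[list[str]], side: str):
        if not side_smiles:
            raise ValueError(f"reaction {reaction_id}: empty {side} side")
        components = side_smiles.split(".")
        if ids is not None and len(ids) != len(components):
            raise ValueError(
                f"reaction {reaction_id}: {len(ids)} {side} ids for "
                f"{len(components)} components"
            )
        out = []
        for i, comp in enumerate(components):
            mol = Chem.MolFromSmiles(comp)
            if mol is None:
                raise ValueError(
                    f"reaction {reaction_id}: unparsable component {comp!r}"
                )
            idx_of_atom: dict[int, int] = {}
            for atom in mol.GetAtoms():
                if atom.GetAtomicNum() == 1:
                    continue
                mapno = atom.GetAtomMapNum()
                idx_of_atom[atom.GetIdx()] = mapno if mapno > 0 else next(fresh)
            coa_atoms: frozenset[int] = frozenset()
            if coa_query is not None:
                match = mol.GetSubstructMatch(coa_query)
                if match:
                    coa_atoms = frozenset(
                        idx_of_atom[a] for a in match if a in idx_of_atom
                    )
            if ids is not None:
                cid = ids[i]
            else:
                inchikey = Chem.MolToInchiKey(mol)
                cid = inchikey[:14] if inchikey else Chem.MolToSmiles(mol)
            out.append(ReactionParticipant(
                compound_id=cid,
                atoms=frozenset(idx_of_atom.values()),
                coa_atoms=coa_atoms,
            ))
        return tuple(out)

    return AtomMappedReaction(
        reaction_id=reaction_id,
        reactants=parse_side(parts[0], reactant_ids, "reactant"),
        products=parse_side(parts[2], product_ids, "product"),
    )


def load_reaction_smiles(path: str | Path, detect_coa: bool = True) -> list[AtomMappedReaction]:
    """TSV with columns reaction_id, reaction_smiles and optional
    reactant_ids/product_ids (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("reaction_id", "reaction_smiles"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    reactions = []
    for _, row in df.iterrows():
        def split_ids(col: str) -> Optional[list[str]]:
            if col in df.columns and not pd.isna(row[col]):
                return [s.strip() for s in str(row[col]).split(";")]
            return None

        reactions.append(parse_reaction_smiles(
            str(row["reaction_id"]),
            str(row["reaction_smiles"]),
            reactant_ids=split_ids("reactant_ids"),
            product_ids=split_ids("product_ids"),
            detect_coa=detect_coa,
        ))
    return reactions
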