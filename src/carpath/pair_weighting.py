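"""Decompose atom-mapped reactions into CAR-weighted reactant-product pairs.

Each reaction is split into all reactant x product combinations.  For a
pair, ``n_c`` counts the non-hydrogen atoms shared between the two sides
(atoms are identified by their atom-map index), ``n_r``/``n_p`` the total
non-hydrogen atoms of reactant and product.  The Conserved Atom Ratio is

    CAR_r = n_c / n_r,   CAR_p = n_c / n_p
    CAR   = ((CAR_r + CAR_p) / 2) * (1 - |CAR_r - CAR_p|)

i.e. the mean of the two one-sided ratios shrunk by a size-mismatch
correction factor.  Coenzyme A moieties occurring on both sides of a
reaction are contracted to a single pseudo-atom first, so that the small
acyl groups attached to the carrier dominate the score instead of the
large, always-conserved CoA scaffold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactionParticipant:
    """One reactant or product occurrence within an atom-mapped reaction.

    ``atoms`` holds the atom-map indices of the non-hydrogen atoms.
    Unmapped heavy atoms must be given unique indices that occur on one
    side only (the SMILES parser uses fresh negative integers), so that
    set sizes equal heavy-atom counts.  ``coa_atoms`` optionally marks the
    subset forming a Coenzyme A moiety.
    """

    compound_id: str
    atoms: frozenset[int]
    coa_atoms: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", frozenset(self.atoms))
        object.__setattr__(self, "coa_atoms", frozenset(self.coa_atoms))
        if not self.coa_atoms <= self.atoms:
            raise ValueError(
                f"coa_atoms must be a subset of atoms for {self.compound_id}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class AtomMappedReaction:
    """A reaction with per-participant atom-map index sets.

    Invariants: every atom-map index appears at most once among the
    reactants and at most once among the products; hydrogens carry no
    indices.  Reactions are treated as bidirectional.
    """

    reaction_id: str
    reactants: tuple[ReactionParticipant, ...]
    products: tuple[ReactionParticipant, ...]
    bidirectional: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        for side_name, side in (("reactant", self.reactants), ("product", self.products)):
            seen: set[int] = set()
            for part in side:
                overlap = seen & part.atoms
                if overlap:
                    raise ValueError(
                        f"reaction {self.reaction_id}: atom-map indices "
                        f"{sorted(overlap)} repeated on the {side_name} side"
                    )
                seen |= part.atoms


@dataclass(frozen=True)
class ReactantProductPair:
    """One substrate->product alignment with conserved-atom counts.

    ``n_c``, ``n_r``, ``n_p`` may be None when the pair was loaded from a
    pre-weighted table that ships only the final CAR.
    """

    reaction_id: str
    substrate_id: str
    product_id: str
    car: float
    n_c: Optional[int] = None
    n_r: Optional[int] = None
    n_p: Optional[int] = None
    car_r: Optional[float] = None
    car_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.car <= 1.0:
            raise ValueError(f"CAR {self.car} outside [0, 1]")

    @classmethod
    def from_counts(
        cls, reaction_id: str, substrate_id: str, product_id: str,
        n_c: int, n_r: int, n_p: int,
    ) -> "ReactantProductPair":
        car = compute_car(n_c, n_r, n_p)
        return cls(
            reaction_id=reaction_id,
            substrate_id=substrate_id,
            product_id=product_id,
            car=car,
            n_c=n_c,
            n_r=n_r,
            n_p=n_p,
            car_r=n_c / n_r,
            car_p=n_c / n_p,
        )


def compute_car(n_c: int, n_r: int, n_p: int) -> float:
    """Conserved Atom Ratio of a reactant-product pair.

    Parameters
    ----------
    n_c : int
        Number of non-hydrogen atoms conserved between the two molecules.
    n_r, n_p : int
        Total non-hydrogen atom counts of reactant and product.

    Returns
    -------
    float
        ``((n_c/n_r + n_c/n_p)/2) * (1 - |n_c/n_r - n_c/n_p|)``, clipped
        to [0, 1].  The clip guards the extreme size-mismatch regime where
        the correction factor would go negative.
    """
    if n_r < 1 or n_p < 1:
        raise ValueError(f"molecule sizes must be >= 1, got n_r={n_r}, n_p={n_p}")
    if not 0 <= n_c <= min(n_r, n_p):
        raise ValueError(
            f"conserved count n_c={n_c} outside [0, min(n_r, n_p)={min(n_r, n_p)}]"
        )
    car_r = n_c / n_r
    car_p = n_c / n_p
    car = ((car_r + car_p) / 2.0) * (1.0 - abs(car_r - car_p))
    return min(1.0, max(0.0, car))


def decompose_reaction(rxn: AtomMappedReaction) -> list[ReactantProductPair]:
    """Split a reaction into all reactant-product pairs with their CARs.

    One pair per (reactant, product) combination; ``n_c`` is the size of
    the intersection of the two atom-map index sets.  Pairs conserving
    zero atoms are retained here and filtered at graph construction.

    Self-pairs (the same compound on both sides, e.g. a regenerated
    carrier) are dropped with a warning -- a self-edge can never occur in
    a loop-less path.  When stoichiometric duplicates produce several
    pairs for one (substrate, product) combination, the pair with the
    maximal ``n_c`` is kept.
    """
    best: dict[tuple[str, str], ReactantProductPair] = {}
    order: list[tuple[str, str]] = []
    for reac, prod in itertools.product(rxn.reactants, rxn.products):
        if reac.compound_id == prod.compound_id:
            logger.warning(
                "reaction %s: dropping self-pair %s -> %s",
                rxn.reaction_id, reac.compound_id, prod.compound_id,
            )
            continue
        if reac.n_atoms == 0 or prod.n_atoms == 0:
            logger.warning(
                "reaction %s: pair %s -> %s has a zero-atom participant; "
                "CAR undefined, pair rejected",
                rxn.reaction_id, reac.compound_id, prod.compound_id,
            )
            continue
        n_c = len(reac.atoms & prod.atoms)
        pair = ReactantProductPair.from_counts(
            rxn.reaction_id, reac.compound_id, prod.compound_id,
            n_c, reac.n_atoms, prod.n_atoms,
        )
        key = (reac.compound_id, prod.compound_id)
        if key not in best:
            best[key] = pair
            order.append(key)
        elif pair.n_c > (best[key].n_c or 0):
            best[key] = pair
    return [best[k] for k in order]


def _moiety(part: ReactionParticipant, coa_ids: frozenset[str]) -> frozenset[int]:
    """CoA moiety of a participant: the explicit subset, or all atoms for a
    compound configured as free CoA."""
    if part.coa_atoms:
        return part.coa_atoms
    if part.compound_id in coa_ids:
        return part.atoms
    return frozenset()


def _pseudo_index(moiety: frozenset[int]) -> int:
    # deterministic representative; prefer mapped (positive) indices so a
    # conserved moiety collapses to the same pseudo-atom on both sides
    positives = [i for i in moiety if i > 0]
    return min(positives) if positives else min(moiety)


def contract_coa(
    rxn: AtomMappedReaction,
    coa_ids: Iterable[str] = (),
) -> AtomMappedReaction:
    """Collapse Coenzyme A moieties to single pseudo-atoms.

    The contraction applies only when CoA occurs on both sides of the
    reaction; a moiety flagged on one side only is left as ordinary atoms
    (with a warning).  Each moiety is replaced by one pseudo-atom indexed
    by the smallest mapped index of the moiety, so a moiety conserved
    across the reaction contributes exactly one conserved atom to ``n_c``.
    """
    ids = frozenset(coa_ids)
    r_moieties = [_moiety(p, ids) for p in rxn.reactants]
    p_moieties = [_moiety(p, ids) for p in rxn.products]
    has_r = any(r_moieties)
    has_p = any(p_moieties)
    if not (has_r or has_p):
        return rxn
    if has_r != has_p:
        logger.warning(
            "reaction %s: CoA moiety on one side only; no contraction applied",
            rxn.reaction_id,
        )
        return rxn

    def contract_side(
        parts: tuple[ReactionParticipant, ...], moieties: list[frozenset[int]]
    ) -> tuple[ReactionParticipant, ...]:
        out = []
        for part, moiety in zip(parts, moieties):
            if not moiety:
                out.append(part)
                continue
            pseudo = _pseudo_index(moiety)
            out.append(
                replace(
                    part,
                    atoms=(part.atoms - moiety) | {pseudo},
                    coa_atoms=frozenset({pseudo}),
                )
            )
        return tuple(out)

    return replace(
        rxn,
        reactants=contract_side(rxn.reactants, r_moieties),
        products=contract_side(rxn.products, p_moieties),
    )


def reactions_to_pairs(
    reactions: Iterable[AtomMappedReaction],
    coa_ids: Iterable[str] = (),
    coa_contraction: bool = True,
) -> list[ReactantProductPair]:
    """Pipeline helper: contract CoA (optionally) then decompose each reaction."""
    ids = frozenset(coa_ids)
    pairs: list[ReactantProductPair] = []
    for rxn in reactions:
        if coa_contraction:
            rxn = contract_coa(rxn, ids)
        pairs.extend(decompose_reaction(rxn))
    return pairs
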