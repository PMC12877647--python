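"""Pathogenic-hotspot registry, rotamer contacts, and the hotspot score.

The fifth component of the pathogenicity score looks at which residues the
mutant side chain would touch.  For each rotamer with library probability
strictly greater than 10%, the fraction of its direct-contact residues
whose position carries a known pathogenic (ACMG class 4/5) substitution is
weighted by the rotamer's raw probability and summed:

    E = sum over rotamers (p > min_prob) of  p * n_pathogenic / n_total

A residue is a "direct contact" when any of its atoms comes within a
near-touching van der Waals overlap (default >= -0.4 A, no H-bond
allowance) of any side-chain atom of the rotamer.  Probabilities are not
renormalized, so E <= sum of retained probabilities <= 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .rotamers import (
    ClashCriterion,
    PlacedRotamer,
    RotamerLibrary,
    _environment_indices,
    _pairwise_overlaps,
    place_rotamers,
)
from .structure import StructureContext, Variant

__all__ = [
    "PathogenicRegistry",
    "load_registry",
    "ContactSet",
    "contact_criterion",
    "contacts_of",
    "score_E",
    "score_E_from_contact_sets",
]


def contact_criterion(contact_cutoff: float = -0.4) -> ClashCriterion:
    """Near-touching contact criterion: overlap >= ``contact_cutoff``."""
    return ClashCriterion(overlap_cutoff=contact_cutoff, hbond_allowance=0.0)


@dataclass(frozen=True)
class PathogenicRegistry:
    """Protein positions with a known ACMG class 4/5 substitution.

    Pathogenicity of a contact is decided at position level: a position is
    a hotspot if any substitution there is class 4/5.  Specific
    substitutions and class labels are retained for reporting.
    """

    positions: frozenset[int]
    substitutions: tuple[tuple[int, str, str, int], ...] = ()  # (pos, wt, mut, class)

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.positions):
            raise ValueError("registry positions must be >= 1")
        for (_p, _w, _m, cls) in self.substitutions:
            if cls not in (4, 5):
                raise ValueError(f"registry classes restricted to 4/5, got {cls}")
        object.__setattr__(self, "positions", frozenset(int(p) for p in self.positions))

    def __contains__(self, position: int) -> bool:
        return int(position) in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls) -> "PathogenicRegistry":
        return cls(positions=frozenset())


def load_registry(path) -> PathogenicRegistry:
    """Load a hotspot TSV (columns: position [, wt, mut, acmg_class]).

    Position-only rows are tolerated; class defaults to 5.
    """
    positions: set[int] = set()
    subs: list[tuple[int, str, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].strip().lower() == "position":
                continue
            pos = int(row[0])
            positions.add(pos)
            if len(row) >= 4 and row[1].strip() and row[2].strip():
                subs.append((pos, row[1].strip(), row[2].strip(), int(row[3])))
    return PathogenicRegistry(positions=frozenset(positions), substitutions=tuple(subs))


@dataclass(frozen=True)
class ContactSet:
    """Residues in direct contact with one rotamer's side chain."""

    probability: float
    contacts: frozenset[tuple[str, int]]
    n_pathogenic: int
    rotamer: PlacedRotamer | None = None

    @property
    def n_total(self) -> int:
        return len(self.contacts)

    @property
    def pathogenic_fraction(self) -> float:
        return self.n_pathogenic / self.n_total if self.n_total else 0.0


def contacts_of(ctx: StructureContext, rot: PlacedRotamer,
                registry: PathogenicRegistry | None = None,
                criterion: ClashCriterion | None = None) -> ContactSet:
    """Enumerate residues in direct contact with the rotamer's side chain.

    A residue counts once however many of its atoms touch; the mutated
    residue itself is excluded.  ``n_pathogenic`` counts contacts whose
    protein position (structure residue number corrected by the chain
    offset) is a registry hotspot.
    """
    registry = registry or PathogenicRegistry.empty()
    criterion = criterion or contact_criterion()
    contacts: set[tuple[str, int]] = set()
    if rot.atoms:
        env = _environment_indices(ctx, rot)
        if env.size:
            overlap = _pairwise_overlaps(
                rot.coords_array(), rot.radii_array(), rot.elements(),
                ctx.coords[env], ctx.radii[env], [ctx.elements[i] for i in env],
                criterion,
            )
            hit = np.nonzero((overlap >= criterion.overlap_cutoff).any(axis=0))[0]
            contacts = {(ctx.chains[env[i]], ctx.resnums[env[i]]) for i in hit}
    n_path = sum(
        1 for (ch, rn) in contacts
        if (rn - ctx.offsets.get(ch, 0)) in registry
    )
    return ContactSet(probability=rot.probability, contacts=frozenset(contacts),
                      n_pathogenic=n_path, rotamer=rot)


def score_E_from_contact_sets(contact_sets: Iterable[ContactSet],
                              min_prob: float = 0.10) -> float:
    """The hotspot-contact sum over rotamers with probability > ``min_prob``.

    Raw (unrenormalized) probabilities weight each rotamer's pathogenic
    contact fraction; rotamers with no contacts contribute 0.
    """
    return float(sum(
        cs.probability * cs.pathogenic_fraction
        for cs in contact_sets
        if cs.probability > min_prob
    ))


def score_E(ctx: StructureContext, variant: Variant, lib: RotamerLibrary,
            registry: PathogenicRegistry, min_prob: float = 0.10,
            criterion: ClashCriterion | None = None,
            chain: str | None = None) -> float:
    """Pathogenic-hotspot contact score in [0, 1]."""
    rots = place_rotamers(ctx, variant, lib, min_prob=0.0, chain=chain)
    sets = [contacts_of(ctx, r, registry, criterion) for r in rots]
    return score_E_from_contact_sets(sets, min_prob=min_prob)
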