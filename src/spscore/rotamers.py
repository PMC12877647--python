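"""Rotamer placement, steric-clash detection/relief, and the clash score.

The steric component of the pathogenicity score asks: if the mutant side
chain is grafted onto the wild-type backbone at each rotamer from a
library, does it collide with its surroundings, and can the collision be
relieved by torsion-space adjustment of the side chains involved?

* A **clash** is a van der Waals overlap ``r_a + r_b - d`` of at least
  ``overlap_cutoff`` (default 0.6 A) after subtracting an H-bond allowance
  (default 0.4 A) for polar atom pairs.
* **Relief** is deterministic coordinate descent over the chi angles of the
  mutant side chain and of every clashing neighbor side chain (backbone
  fixed), minimizing total squared overlap.
* **Score D** averages a per-rotamer severity (0 = no clash, ``w_relieved``
  = clash relieved, 1 = clash persists) under library probabilities
  renormalized to sum to one.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from . import geometry
from .properties import ONE_TO_THREE, normalize_residue
from .structure import (
    StructureContext,
    UnresolvedPositionError,
    Variant,
    VDW_RADII,
)

__all__ = [
    "RotamerLibrary",
    "load_rotamer_library",
    "default_rotamer_library",
    "PlacedRotamer",
    "Clash",
    "ClashCriterion",
    "ReliefConfig",
    "place_rotamers",
    "detect_clashes",
    "relieve_clashes",
    "score_D",
]

_POLAR_ELEMENTS = frozenset({"N", "O", "S"})


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class RotamerLibrary:
    """Backbone-independent rotamer library: residue -> [(chis, probability)]."""

    entries: Mapping[str, tuple[tuple[tuple[float, ...], float], ...]]

    def __post_init__(self) -> None:
        norm: dict[str, tuple[tuple[tuple[float, ...], float], ...]] = {}
        for res, rots in self.entries.items():
            one = normalize_residue(res)
            total = 0.0
            nchi = geometry.N_CHI[ONE_TO_THREE[one]]
            clean = []
            for chis, p in rots:
                if not (0.0 < p <= 1.0):
                    raise ValueError(f"{one}: probability {p} outside (0, 1]")
                if len(chis) != nchi:
                    raise ValueError(
                        f"{one}: rotamer has {len(chis)} chi angles, expected {nchi}"
                    )
                total += p
                clean.append((tuple(float(c) for c in chis), float(p)))
            if total > 1.0 + 1e-6:
                raise ValueError(f"{one}: probabilities sum to {total} > 1")
            # descending probability, chi tuple as deterministic tie-break
            clean.sort(key=lambda cp: (-cp[1], cp[0]))
            norm[one] = tuple(clean)
        object.__setattr__(self, "entries", norm)

    def rotamers(self, residue: str) -> tuple[tuple[tuple[float, ...], float], ...]:
        one = normalize_residue(residue)
        if one not in self.entries:
            raise KeyError(f"no rotamers for residue {one}")
        return self.entries[one]


def load_rotamer_library(path) -> RotamerLibrary:
    """Load a TSV rotamer library (residue, chi1..chi4, probability)."""
    entries: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].strip().lower() == "residue":
                continue
            res = normalize_residue(row[0])
            chis = tuple(float(x) for x in row[1:5] if x.strip() != "")
            prob = float(row[5])
            entries.setdefault(res, []).append((chis, prob))
    return RotamerLibrary(entries={k: tuple(v) for k, v in entries.items()})


def default_rotamer_library() -> RotamerLibrary:
    return load_rotamer_library(
        resources.files("spscore.data").joinpath("rotamers_default.tsv")
    )


@dataclass(frozen=True)
class Clash:
    """One overlapping atom pair; ``overlap`` is after any H-bond allowance."""

    atom_a: tuple[str, int, str]  # (chain, resnum, atom name) of the rotamer atom
    atom_b: tuple[str, int, str]  # environment atom
    overlap: float


@dataclass(frozen=True)
class PlacedRotamer:
    """A candidate mutant side-chain conformation grafted onto the backbone."""

    chain: str
    resnum: int
    res_type: str  # one-letter mutant type
    chi: tuple[float, ...]
    probability: float
    atoms: Mapping[str, np.ndarray]  # side-chain heavy atoms incl. CB
    clashes_before: tuple[Clash, ...] = ()
    clashes_after: tuple[Clash, ...] = ()
    relieved: bool = False

    @property
    def atom_names(self) -> list[str]:
        return list(self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([self.atoms[n] for n in self.atoms])

    def radii_array(self) -> np.ndarray:
        return np.array([VDW_RADII[_element_of(n)] for n in self.atoms])

    def elements(self) -> list[str]:
        return [_element_of(n) for n in self.atoms]


@dataclass(frozen=True)
class ClashCriterion:
    """Overlap-based clash (or contact) criterion, Chimera-style defaults."""

    overlap_cutoff: float = 0.6
    hbond_allowance: float = 0.4

    def allowance(self, elem_a: str, elem_b: str) -> float:
        # applied to polar pairs, where a donor/acceptor geometry is possible
        if elem_a in _POLAR_ELEMENTS and elem_b in _POLAR_ELEMENTS:
            return self.hbond_allowance
        return 0.0


@dataclass(frozen=True)
class ReliefConfig:
    """Torsion-space clash-relief settings."""

    max_iterations: int = 200
    step_schedule: tuple[float, ...] = (30.0, 10.0, 5.0)
    criterion: ClashCriterion = field(default_factory=ClashCriterion)


def _mutation_site(ctx: StructureContext, variant: Variant, chain: str | None):
    chain = chain or ctx.chain_ids[0]
    resnum = ctx.resnum_for_position(variant.position, chain)
    if (chain, resnum) not in ctx.residue_index:
        raise UnresolvedPositionError(
            f"position {variant.position} (chain {chain}) has no coordinates; "
            "use A-C scoring"
        )
    return chain, resnum


def place_rotamers(ctx: StructureContext, variant: Variant, lib: RotamerLibrary,
                   min_prob: float = 0.0, chain: str | None = None
                   ) -> list[PlacedRotamer]:
    """Construct mutant side chains at every library rotamer with
    probability >= ``min_prob``, ordered by descending probability.

    The backbone (N, CA, C, O) and the CB position are inherited from the
    wild-type residue; a missing CB (e.g. glycine sites) is reconstructed
    from the backbone with a warning.
    """
    chain, resnum = _mutation_site(ctx, variant, chain)
    frame = ctx.atom_map(chain, resnum)
    for need in ("N", "CA", "C"):
        if need not in frame:
            raise ValueError(f"residue {chain}/{resnum} lacks backbone atom {need}")
    mut3 = ONE_TO_THREE[normalize_residue(variant.mut)]
    frame = {k: np.asarray(v, dtype=float) for k, v in frame.items()}
    if mut3 != "GLY" and "CB" not in frame:
        warnings.warn(
            f"residue {chain}/{resnum} has no CB; reconstructing from backbone"
        )
        frame["CB"] = geometry.cb_position(frame["N"], frame["CA"], frame["C"])

    placed: list[PlacedRotamer] = []
    for chis, prob in lib.rotamers(variant.mut):
        if prob < min_prob:
            continue
        atoms: dict[str, np.ndarray] = {}
        if mut3 != "GLY":
            atoms["CB"] = frame["CB"]
            atoms.update(geometry.build_side_chain(mut3, frame, chis))
        placed.append(PlacedRotamer(
            chain=chain, resnum=resnum, res_type=normalize_residue(variant.mut),
            chi=tuple(chis), probability=prob, atoms=atoms,
        ))
    return placed


def _pairwise_overlaps(coords_a, radii_a, elems_a, coords_b, radii_b, elems_b,
                       criterion: ClashCriterion) -> np.ndarray:
    """Effective overlap matrix (n_a, n_b) after H-bond allowance."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.empty((len(coords_a), len(coords_b)))
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    overlap = radii_a[:, None] + radii_b[None, :] - d
    if criterion.hbond_allowance:
        pa = np.array([e in _POLAR_ELEMENTS for e in elems_a])
        pb = np.array([e in _POLAR_ELEMENTS for e in elems_b])
        overlap -= criterion.hbond_allowance * (pa[:, None] & pb[None, :])
    return overlap


def _environment_indices(ctx: StructureContext, rot: PlacedRotamer,
                         reach: float = 12.0) -> np.ndarray:
    """Atom indices near the mutation site, excluding the mutated residue."""
    own_idx = ctx.residue_index.get((rot.chain, rot.resnum), [])
    own = set(own_idx)
    pts = rot.coords_array()
    if own_idx:
        center = ctx.coords[own_idx].mean(axis=0)
        pts = np.vstack([pts, center[None, :]]) if len(pts) else center[None, :]
    elif not len(pts):
        return np.empty(0, dtype=int)
    near = ctx.query_radius(pts, reach)
    return np.array(sorted(near - own), dtype=int)


def detect_clashes(ctx: StructureContext, rot: PlacedRotamer,
                   criterion: ClashCriterion | None = None) -> list[Clash]:
    """All environment atoms clashing with the rotamer's side-chain atoms.

    Atoms of the mutated residue itself (its backbone and the wild-type side
    chain being replaced) are excluded from the environment.
    """
    criterion = criterion or ClashCriterion()
    if not rot.atoms:
        return []
    env = _environment_indices(ctx, rot)
    if env.size == 0:
        return []
    overlap = _pairwise_overlaps(
        rot.coords_array(), rot.radii_array(), rot.elements(),
        ctx.coords[env], ctx.radii[env], [ctx.elements[i] for i in env],
        criterion,
    )
    names = rot.atom_names
    clashes = []
    for ia, ib in zip(*np.nonzero(overlap >= criterion.overlap_cutoff)):
        j = env[ib]
        clashes.append(Clash(
            atom_a=(rot.chain, rot.resnum, names[ia]),
            atom_b=(ctx.chains[j], ctx.resnums[j], ctx.names[j]),
            overlap=float(overlap[ia, ib]),
        ))
    clashes.sort(key=lambda c: (-c.overlap, c.atom_a, c.atom_b))
    return clashes


class _ReliefState:
    """Mutable working state for torsion-space relief."""

    def __init__(self, ctx: StructureContext, rot: PlacedRotamer,
                 criterion: ClashCriterion):
        self.ctx = ctx
        self.criterion = criterion
        self.chain, self.resnum = rot.chain, rot.resnum
        self.mut_type3 = ONE_TO_THREE[rot.res_type]
        self.frame = {k: np.asarray(v) for k, v in ctx.atom_map(rot.chain, rot.resnum).items()}
        if "CB" in rot.atoms:
            self.frame["CB"] = np.asarray(rot.atoms["CB"])
        self.mut_chis = list(rot.chi)
        # neighbors selected for motion: (chain, resnum) -> list of chis
        self.neighbors: dict[tuple[str, int], list[float]] = {}
        self.coords = ctx.coords.copy()

    def add_neighbor(self, key: tuple[str, int]) -> bool:
        if key in self.neighbors or key == (self.chain, self.resnum):
            return False
        res3 = ONE_TO_THREE[self.ctx.residue_type(*key)]
        if geometry.N_CHI.get(res3, 0) == 0:
            return False
        amap = {self.ctx.names[i]: self.coords[i] for i in self.ctx.residue_atoms(*key)}
        chis = geometry.measure_chis(res3, amap)
        if len(chis) < geometry.N_CHI[res3]:
            return False  # incomplete side chain: leave it fixed
        self.neighbors[key] = list(chis)
        self._rebuild_neighbor(key)
        return True

    def _rebuild_neighbor(self, key: tuple[str, int]) -> None:
        res3 = ONE_TO_THREE[self.ctx.residue_type(*key)]
        idx = self.ctx.residue_atoms(*key)
        amap = {self.ctx.names[i]: self.ctx.coords[i] for i in idx}
        frame = {k: np.asarray(v) for k, v in amap.items() if k in ("N", "CA", "C", "CB")}
        if "CB" not in frame:
            return
        built = geometry.build_side_chain(res3, frame, self.neighbors[key])
        name_to_idx = {self.ctx.names[i]: i for i in idx}
        for name, xyz in built.items():
            if name in name_to_idx:
                self.coords[name_to_idx[name]] = xyz

    def mut_atoms(self) -> dict[str, np.ndarray]:
        atoms: dict[str, np.ndarray] = {}
        if self.mut_type3 != "GLY":
            atoms["CB"] = self.frame["CB"]
            atoms.update(geometry.build_side_chain(self.mut_type3, self.frame, self.mut_chis))
        return atoms

    def _moved_blocks(self):
        """[(tag, names, coords, radii, elems, env_exclude_indices)]"""
        blocks = []
        mut = self.mut_atoms()
        names = list(mut)
        blocks.append((
            (self.chain, self.resnum), names,
            np.array([mut[n] for n in names]) if names else np.empty((0, 3)),
            np.array([VDW_RADII[_element_of(n)] for n in names]),
            [_element_of(n) for n in names],
        ))
        for key in self.neighbors:
            idx = [i for i in self.ctx.residue_atoms(*key)
                   if self.ctx.names[i] not in ("N", "CA", "C", "O", "OXT")]
            blocks.append((
                key, [self.ctx.names[i] for i in idx],
                self.coords[idx] if idx else np.empty((0, 3)),
                self.ctx.radii[list(idx)] if idx else np.empty(0),
                [self.ctx.elements[i] for i in idx],
            ))
        return blocks

    def overlaps(self) -> list[tuple[tuple, tuple, float]]:
        """Positive effective overlaps of moved atoms vs the rest + each other."""
        blocks = self._moved_blocks()
        moved_keys = {b[0] for b in blocks}
        out = []
        # moved vs static environment
        env = [i for i in range(len(self.coords))
               if (self.ctx.chains[i], self.ctx.resnums[i]) not in moved_keys]
        env = np.array(env, dtype=int)
        env_coords = self.coords[env]
        env_radii = self.ctx.radii[env]
        env_elems = [self.ctx.elements[i] for i in env]
        for key, names, coords, radii, elems in blocks:
            if len(coords) == 0:
                continue
            ov = _pairwise_overlaps(coords, radii, elems, env_coords, env_radii,
                                    env_elems, self.criterion)
            for ia, ib in zip(*np.nonzero(ov > 0)):
                j = env[ib]
                out.append(((key[0], key[1], names[ia]),
                            (self.ctx.chains[j], self.ctx.resnums[j], self.ctx.names[j]),
                            float(ov[ia, ib])))
        # moved vs moved (distinct residues)
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                ka, na, ca, ra, ea = blocks[i]
                kb, nb, cb, rb, eb = blocks[j]
                if len(ca) == 0 or len(cb) == 0:
                    continue
                ov = _pairwise_overlaps(ca, ra, ea, cb, rb, eb, self.criterion)
                for ia, ib in zip(*np.nonzero(ov > 0)):
                    out.append(((ka[0], ka[1], na[ia]), (kb[0], kb[1], nb[ib]),
                                float(ov[ia, ib])))
        return out

    def objective(self) -> float:
        return sum(o * o for _, _, o in self.overlaps())

    def clash_list(self) -> list[Clash]:
        cut = self.criterion.overlap_cutoff
        clashes = [Clash(a, b, o) for a, b, o in self.overlaps() if o >= cut]
        clashes.sort(key=lambda c: (-c.overlap, c.atom_a, c.atom_b))
        return clashes

    def movable(self):
        handles = [("mut", k) for k in range(len(self.mut_chis))]
        for key in self.neighbors:
            handles.extend(("nbr", key, k) for k in range(len(self.neighbors[key])))
        return handles

    def nudge(self, handle, delta: float) -> None:
        if handle[0] == "mut":
            self.mut_chis[handle[1]] += delta
        else:
            _, key, k = handle
            self.neighbors[key][k] += delta
            self._rebuild_neighbor(key)


def relieve_clashes(ctx: StructureContext, rot: PlacedRotamer,
                    params: ReliefConfig | None = None) -> PlacedRotamer:
    """Attempt to remove the rotamer's clashes by torsion-space coordinate
    descent over the mutant side chain and clashing neighbor side chains.

    Deterministic; backbone never moves.  ``relieved`` is True iff no clash
    (involving any moved side chain) remains under the same criterion.
    """
    params = params or ReliefConfig()
    clashes = detect_clashes(ctx, rot, params.criterion)
    if not clashes:
        return replace(rot, clashes_before=(), clashes_after=(), relieved=True)

    state = _ReliefState(ctx, rot, params.criterion)
    for clash in clashes:
        state.add_neighbor((clash.atom_b[0], clash.atom_b[1]))

    best = state.objective()
    iterations = 0
    for step in params.step_schedule:
        improved = True
        while improved and iterations < params.max_iterations and best > 0:
            improved = False
            for handle in state.movable():
                if iterations >= params.max_iterations:
                    break
                for delta in (step, -step):
                    state.nudge(handle, delta)
                    val = state.objective()
                    iterations += 1
                    if val < best - 1e-12:
                        best = val
                        improved = True
                        break
                    state.nudge(handle, -delta)
                else:
                    continue
    remaining = state.clash_list()
    mut_atoms = state.mut_atoms()
    return replace(
        rot,
        chi=tuple(((c + 180.0) % 360.0) - 180.0 for c in state.mut_chis),
        atoms=mut_atoms,
        clashes_before=tuple(clashes),
        clashes_after=tuple(remaining),
        relieved=not remaining,
    )


def score_D(ctx: StructureContext, variant: Variant, lib: RotamerLibrary,
            criterion: ClashCriterion | None = None,
            relief: ReliefConfig | None = None,
            w_relieved: float = 0.5,
            chain: str | None = None) -> float:
    """Steric-clash severity in [0, 1].

    Every library rotamer of the mutant type is placed; probabilities are
    renormalized to sum to one, and each rotamer contributes 0 (no clash),
    ``w_relieved`` (clash relieved) or 1 (clash persists).
    """
    criterion = criterion or ClashCriterion()
    relief = relief or ReliefConfig(criterion=criterion)
    rots = place_rotamers(ctx, variant, lib, min_prob=0.0, chain=chain)
    total_p = sum(r.probability for r in rots)
    if total_p <= 0:
        raise ValueError(f"no rotamers for {variant.mut}")
    d = 0.0
    for rot in rots:
        clashes = detect_clashes(ctx, rot, criterion)
        if not clashes:
            s = 0.0
        else:
            relieved = relieve_clashes(ctx, rot, relief)
            s = w_relieved if relieved.relieved else 1.0
        d += (rot.probability / total_p) * s
    return d
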