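"""Structure parsing, sequence-position mapping and neighbor search.

The scorer works against a single experimental model (the reference use
case is the cryo-EM structure of the hERG channel, a homotetramer).  This
module loads PDB/mmCIF files via :mod:`gemmi` into a flat atom table with
element-based van der Waals radii, keeps a registry of protein regions that
lack coordinates (scored in A-C mode), and answers residue-level neighbor
queries through a KD-tree.

Conventions
-----------
* Protein positions are 1-based and intervals are closed on both ends.
* Structure residue numbers are the author-assigned numbers in the file;
  an optional per-chain offset reconciles them with protein numbering
  (identity by default).
* The mutation is modeled on one chain (default: the first chain), but the
  clash/contact environment always includes every chain, so cross-chain
  interfaces are seen.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .properties import THREE_TO_ONE, UnknownResidueError, normalize_residue

__all__ = [
    "VDW_RADII",
    "Variant",
    "parse_variant",
    "RegionMap",
    "default_region_map",
    "is_resolved",
    "StructureContext",
    "load_structure",
    "neighbors_of",
    "UnresolvedPositionError",
]

# Fixed element-based van der Waals radii (A), overridable in load_structure.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


class UnresolvedPositionError(ValueError):
    """The position has no coordinates; only A-C scoring applies there."""


class SynonymousVariantError(ValueError):
    """wt == mut: nothing to score."""


@dataclass(frozen=True)
class Variant:
    """A missense substitution in protein (translation) numbering."""

    position: int
    wt: str
    mut: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


_VARIANT_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{1}|[A-Za-z]{3})(\d+)([A-Za-z]{1}|[A-Za-z]{3})$"
)


def parse_variant(text: str) -> Variant:
    """Parse ``G903R``, ``p.G903R`` or ``p.Gly903Arg`` into a :class:`Variant`.

    Raises ``ValueError`` for malformed strings, ``UnknownResidueError`` for
    non-canonical residues, and :class:`SynonymousVariantError` when
    wt == mut.
    """
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValueError(f"unrecognized variant notation: {text!r}")
    wt = normalize_residue(m.group(1))
    mut = normalize_residue(m.group(3))
    pos = int(m.group(2))
    if wt == mut:
        raise SynonymousVariantError(f"synonymous variant (wt == mut): {text!r}")
    return Variant(position=pos, wt=wt, mut=mut, id=text.strip())


@dataclass(frozen=True)
class RegionMap:
    """Unresolved-region registry plus named domain intervals."""

    unresolved: tuple[tuple[int, int], ...]
    domains: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        ivs = sorted(tuple(iv) for iv in self.unresolved)
        for (a, b) in ivs:
            if a > b or a < 1:
                raise ValueError(f"bad interval {a}-{b}")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping unresolved intervals {a1}-{b1}, {a2}-{b2}")
        object.__setattr__(self, "unresolved", tuple(ivs))
        object.__setattr__(
            self, "domains", tuple((str(n), (int(i[0]), int(i[1]))) for n, i in self.domains)
        )

    def is_resolved(self, position: int) -> bool:
        if position < 1:
            raise ValueError("position must be >= 1")
        return not any(a <= position <= b for a, b in self.unresolved)

    def domain_of(self, position: int) -> str | None:
        for name, (a, b) in self.domains:
            if a <= position <= b:
                return name
        return None

    def in_domain(self, position: int, name: str) -> bool:
        return self.domain_of(position) == name

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            unresolved=tuple((int(a), int(b)) for a, b in cfg.get("unresolved", [])),
            domains=tuple(
                (d["name"], (int(d["interval"][0]), int(d["interval"][1])))
                for d in cfg.get("domains", [])
            ),
        )


def default_region_map() -> RegionMap:
    """The hERG region map: six unresolved intervals + domain placeholders."""
    return RegionMap.from_yaml(resources.files("spscore.data").joinpath("herg_regions.yaml"))


def is_resolved(position: int, regions: RegionMap) -> bool:
    """False iff ``position`` falls in an unresolved interval (closed bounds)."""
    return regions.is_resolved(position)


class StructureContext:
    """Flat atom table over a parsed model, with a residue index and KD-tree.

    Attributes
    ----------
    coords : (n_atoms, 3) float array, A
    radii : (n_atoms,) van der Waals radii, A
    elements, names : per-atom element symbols and atom names
    chains, resnums, restypes : per-atom residue identity (one-letter type)
    residue_index : mapping (chain, resnum) -> list of atom indices,
        in file order
    """

    def __init__(self, coords, radii, elements, names, chains, resnums, restypes,
                 offsets: Mapping[str, int] | None = None):
        self.coords = np.asarray(coords, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.elements = list(elements)
        self.names = list(names)
        self.chains = list(chains)
        self.resnums = list(resnums)
        self.restypes = list(restypes)
        self.offsets = dict(offsets or {})
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        if self.radii.size and self.radii.min() <= 0:
            raise ValueError("non-positive van der Waals radius")
        self.residue_index: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        for i, key in enumerate(zip(self.chains, self.resnums)):
            if key not in self.residue_index:
                self.residue_index[key] = []
                order.append(key)
            self.residue_index[key].append(i)
        self.residue_order = order
        self._tree = cKDTree(self.coords) if len(self.coords) else None

    # -- residue-level accessors -------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for ch, _ in self.residue_order:
            if ch not in seen:
                seen.append(ch)
        return seen

    def resnum_for_position(self, position: int, chain: str) -> int:
        return position + self.offsets.get(chain, 0)

    def has_position(self, position: int, chain: str | None = None) -> bool:
        chain = chain or (self.chain_ids[0] if self.chain_ids else "")
        return (chain, self.resnum_for_position(position, chain)) in self.residue_index

    def residue_atoms(self, chain: str, resnum: int) -> list[int]:
        return self.residue_index[(chain, resnum)]

    def residue_type(self, chain: str, resnum: int) -> str:
        return self.restypes[self.residue_index[(chain, resnum)][0]]

    def atom_map(self, chain: str, resnum: int) -> dict[str, np.ndarray]:
        return {self.names[i]: self.coords[i] for i in self.residue_atoms(chain, resnum)}

    def query_radius(self, points: np.ndarray, radius: float) -> set[int]:
        """Indices of atoms within ``radius`` of any of ``points``."""
        if self._tree is None:
            return set()
        hits = self._tree.query_ball_point(np.atleast_2d(points), r=radius)
        return set(i for sub in hits for i in sub)

    def with_coords(self, coords: np.ndarray) -> "StructureContext":
        """Copy of this context with replaced coordinates (same atoms)."""
        return StructureContext(coords, self.radii, self.elements, self.names,
                                self.chains, self.resnums, self.restypes, self.offsets)


def load_structure(path, fmt: str = "auto",
                   vdw_radii: Mapping[str, float] | None = None,
                   keep_hydrogens: bool = True,
                   offsets: Mapping[str, int] | None = None) -> StructureContext:
    """Load protein atoms from a PDB or mmCIF file.

    Waters and non-protein heteroatoms are excluded; hydrogens are kept if
    present.  Alternate locations collapse to the highest-occupancy
    conformer.  Unknown elements are rejected.
    """
    import gemmi

    radii = dict(VDW_RADII)
    radii.update(vdw_radii or {})
    fmt = fmt.lower()
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    elif fmt in ("cif", "mmcif"):
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    elif fmt == "auto":
        st = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")
    st.setup_entities()

    coords, rads, elements, names, chains, resnums, restypes = [], [], [], [], [], [], []
    skipped_het = 0
    for chain in st[0]:
        for res in chain:
            if res.name not in THREE_TO_ONE:
                skipped_het += 1
                continue
            one = THREE_TO_ONE[res.name]
            best: dict[str, "gemmi.Atom"] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                elem = atom.element.name.upper()
                if elem == "H" and not keep_hydrogens:
                    continue
                if elem not in radii:
                    raise ValueError(
                        f"{path}: unknown element {elem!r} in atom "
                        f"{chain.name}/{res.seqid.num}/{atom.name}"
                    )
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                rads.append(radii[elem])
                elements.append(elem)
                names.append(atom.name)
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                restypes.append(one)
    if not coords:
        warnings.warn(f"{path}: no protein residues found "
                      f"({skipped_het} non-protein residues skipped)")
        coords = np.empty((0, 3))
    return StructureContext(coords, rads, elements, names, chains, resnums,
                            restypes, offsets)


def neighbors_of(ctx: StructureContext, position: int, radius: float,
                 chain: str | None = None) -> set[tuple[str, int]]:
    """Residues (any chain) with >=1 atom within ``radius`` A of any atom of
    the query residue, excluding the query residue itself."""
    chain = chain or ctx.chain_ids[0]
    resnum = ctx.resnum_for_position(position, chain)
    if (chain, resnum) not in ctx.residue_index:
        raise UnresolvedPositionError(
            f"position {position} (chain {chain}) is not in the structure; "
            "score it in A-C mode"
        )
    own = ctx.residue_atoms(chain, resnum)
    pts = ctx.coords[own]
    out: set[tuple[str, int]] = set()
    for i in ctx.query_radius(pts, radius):
        key = (ctx.chains[i], ctx.resnums[i])
        if key != (chain, resnum):
            out.add(key)
    return out


def check_sequence(ctx: StructureContext, sequence: str, chain: str | None = None
                   ) -> list[tuple[int, str, str]]:
    """Compare structure residue types against a reference protein sequence.

    Returns a list of (position, expected, found) mismatches for resolved
    positions; an empty list means the mapping is consistent.
    """
    chain = chain or ctx.chain_ids[0]
    mismatches = []
    for pos in range(1, len(sequence) + 1):
        resnum = ctx.resnum_for_position(pos, chain)
        if (chain, resnum) in ctx.residue_index:
            found = ctx.residue_type(chain, resnum)
            if found != sequence[pos - 1].upper():
                mismatches.append((pos, sequence[pos - 1].upper(), found))
    return mismatches
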