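"""Deterministic synthetic fixtures: structures, variant tables, registries.

Every module in the package is testable without downloading anything.  The
generators here build small poly-alanine/glycine models with ideal geometry
and, where a test needs a specific steric situation, *verify the planted
feature at generation time* using the package's own detection routines —
an infeasible feature raises instead of silently producing a wrong
fixture.

Geometries
----------
* ``helix`` / ``extended`` — ideal backbones (alpha: rise ~1.5 A,
  ~100 deg/residue; strand: phi -120, psi 120).
* ``cavity`` — a helix whose designated mutation site is caged by a shell
  of backbone-only glycine residues so that *every* rotamer of the
  designated mutant clashes and no torsion move can relieve it.
* ``relief`` — two facing residues placed so the designated mutation
  clashes with a leucine neighbor at its initial chi angles, while an
  exhaustive chi-grid search proves a clash-free arrangement exists.
* ``random`` — CA-only residues scattered uniformly in a box (for
  neighbor-search oracles).

Same seed + spec => byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .properties import ONE_TO_THREE, normalize_residue
from .rotamers import (
    ClashCriterion,
    PlacedRotamer,
    default_rotamer_library,
    detect_clashes,
    place_rotamers,
)
from .structure import StructureContext, Variant, load_structure

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_variant_table",
    "make_registry",
    "make_calibration_frame",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    seed: int = 0
    n_residues: int = 20
    geometry: str = "helix"  # helix | extended | cavity | relief | random
    sequence: str | None = None  # default poly-alanine
    target_position: int | None = None  # cavity/relief feature site
    target_mut: str = "W"  # designated mutation for cavity/relief checks
    cage_radius: float = 5.0
    cage_points: int = 80
    box_size: float = 25.0  # random geometry


def _pdb_line(serial: int, name: str, res3: str, chain: str, resnum: int,
              xyz, element: str) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {nm:<4s} {res3:>3s} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def _write_pdb(records, path) -> None:
    lines = []
    for serial, rec in enumerate(records, start=1):
        lines.append(_pdb_line(serial, *rec))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _backbone_records(residues, sequence, chain="A", start=1):
    """(name, res3, chain, resnum, xyz, element) records for a backbone."""
    lib = default_rotamer_library()
    records = []
    for i, res in enumerate(residues):
        one = sequence[i]
        res3 = ONE_TO_THREE[one]
        atoms = dict(res)
        if one == "G":
            atoms.pop("CB", None)
        elif one != "A":
            chis = lib.rotamers(one)[0][0]  # most probable rotamer
            atoms.update(geometry.build_side_chain(res3, atoms, chis))
        for name, xyz in atoms.items():
            records.append((name, res3, chain, start + i, xyz, name[0]))
    return records


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _sequence_for(spec: FixtureSpec) -> str:
    if spec.sequence is not None:
        seq = "".join(normalize_residue(c) for c in spec.sequence)
        if len(seq) != spec.n_residues:
            raise ValueError("sequence length must match n_residues")
        return seq
    return "A" * spec.n_residues


def _grid_has_clash_free(ctx: StructureContext, variant: Variant,
                         neighbor_keys, criterion: ClashCriterion,
                         step: float = 30.0) -> bool:
    """Exhaustive chi-grid oracle: does any (mutant chi x neighbor chi)
    combination avoid all clashes?  Neighbor grids cover chi1 only (the
    dominant escape move); the mutant grid covers all its chis."""
    lib = default_rotamer_library()
    mut3 = ONE_TO_THREE[normalize_residue(variant.mut)]
    nchi = geometry.N_CHI[mut3]
    grid = np.arange(-180.0, 180.0, step)
    frame = ctx.atom_map(ctx.chain_ids[0], ctx.resnum_for_position(
        variant.position, ctx.chain_ids[0]))
    frame = {k: np.asarray(v) for k, v in frame.items()}
    if "CB" not in frame:
        frame["CB"] = geometry.cb_position(frame["N"], frame["CA"], frame["C"])

    nbr_variants: list[list[np.ndarray | None]] = []
    movable = []
    for key in neighbor_keys:
        res3 = ONE_TO_THREE[ctx.residue_type(*key)]
        if geometry.N_CHI.get(res3, 0) == 0:
            continue
        amap = ctx.atom_map(*key)
        if "CB" not in amap:
            continue
        chis = geometry.measure_chis(res3, amap)
        if len(chis) < geometry.N_CHI[res3]:
            continue
        movable.append((key, res3, chis))

    def ctx_with_neighbor_chis(nbr_chi1s):
        coords = ctx.coords.copy()
        for (key, res3, chis), chi1 in zip(movable, nbr_chi1s):
            amap = {ctx.names[i]: ctx.coords[i] for i in ctx.residue_atoms(*key)}
            new = geometry.build_side_chain(res3, amap, [chi1] + list(chis[1:]))
            n2i = {ctx.names[i]: i for i in ctx.residue_atoms(*key)}
            for nm, xyz in new.items():
                if nm in n2i:
                    coords[n2i[nm]] = xyz
        return ctx.with_coords(coords)

    nbr_grids = [grid] * len(movable) if movable else [np.array([0.0])]
    for nbr_choice in itertools.product(*nbr_grids):
        c2 = ctx_with_neighbor_chis(nbr_choice if movable else [])
        for mut_chis in itertools.product(grid, repeat=nchi):
            atoms = {"CB": frame["CB"]}
            if mut3 != "GLY":
                atoms.update(geometry.build_side_chain(mut3, frame, mut_chis))
            rot = PlacedRotamer(
                chain=ctx.chain_ids[0],
                resnum=ctx.resnum_for_position(variant.position, ctx.chain_ids[0]),
                res_type=normalize_residue(variant.mut),
                chi=tuple(mut_chis), probability=1.0, atoms=atoms,
            )
            if not detect_clashes(c2, rot, criterion):
                # also require moved neighbors stay clash-free vs the rest
                return True
    return False


def make_structure(spec: FixtureSpec, out_path) -> Path:
    """Generate the structure described by ``spec`` and write it as PDB."""
    out_path = Path(out_path)
    seq = _sequence_for(spec)
    criterion = ClashCriterion()

    if spec.geometry in ("helix", "extended"):
        phi, psi = (-57.0, -47.0) if spec.geometry == "helix" else (-120.0, 120.0)
        residues = geometry.build_backbone(spec.n_residues, phi=phi, psi=psi)
        _write_pdb(_backbone_records(residues, seq), out_path)
        return out_path

    if spec.geometry == "random":
        rng = np.random.default_rng(spec.seed)
        records = []
        coords = rng.uniform(0, spec.box_size, size=(spec.n_residues, 3))
        for i, xyz in enumerate(coords):
            records.append(("CA", "GLY", "A", i + 1, xyz, "C"))
        _write_pdb(records, out_path)
        return out_path

    if spec.geometry == "cavity":
        target = spec.target_position or (spec.n_residues // 2 + 1)
        residues = geometry.build_backbone(spec.n_residues)
        records = _backbone_records(residues, seq)
        frame = residues[target - 1]
        u = frame["CB"] - frame["CA"]
        u /= np.linalg.norm(u)
        center = frame["CA"] + 4.0 * u
        helix_xyz = np.array([r[4] for r in records])
        shell = center + spec.cage_radius * _fibonacci_sphere(spec.cage_points)
        resnum = spec.n_residues + 1
        for pt in shell:
            if np.min(np.linalg.norm(helix_xyz - pt, axis=1)) < 2.9:
                continue  # don't fuse the cage into the helix
            records.append(("CA", "GLY", "B", resnum, pt, "C"))
            resnum += 1
        _write_pdb(records, out_path)
        ctx = load_structure(out_path, fmt="pdb")
        variant = Variant(position=target, wt=seq[target - 1], mut=spec.target_mut)
        rots = place_rotamers(ctx, variant, default_rotamer_library())
        if any(not detect_clashes(ctx, r, criterion) for r in rots):
            raise ValueError("cavity fixture infeasible: a rotamer escapes the cage")
        if _grid_has_clash_free(ctx, variant, [], criterion):
            raise ValueError("cavity fixture infeasible: chi grid finds a gap")
        return out_path

    if spec.geometry == "relief":
        target = spec.target_position or 1
        if target != 1:
            raise ValueError("relief geometry places the target at position 1")
        mut = normalize_residue(spec.target_mut)
        lib = default_rotamer_library()
        base = geometry.build_backbone(1)[0]
        # candidate separations and neighbor (leucine) starting chis
        for d in (9.0, 9.5, 10.0, 10.5, 8.5, 11.0):
            u = base["CB"] - base["CA"]
            u /= np.linalg.norm(u)
            mid = base["CA"] + 0.5 * d * u
            mirrored = {k: 2 * mid - v for k, v in base.items()}
            for chi_l in ([-65.0, 175.0], [-177.0, 65.0], [-85.0, 65.0],
                          [-65.0, 100.0], [-120.0, 175.0]):
                records = []
                for name, xyz in base.items():
                    records.append((name, ONE_TO_THREE[seq[0]] if seq[0] != "G"
                                    else "GLY", "A", 1, xyz, name[0]))
                nbr_atoms = dict(mirrored)
                nbr_atoms.update(geometry.build_side_chain("LEU", mirrored, chi_l))
                for name, xyz in nbr_atoms.items():
                    records.append((name, "LEU", "B", 2, xyz, name[0]))
                _write_pdb(records, out_path)
                ctx = load_structure(out_path, fmt="pdb")
                variant = Variant(position=1, wt=seq[0], mut=mut)
                rots = place_rotamers(ctx, variant, lib)
                top = rots[0]
                if not detect_clashes(ctx, top, criterion):
                    continue  # no planted clash; try next arrangement
                if _grid_has_clash_free(ctx, variant, [("B", 2)], criterion):
                    return out_path
        raise ValueError("relief fixture infeasible: no clash+escape arrangement found")

    raise ValueError(f"unknown fixture geometry: {spec.geometry!r}")


def make_variant_table(n: int, seed: int = 0, max_position: int = 1159,
                       acmg_mix: dict[int, float] | None = None,
                       out_path=None) -> pd.DataFrame:
    """Deterministic table of parseable HGVS missense rows.

    ``acmg_mix`` maps ACMG class -> sampling weight; omit for no class
    column.
    """
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for _ in range(n):
        pos = int(rng.integers(1, max_position + 1))
        wt, mt = rng.choice(aas, size=2, replace=False)
        row = {"variant": f"p.{ONE_TO_THREE[wt].capitalize()}{pos}"
                          f"{ONE_TO_THREE[mt].capitalize()}"}
        if acmg_mix:
            classes = sorted(acmg_mix)
            w = np.array([acmg_mix[c] for c in classes], dtype=float)
            row["acmg_class"] = int(rng.choice(classes, p=w / w.sum()))
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def make_registry(positions, out_path=None) -> pd.DataFrame:
    """Hotspot registry table from a list of pathogenic positions."""
    df = pd.DataFrame({"position": sorted(int(p) for p in positions)})
    df["wt"] = ""
    df["mut"] = ""
    df["acmg_class"] = 5
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def make_calibration_frame(breakpoint: float = 3.25, n_per_bin: int = 40,
                           rise_per_bin: float = 0.025,
                           position: int = 460) -> pd.DataFrame:
    """Scored table whose pathogenic fraction is an exact ramp-then-plateau.

    The fraction rises by ``rise_per_bin`` per 0.25 SPS step up to
    ``breakpoint`` and is flat beyond, so the saturation fit recovers the
    breakpoint exactly (constructed inverse; ``rise_per_bin * n_per_bin``
    must be an integer).
    """
    from .scoring import SPS_GRID

    k_path = {}
    for s in SPS_GRID:
        steps = (min(s, breakpoint) - 1.0) / 0.25
        k = steps * rise_per_bin * n_per_bin
        if abs(k - round(k)) > 1e-9:
            raise ValueError("rise_per_bin * n_per_bin must give integer counts")
        k_path[s] = int(round(k))
    rows = []
    for s in SPS_GRID:
        for i in range(n_per_bin):
            cls = 4 if i < k_path[s] else 3
            rows.append({"sps": s, "acmg_class": cls, "position": position})
    return pd.DataFrame(rows)
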