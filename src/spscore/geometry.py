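"""Internal-coordinate geometry: atom placement and side-chain templates.

Side chains are constructed from ideal internal coordinates (bond lengths,
bond angles, and dihedrals) using the standard NeRF construction: each atom
is placed from three previously placed reference atoms plus (length, angle,
dihedral).  Rotatable dihedrals are the chi angles supplied by a rotamer
library; branch atoms ride on the same chi with a fixed offset, and ring
atoms use fixed dihedrals.

The templates cover heavy atoms of the 20 canonical residues.  Proline's
ring is approximated with fixed pseudo-chi values (its pucker is not a free
rotamer here).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "SIDECHAIN_TEMPLATES",
    "CHI_DEFS",
    "N_CHI",
    "build_side_chain",
    "measure_chis",
    "build_backbone",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to ``c`` with angle B-C-D and dihedral A-B-C-D."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # colinear references: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(dih),
        length * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    cosa = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosa))))


# Each template row: (atom, ref1, ref2, ref3, bond, angle, dihedral_spec)
# placing `atom` bonded to ref3 with angle ref2-ref3-atom and dihedral
# ref1-ref2-ref3-atom.  dihedral_spec is a float (fixed) or ("chi", k, offset)
# meaning chi_k + offset degrees.
_T = {}

_T["ALA"] = []
_T["GLY"] = []
_T["SER"] = [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))]
_T["CYS"] = [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))]
_T["THR"] = [
    ("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
    ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
]
_T["VAL"] = [
    ("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
    ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 120.0)),
]
_T["LEU"] = [
    ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
    ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
    ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 120.0)),
]
_T["ILE"] = [
    ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
    ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
    ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0)),
]
_T["MET"] = [
    ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
    ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
    ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0)),
]
_T["PRO"] = [
    # ring pucker reduced to chi1; CD closes the ring at a fixed dihedral
    ("CG", "N", "CA", "CB", 1.492, 104.5, ("chi", 1, 0.0)),
    ("CD", "CA", "CB", "CG", 1.503, 105.5, -35.0),
]
_T["PHE"] = [
    ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
    ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 0.0)),
    ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 180.0)),
    ("CE1", "CB", "CG", "CD1", 1.393, 120.1, 180.0),
    ("CE2", "CB", "CG", "CD2", 1.393, 120.1, 180.0),
    ("CZ", "CG", "CD1", "CE1", 1.389, 120.0, 0.0),
]
_T["TYR"] = _T["PHE"][:] + [
    ("OH", "CD1", "CE1", "CZ", 1.380, 119.9, 180.0),
]
_T["TRP"] = [
    ("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
    ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
    ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi", 2, 180.0)),
    ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
    ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
    ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
    ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
    ("CZ3", "CG", "CD2", "CE3", 1.382, 118.7, 180.0),
    ("CH2", "CD2", "CE2", "CZ2", 1.368, 117.5, 0.0),
]
_T["HIS"] = [
    ("CG", "N", "CA", "CB", 1.504, 113.8, ("chi", 1, 0.0)),
    ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2, 0.0)),
    ("CD2", "CA", "CB", "CG", 1.354, 131.0, ("chi", 2, 180.0)),
    ("CE1", "CB", "CG", "ND1", 1.320, 109.2, 180.0),
    ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0),
]
_T["ASP"] = [
    ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
    ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
    ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0)),
]
_T["ASN"] = [
    ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
    ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
    ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0)),
]
_T["GLU"] = [
    ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
    ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
    ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
    ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0)),
]
_T["GLN"] = [
    ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
    ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
    ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
    ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0)),
]
_T["LYS"] = [
    ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
    ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
    ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
    ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0)),
]
_T["ARG"] = [
    ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
    ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
    ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
    ("CZ", "CG", "CD", "NE", 1.329, 124.2, ("chi", 4, 0.0)),
    ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
    ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
]

SIDECHAIN_TEMPLATES: Mapping[str, list] = _T

# chi_k is defined by the dihedral over these four atoms.
CHI_DEFS: Mapping[str, list[tuple[str, str, str, str]]] = {}
for _res, _rows in _T.items():
    defs = []
    for (atom, r1, r2, r3, _l, _a, dspec) in _rows:
        if isinstance(dspec, tuple) and dspec[2] == 0.0:
            defs.append((r1, r2, r3, atom))
    CHI_DEFS[_res] = defs

N_CHI = {res: len(defs) for res, defs in CHI_DEFS.items()}


def build_side_chain(res_type: str, frame: Mapping[str, np.ndarray],
                     chis: Sequence[float]) -> dict[str, np.ndarray]:
    """Build heavy side-chain atoms beyond CB for ``res_type``.

    ``frame`` must contain N, CA and (except glycine) CB coordinates.
    Returns atom-name -> xyz for the newly built atoms only.
    """
    rows = SIDECHAIN_TEMPLATES[res_type]
    nchi = N_CHI[res_type]
    if len(chis) < nchi:
        raise ValueError(f"{res_type} needs {nchi} chi angles, got {len(chis)}")
    pos = dict(frame)
    built: dict[str, np.ndarray] = {}
    for (atom, r1, r2, r3, length, angle, dspec) in rows:
        if isinstance(dspec, tuple):
            _, k, offset = dspec
            dih = float(chis[k - 1]) + offset
        else:
            dih = float(dspec)
        xyz = place_atom(pos[r1], pos[r2], pos[r3], length, angle, dih)
        pos[atom] = xyz
        built[atom] = xyz
    return built


def measure_chis(res_type: str, coords: Mapping[str, np.ndarray]) -> list[float]:
    """Measure the chi angles of a residue from its atom coordinates.

    Missing atoms truncate the list (only leading measurable chis are
    returned).
    """
    chis: list[float] = []
    for (a, b, c, d) in CHI_DEFS.get(res_type, []):
        if any(name not in coords for name in (a, b, c, d)):
            break
        chis.append(dihedral(coords[a], coords[b], coords[c], coords[d]))
    return chis


# Ideal backbone internal coordinates.
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_C_N_CA, _ANG_N_CA_C, _ANG_CA_C_N, _ANG_CA_C_O = 121.7, 111.2, 116.2, 120.8
_CB_LEN, _ANG_N_CA_CB = 1.530, 110.4


def cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB from backbone N, CA, C (L-configuration)."""
    # dihedral C-N-CA-CB = -122.55 deg gives the L-amino-acid hand
    return place_atom(c, n, ca, _CB_LEN, _ANG_N_CA_CB, -122.55)


def build_backbone(n_residues: int, phi: float = -57.0, psi: float = -47.0,
                   omega: float = 180.0, with_cb: bool = True) -> list[dict[str, np.ndarray]]:
    """Build an ideal polypeptide backbone (N, CA, C, O [, CB]) per residue.

    Default torsions give an alpha helix (rise ~1.5 A, ~100 deg/residue);
    phi=-120, psi=120 gives an extended strand.
    """
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_N_CA, 0.0, 0.0])
    c0 = place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0, _CA_C, _ANG_N_CA_C, phi)
    res = {"N": n0, "CA": ca0, "C": c0}
    for i in range(n_residues):
        n, ca, c = res["N"], res["CA"], res["C"]
        if i < n_residues - 1:
            n_next = place_atom(n, ca, c, _C_N, _ANG_CA_C_N, psi)
        else:
            n_next = place_atom(n, ca, c, _C_N, _ANG_CA_C_N, psi)  # only for O placement
        # carbonyl O opposite the next N
        res["O"] = place_atom(n, ca, c, _C_O, _ANG_CA_C_O,
                              dihedral(n, ca, c, n_next) + 180.0)
        if with_cb:
            res["CB"] = cb_position(n, ca, c)
        residues.append(res)
        if i == n_residues - 1:
            break
        ca_next = place_atom(ca, c, n_next, _N_CA, _ANG_C_N_CA, omega)
        c_next = place_atom(c, n_next, ca_next, _CA_C, _ANG_N_CA_C, phi)
        res = {"N": n_next, "CA": ca_next, "C": c_next}
    return residues
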