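"""Amino-acid property tables and the structure-independent scores.

Three of the five components of the structural pathogenicity score need no
3D coordinates at all:

* **Score A** — change in residue size, the median over one or more size
  tables (residue volume, maximum accessible surface area) of the
  normalized absolute difference between mutant and wild type.
* **Score B** — change in hydrophobic character, the median over several
  hydrophobicity scales of the same normalized absolute difference
  (default: four widely used scales).
* **Score C** — formal-charge alteration: half a point per unit of charge
  gained or lost, so a full charge inversion (e.g. Glu->Lys) scores 1.

Each table is normalized by its own maximum pairwise difference, so every
per-table contribution lies in [0, 1] and at least one substitution attains
exactly 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from statistics import median
from typing import Iterable, Mapping

__all__ = [
    "CANONICAL_AA",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "normalize_residue",
    "PropertyTable",
    "ChargeAssignment",
    "load_property_table",
    "default_size_tables",
    "default_hydrophobicity_scales",
    "score_A",
    "score_B",
    "score_C",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_AA = tuple(sorted(ONE_TO_THREE))


class UnknownResidueError(ValueError):
    """Raised when a residue code is not one of the 20 canonical residues."""


def normalize_residue(code: str) -> str:
    """Return the canonical one-letter code for ``code``.

    Accepts one- or three-letter codes, case-insensitively.  Anything else
    raises :class:`UnknownResidueError` naming the offending code.
    """
    if not isinstance(code, str):
        raise UnknownResidueError(f"residue code must be a string, got {code!r}")
    c = code.strip().upper()
    if len(c) == 1 and c in ONE_TO_THREE:
        return c
    if len(c) == 3 and c in THREE_TO_ONE:
        return THREE_TO_ONE[c]
    raise UnknownResidueError(f"unknown residue code: {code!r}")


@dataclass(frozen=True)
class PropertyTable:
    """A per-residue numeric scale with its normalization constant.

    ``max_pair_diff`` is the maximum of ``|values[i] - values[j]|`` over all
    ordered residue pairs, computed at load time; dividing any pairwise
    absolute difference by it yields a value in [0, 1].
    """

    name: str
    kind: str  # "size" or "hydrophobicity"
    values: Mapping[str, float]
    max_pair_diff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("size", "hydrophobicity"):
            raise ValueError(f"unknown table kind: {self.kind!r}")
        missing = [aa for aa in CANONICAL_AA if aa not in self.values]
        if missing:
            raise ValueError(f"table {self.name!r} missing residues: {missing}")
        vals = [float(self.values[aa]) for aa in CANONICAL_AA]
        diff = max(vals) - min(vals)
        if diff <= 0:
            raise ValueError(f"table {self.name!r} is constant; cannot normalize")
        object.__setattr__(self, "max_pair_diff", diff)

    def normalized_diff(self, wt: str, mut: str) -> float:
        """|value(mut) - value(wt)| / max_pair_diff, in [0, 1]."""
        w = normalize_residue(wt)
        m = normalize_residue(mut)
        return abs(float(self.values[m]) - float(self.values[w])) / self.max_pair_diff


@dataclass(frozen=True)
class ChargeAssignment:
    """Formal charges at physiological pH: D,E = -1; K,R = +1; others 0.

    Histidine is neutral by default (pH 7.4); pass ``histidine_positive=True``
    to treat it as +1.
    """

    histidine_positive: bool = False
    charges: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        charges = {aa: 0 for aa in CANONICAL_AA}
        charges["D"] = charges["E"] = -1
        charges["K"] = charges["R"] = +1
        if self.histidine_positive:
            charges["H"] = +1
        object.__setattr__(self, "charges", charges)

    def charge(self, residue: str) -> int:
        return self.charges[normalize_residue(residue)]


def load_property_table(path, name: str | None = None, kind: str = "size") -> PropertyTable:
    """Load a two-column (residue, value) TSV into a :class:`PropertyTable`.

    Lines starting with ``#`` are comments; a ``residue\\tvalue`` header row
    is accepted and skipped.
    """
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "residue":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: malformed row {row!r}")
            values[normalize_residue(row[0])] = float(row[1])
    return PropertyTable(name=name or str(path), kind=kind, values=values)


def _data_path(filename: str):
    return resources.files("spscore.data").joinpath(filename)


def default_size_tables() -> list[PropertyTable]:
    """Residue volume (Zamyatnin) and maximum ASA (Tien et al.) tables."""
    return [
        load_property_table(_data_path("volume_zamyatnin.tsv"), "volume_zamyatnin", "size"),
        load_property_table(_data_path("surface_tien.tsv"), "surface_tien", "size"),
    ]


def default_hydrophobicity_scales() -> list[PropertyTable]:
    """Four standard hydrophobicity scales (Kyte-Doolittle, Hopp-Woods,
    Eisenberg consensus, Janin)."""
    return [
        load_property_table(_data_path(f), f.removesuffix(".tsv"), "hydrophobicity")
        for f in (
            "hydro_kyte_doolittle.tsv",
            "hydro_hopp_woods.tsv",
            "hydro_eisenberg.tsv",
            "hydro_janin.tsv",
        )
    ]


def _median_normalized_diff(
    wt: str, mut: str, tables: Iterable[PropertyTable], kind: str
) -> float:
    tables = list(tables)
    if not tables:
        raise ValueError(f"at least one {kind} table is required")
    for t in tables:
        if t.kind != kind:
            raise ValueError(f"table {t.name!r} has kind {t.kind!r}, expected {kind!r}")
    # median of an even count = mean of the two central values
    return float(median(t.normalized_diff(wt, mut) for t in tables))


def score_A(wt: str, mut: str, size_tables: Iterable[PropertyTable] | None = None) -> float:
    """Size-alteration score: median normalized |volume/surface difference|."""
    if size_tables is None:
        size_tables = default_size_tables()
    return _median_normalized_diff(wt, mut, size_tables, "size")


def score_B(wt: str, mut: str, scales: Iterable[PropertyTable] | None = None) -> float:
    """Hydrophobicity-alteration score: median normalized difference over scales."""
    if scales is None:
        scales = default_hydrophobicity_scales()
    return _median_normalized_diff(wt, mut, scales, "hydrophobicity")


def score_C(wt: str, mut: str, charges: ChargeAssignment | None = None) -> float:
    """Charge-alteration score: |q(mut) - q(wt)| / 2, i.e. 0, 0.5 or 1."""
    if charges is None:
        charges = ChargeAssignment()
    return abs(charges.charge(mut) - charges.charge(wt)) / 2.0
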