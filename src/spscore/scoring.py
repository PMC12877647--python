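"""Aggregation of the five component scores into the scaled SPS.

The structural pathogenicity score (SPS) maps the raw component sum
``A + B + C + D + E`` onto the familiar five-tier clinical scale:

    x = (sum / scale_max_sum) * 16
    y = 1 + floor(x + 1/2) / 4

with ``scale_max_sum`` = 3.3, the maximum cumulative value observed in the
hERG study.  The result lies on the 17-value grid {1.00, 1.25, ..., 5.00};
``floor(x + 1/2)`` is round-half-up, matching rounding to the nearest 0.25
increment.  Scores at or above the decision threshold (default 3.25) are
called **high risk**; everything below is **uncertain risk** — never
"benign".

Variants at positions without coordinates are scored in A-C mode: D and E
are set to 0 and the same equation applies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import properties
from .hotspots import PathogenicRegistry, contact_criterion, contacts_of, score_E
from .properties import ChargeAssignment, PropertyTable, score_A, score_B, score_C
from .rotamers import (
    ClashCriterion,
    ReliefConfig,
    RotamerLibrary,
    default_rotamer_library,
    detect_clashes,
    place_rotamers,
    relieve_clashes,
    score_D,
)
from .structure import (
    RegionMap,
    StructureContext,
    Variant,
    default_region_map,
    parse_variant,
)

__all__ = [
    "ScoringConfig",
    "SPS_GRID",
    "scale_sps",
    "classify",
    "ScoreBreakdown",
    "score_variant",
    "batch_score",
]

SPS_GRID = tuple(1.0 + 0.25 * k for k in range(17))


@dataclass
class ScoringConfig:
    """All tunable thresholds and table selections in one place."""

    scale_max_sum: float = 3.3
    threshold: float = 3.25
    pore_threshold: float = 2.5  # advisory flag only, never the primary call
    pore_domain: str = "pore"
    w_relieved: float = 0.5
    rotamer_min_prob: float = 0.10  # strict > filter, hotspot score only
    contact_cutoff: float = -0.4
    clash: ClashCriterion = field(default_factory=ClashCriterion)
    relief: ReliefConfig = field(default_factory=ReliefConfig)
    histidine_positive: bool = False
    size_tables: list[PropertyTable] | None = None
    hydrophobicity_scales: list[PropertyTable] | None = None
    mutation_chain: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 5):
            raise ValueError("threshold must be in (0, 5]")
        if self.scale_max_sum <= 0:
            raise ValueError("scale_max_sum must be positive")

    @property
    def charges(self) -> ChargeAssignment:
        return ChargeAssignment(histidine_positive=self.histidine_positive)

    def resolved_size_tables(self) -> list[PropertyTable]:
        return self.size_tables or properties.default_size_tables()

    def resolved_hydro_scales(self) -> list[PropertyTable]:
        return self.hydrophobicity_scales or properties.default_hydrophobicity_scales()

    def to_provenance(self) -> dict:
        return {
            "scale_max_sum": self.scale_max_sum,
            "threshold": self.threshold,
            "pore_threshold": self.pore_threshold,
            "w_relieved": self.w_relieved,
            "rotamer_min_prob": self.rotamer_min_prob,
            "contact_cutoff": self.contact_cutoff,
            "clash_overlap_cutoff": self.clash.overlap_cutoff,
            "clash_hbond_allowance": self.clash.hbond_allowance,
            "histidine_positive": self.histidine_positive,
            "size_tables": [t.name for t in self.resolved_size_tables()],
            "hydrophobicity_scales": [t.name for t in self.resolved_hydro_scales()],
        }


def scale_sps(raw_sum: float, cfg: ScoringConfig | None = None) -> float:
    """Rescale a raw component sum onto the 1-5 grid in 0.25 steps."""
    cfg = cfg or ScoringConfig()
    if raw_sum < 0:
        raise ValueError(f"raw component sum cannot be negative: {raw_sum}")
    if raw_sum > cfg.scale_max_sum:
        warnings.warn(
            f"raw sum {raw_sum:.4f} exceeds scale maximum {cfg.scale_max_sum}; clamping"
        )
        raw_sum = cfg.scale_max_sum
    x = (raw_sum / cfg.scale_max_sum) * 16.0
    return 1.0 + math.floor(x + 0.5) / 4.0


def classify(sps: float, cfg: ScoringConfig | None = None) -> str:
    """Binary call: 'high' iff sps >= threshold, else 'uncertain'."""
    cfg = cfg or ScoringConfig()
    return "high" if sps >= cfg.threshold else "uncertain"


@dataclass
class ScoreBreakdown:
    """Complete per-variant scoring record."""

    variant: Variant
    A: float
    B: float
    C: float
    D: float
    E: float
    mode: str  # "A-C" or "A-E"
    raw_sum: float
    sps: float
    sps_ac: float  # structure-independent screen (A+B+C only)
    risk: str
    domain: str | None = None
    in_pore: bool = False
    pore_call: str | None = None
    details: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "variant": self.variant.id or self.variant.label,
            "position": self.variant.position,
            "wt": self.variant.wt,
            "mut": self.variant.mut,
            "A": self.A, "B": self.B, "C": self.C, "D": self.D, "E": self.E,
            "raw_sum": self.raw_sum,
            "sps_ac": self.sps_ac,
            "sps": self.sps,
            "mode": self.mode,
            "risk": self.risk,
            "domain": self.domain,
            "in_pore": self.in_pore,
            "pore_call": self.pore_call,
            "error": "",
        }


def score_variant(variant: Variant | str,
                  ctx: StructureContext | None = None,
                  lib: RotamerLibrary | None = None,
                  registry: PathogenicRegistry | None = None,
                  regions: RegionMap | None = None,
                  cfg: ScoringConfig | None = None,
                  mode: str = "auto",
                  collect_details: bool = False) -> ScoreBreakdown:
    """Score one missense variant.

    ``mode`` is ``"ac"`` (structure-independent only), ``"ae"`` (require
    structure) or ``"auto"`` (A-E where the position is resolved and a
    structure is available, A-C otherwise).  A structure/sequence mismatch
    at the position raises rather than emitting a silently wrong score.
    """
    cfg = cfg or ScoringConfig()
    regions = regions or default_region_map()
    if isinstance(variant, str):
        variant = parse_variant(variant)

    a = score_A(variant.wt, variant.mut, cfg.resolved_size_tables())
    b = score_B(variant.wt, variant.mut, cfg.resolved_hydro_scales())
    c = score_C(variant.wt, variant.mut, cfg.charges)
    sps_ac = scale_sps(min(a + b + c, cfg.scale_max_sum), cfg)

    resolved = regions.is_resolved(variant.position)
    use_structure = (mode == "ae") or (mode == "auto" and resolved and ctx is not None)
    if mode == "ae" and (ctx is None or not resolved):
        raise ValueError(
            f"A-E mode needs a structure and a resolved position "
            f"(position {variant.position} resolved={resolved})"
        )

    d = e = 0.0
    details: dict = {}
    if use_structure:
        chain = cfg.mutation_chain or ctx.chain_ids[0]
        resnum = ctx.resnum_for_position(variant.position, chain)
        found = ctx.residue_type(chain, resnum) if ctx.has_position(variant.position, chain) else None
        if found is None:
            raise ValueError(
                f"position {variant.position} marked resolved but absent from the "
                f"structure (chain {chain})"
            )
        if found != variant.wt:
            raise ValueError(
                f"structure/sequence mismatch at position {variant.position}: "
                f"structure has {found}, variant says wild type {variant.wt}"
            )
        lib = lib or default_rotamer_library()
        registry = registry if registry is not None else PathogenicRegistry.empty()
        d = score_D(ctx, variant, lib, criterion=cfg.clash, relief=cfg.relief,
                    w_relieved=cfg.w_relieved, chain=chain)
        e = score_E(ctx, variant, lib, registry, min_prob=cfg.rotamer_min_prob,
                    criterion=contact_criterion(cfg.contact_cutoff), chain=chain)
        if collect_details:
            details = _variant_details(ctx, variant, lib, registry, cfg, chain)

    raw = a + b + c + d + e
    sps = scale_sps(min(raw, cfg.scale_max_sum), cfg)
    domain = regions.domain_of(variant.position)
    in_pore = domain == cfg.pore_domain
    return ScoreBreakdown(
        variant=variant, A=a, B=b, C=c, D=d, E=e,
        mode="A-E" if use_structure else "A-C",
        raw_sum=raw, sps=sps, sps_ac=sps_ac,
        risk=classify(sps, cfg),
        domain=domain, in_pore=in_pore,
        pore_call=("high" if sps >= cfg.pore_threshold else "uncertain") if in_pore else None,
        details=details,
    )


def _variant_details(ctx, variant, lib, registry, cfg, chain) -> dict:
    """Rotamer/clash/contact provenance for the per-variant report."""
    rows = []
    for rot in place_rotamers(ctx, variant, lib, min_prob=0.0, chain=chain):
        clashes = detect_clashes(ctx, rot, cfg.clash)
        relieved = None
        if clashes:
            relieved = relieve_clashes(ctx, rot, cfg.relief).relieved
        cs = contacts_of(ctx, rot, registry, contact_criterion(cfg.contact_cutoff))
        rows.append({
            "chi": list(rot.chi),
            "probability": rot.probability,
            "n_clashes": len(clashes),
            "clashes": [
                {"atom": list(c.atom_a), "partner": list(c.atom_b),
                 "overlap": round(c.overlap, 3)}
                for c in clashes
            ],
            "relieved": relieved,
            "contacts": sorted([list(k) for k in cs.contacts]),
            "n_contacts": cs.n_total,
            "n_pathogenic_contacts": cs.n_pathogenic,
        })
    return {"rotamers": rows}


def batch_score(variants: pd.DataFrame | Iterable[str],
                ctx: StructureContext | None = None,
                lib: RotamerLibrary | None = None,
                registry: PathogenicRegistry | None = None,
                regions: RegionMap | None = None,
                cfg: ScoringConfig | None = None,
                mode: str = "auto",
                details_dir: str | Path | None = None) -> pd.DataFrame:
    """Score a variant table, preserving input order and row count.

    ``variants`` is either an iterable of notation strings or a DataFrame
    with a ``variant`` column (HGVS-style) or explicit ``position``/``wt``/
    ``mut`` columns.  Rows that fail validation carry their message in the
    ``error`` column — they are never dropped.  If ``details_dir`` is given,
    a JSON detail report per successfully scored structural variant is
    written there.
    """
    cfg = cfg or ScoringConfig()
    regions = regions or default_region_map()
    if isinstance(variants, pd.DataFrame):
        if "variant" in variants.columns:
            items = list(variants["variant"].astype(str))
        elif {"position", "wt", "mut"} <= set(variants.columns):
            items = [
                f"{r.wt}{int(r.position)}{r.mut}" for r in variants.itertuples()
            ]
        else:
            raise ValueError(
                "variant table needs a 'variant' column or position/wt/mut columns"
            )
        extra = variants.drop(columns=[c for c in ("variant",) if c in variants],
                              errors="ignore")
    else:
        items = [str(v) for v in variants]
        extra = None

    rows = []
    for i, text in enumerate(items):
        try:
            bd = score_variant(text, ctx=ctx, lib=lib, registry=registry,
                               regions=regions, cfg=cfg, mode=mode,
                               collect_details=details_dir is not None)
            row = bd.to_row()
            if details_dir is not None and bd.details:
                out = Path(details_dir)
                out.mkdir(parents=True, exist_ok=True)
                payload = {"variant": row["variant"], "scores": {
                    k: row[k] for k in ("A", "B", "C", "D", "E", "raw_sum", "sps",
                                        "sps_ac", "mode", "risk")
                }, **bd.details}
                (out / f"{bd.variant.label}.json").write_text(
                    json.dumps(payload, indent=1), encoding="utf-8"
                )
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            row = {"variant": text, "position": None, "wt": None, "mut": None,
                   "A": None, "B": None, "C": None, "D": None, "E": None,
                   "raw_sum": None, "sps_ac": None, "sps": None, "mode": None,
                   "risk": None, "domain": None, "in_pore": None,
                   "pore_call": None, "error": str(exc)}
        rows.append(row)
    result = pd.DataFrame(rows)
    if extra is not None and len(extra) == len(result):
        for col in extra.columns:
            if col not in result.columns:
                result[col] = extra[col].to_numpy()
    return result
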