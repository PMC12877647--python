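"""Calibration of the SPS against clinical (ACMG) classes.

Given a scored variant table carrying ACMG classes 1-5, these routines
reproduce the threshold analysis used to pick the high-risk decision
boundary:

* :func:`calibrate` — per-SPS-bin tallies of ACMG classes and the fraction
  of pathogenic (class 4/5) variants, optionally restricted to a stratum
  (non-structured positions, structured positions, or the pore domain).
* :func:`saturation_fit` — a weighted monotone ramp-then-plateau fit of
  pathogenic fraction vs SPS; the breakpoint is the saturation onset, and
  the bin with the largest jump in fraction is the "rupture" point.
* :func:`concordance` — cross-tabulation of the binary high-risk call
  against an external predictor's categorical calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .scoring import SPS_GRID
from .structure import RegionMap, default_region_map

__all__ = [
    "CalibrationTable",
    "calibrate",
    "SaturationFit",
    "saturation_fit",
    "concordance",
    "plot_calibration",
]

ACMG_CLASSES = (1, 2, 3, 4, 5)


@dataclass
class CalibrationTable:
    """Per-SPS-bin ACMG class counts and pathogenic fractions."""

    table: pd.DataFrame  # index: sps bin; columns: class_1..class_5, total, pathogenic_fraction
    n_input: int
    n_invalid: int  # rows with missing/invalid ACMG labels (excluded)
    stratum: str = "all"

    @property
    def bins(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def fraction(self, sps: float) -> float:
        return float(self.table.loc[sps, "pathogenic_fraction"])


def _stratum_mask(df: pd.DataFrame, stratum: str, regions: RegionMap) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=df.index)
    if "position" not in df.columns:
        raise ValueError("stratum selection needs a 'position' column")
    pos = df["position"].astype(int)
    if stratum == "non-structured":
        return ~pos.map(regions.is_resolved)
    if stratum == "structured":
        return pos.map(regions.is_resolved)
    if stratum == "pore":
        return pos.map(lambda p: regions.domain_of(p) == "pore")
    raise ValueError(f"unknown stratum: {stratum!r}")


def calibrate(scored: pd.DataFrame,
              stratum: Literal["all", "non-structured", "structured", "pore"] = "all",
              regions: RegionMap | None = None,
              sps_column: str = "sps",
              acmg_column: str = "acmg_class") -> CalibrationTable:
    """Tally ACMG classes per SPS bin for the requested stratum.

    Rows with missing or invalid ACMG labels are counted in ``n_invalid``
    and excluded from the fractions; conflicting-interpretation labels
    should be mapped to class 3 upstream.
    """
    regions = regions or default_region_map()
    if sps_column not in scored.columns:
        raise ValueError(f"missing column {sps_column!r}")
    sub = scored[_stratum_mask(scored, stratum, regions)].copy()
    if acmg_column not in sub.columns:
        sub[acmg_column] = pd.Series(dtype=float)
    cls = pd.to_numeric(sub[acmg_column], errors="coerce")
    valid = cls.isin(ACMG_CLASSES)
    n_invalid = int((~valid).sum())
    sub = sub[valid]
    cls = cls[valid].astype(int)

    counts = pd.DataFrame(
        0, index=pd.Index(SPS_GRID, name="sps"),
        columns=[f"class_{k}" for k in ACMG_CLASSES],
    )
    for sps, k in zip(sub[sps_column], cls):
        counts.loc[float(sps), f"class_{k}"] += 1
    counts["total"] = counts.sum(axis=1)
    path = counts["class_4"] + counts["class_5"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts["total"] > 0, path / counts["total"], np.nan)
    counts["pathogenic_fraction"] = frac
    return CalibrationTable(table=counts, n_input=len(scored), n_invalid=n_invalid,
                            stratum=stratum)


@dataclass
class SaturationFit:
    """Ramp-then-plateau fit of pathogenic fraction vs SPS."""

    saturation: float  # breakpoint: onset of the plateau
    rupture: float  # bin with the largest jump in fraction
    plateau_fraction: float
    slope: float
    intercept: float
    sse: float
    degenerate: bool = False
    poor_fit: bool = False
    family: str = "weighted piecewise-linear, single breakpoint"

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.minimum(np.asarray(s, dtype=float), self.saturation)
        return self.intercept + self.slope * s


def saturation_fit(table: CalibrationTable) -> SaturationFit:
    """Fit f(s) = a + b*min(s, c) to (bin, fraction), weighted by bin counts.

    The breakpoint ``c`` is scanned over the SPS grid; ``a, b`` come from
    weighted least squares at each candidate (with b >= 0 enforced — the
    curve is monotone non-decreasing).  Degenerate (constant-fraction)
    inputs are flagged and no fit is attempted; a breakpoint landing on the
    top occupied bin is flagged as a poor fit (no plateau observed).
    """
    tab = table.table
    occupied = tab[tab["total"] > 0]
    if len(occupied) < 4:
        raise ValueError(f"need >=4 non-empty bins, have {len(occupied)}")
    s = occupied.index.to_numpy(dtype=float)
    f = occupied["pathogenic_fraction"].to_numpy(dtype=float)
    w = occupied["total"].to_numpy(dtype=float)
    if np.allclose(f, f[0]):
        return SaturationFit(saturation=float(s[-1]), rupture=float(s[-1]),
                             plateau_fraction=float(f[0]), slope=0.0,
                             intercept=float(f[0]), sse=0.0, degenerate=True)

    best = None
    for c in s[1:]:  # breakpoint must leave at least one rising bin
        x = np.minimum(s, c)
        # weighted least squares for f ~ a + b x
        W = w / w.sum()
        xb = np.sum(W * x)
        fb = np.sum(W * f)
        var = np.sum(W * (x - xb) ** 2)
        if var <= 0:
            continue
        b = np.sum(W * (x - xb) * (f - fb)) / var
        b = max(b, 0.0)  # monotone family
        a = fb - b * xb
        resid = f - (a + b * x)
        sse = float(np.sum(w * resid ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(c), float(a), float(b))
    sse, c, a, b = best
    jumps = np.diff(f)
    rupture = float(s[1 + int(np.argmax(jumps))])
    return SaturationFit(
        saturation=c, rupture=rupture,
        plateau_fraction=float(a + b * c), slope=b, intercept=a, sse=sse,
        poor_fit=(c == float(s[-1])),
    )


def concordance(scored: pd.DataFrame, external: pd.DataFrame,
                key: str = "variant",
                risk_column: str = "risk",
                call_column: str = "call") -> dict:
    """Cross-tabulate high-risk calls against an external predictor.

    ``external`` holds one categorical call per variant.  Duplicate variant
    rows on either side are rejected by name; unmatched variants are
    listed, not silently dropped.
    """
    for name, df in (("scored", scored), ("external", external)):
        dup = df[key][df[key].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate variant rows in {name} table: {sorted(set(dup))}")
    merged = scored[[key, risk_column]].merge(
        external[[key, call_column]], on=key, how="outer", indicator=True
    )
    matched = merged[merged["_merge"] == "both"]
    tab = pd.crosstab(matched[risk_column], matched[call_column])
    out = {
        "n_scored": int(len(scored)),
        "n_external": int(len(external)),
        "n_matched": int(len(matched)),
        "unmatched_scored": sorted(merged.loc[merged["_merge"] == "left_only", key]),
        "unmatched_external": sorted(merged.loc[merged["_merge"] == "right_only", key]),
        "crosstab": tab,
    }
    high = matched[matched[risk_column] == "high"]
    out["n_high"] = int(len(high))
    by_call = high[call_column].value_counts().to_dict()
    out["high_risk_by_external_call"] = {str(k): int(v) for k, v in by_call.items()}
    out["high_risk_concordance_pct"] = {
        str(k): round(100.0 * v / len(high), 1) for k, v in by_call.items()
    } if len(high) else {}
    return out


def plot_calibration(table: CalibrationTable, path) -> None:
    """Stacked ACMG-class bar chart per SPS bin with pathogenic fractions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = table.table
    fig, ax = plt.subplots(figsize=(9, 4.5))
    bottom = np.zeros(len(tab))
    colors = {1: "#2166ac", 2: "#67a9cf", 3: "#bdbdbd", 4: "#ef8a62", 5: "#b2182b"}
    for k in ACMG_CLASSES:
        vals = tab[f"class_{k}"].to_numpy(dtype=float)
        ax.bar(tab.index, vals, width=0.2, bottom=bottom,
               color=colors[k], label=f"class {k}")
        bottom += vals
    for x, total, frac in zip(tab.index, tab["total"], tab["pathogenic_fraction"]):
        if total > 0:
            ax.text(x, total, f"{100 * frac:.0f}%", ha="center", va="bottom",
                    fontsize=7)
    ax.set_xlabel("SPS")
    ax.set_ylabel(f"variants ({table.stratum})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
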