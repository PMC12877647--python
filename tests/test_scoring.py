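"""SPS scaling, classification, per-variant and batch scoring."""

import json

import numpy as np
import pandas as pd
import pytest

from spscore import (
    PathogenicRegistry,
    ScoringConfig,
    SPS_GRID,
    Variant,
    batch_score,
    classify,
    scale_sps,
    score_variant,
)
from spscore.properties import CANONICAL_AA, PropertyTable


class TestScaleSps:
    @pytest.mark.parametrize("raw,expected", [
        (0.0, 1.0),      # observed minimum maps to 1
        (3.30, 5.0),     # observed maximum maps to 5
        (1.65, 3.0),     # midpoint: x = 8 -> y = 3
        (1.8566086797, 3.25),
    ])
    def test_endpoints_and_midpoint(self, raw, expected):
        assert scale_sps(raw) == expected

    def test_image_confined_to_grid_over_dense_sweep(self):
        grid = set(SPS_GRID)
        values = [scale_sps(s) for s in np.linspace(0, 3.3, 4001)]
        assert set(values) <= grid
        assert min(values) == 1.0 and max(values) == 5.0

    def test_monotone_non_decreasing(self):
        sweep = np.linspace(0, 3.3, 4001)
        vals = [scale_sps(s) for s in sweep]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scale_sps(-0.01)

    def test_above_maximum_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert scale_sps(3.5) == 5.0

    def test_round_half_up_tie(self):
        # x + 0.5 integral: floor semantics round up
        cfg = ScoringConfig(scale_max_sum=3.2)
        raw = 0.5 / 16 * 3.2  # x = 0.5 -> floor(1.0) = 1 -> 1.25
        assert scale_sps(raw, cfg) == 1.25


class TestClassify:
    @pytest.mark.parametrize("sps,call", [
        (3.25, "high"), (3.0, "uncertain"), (5.0, "high"), (1.0, "uncertain"),
    ])
    def test_threshold_rule(self, sps, call):
        assert classify(sps) == call

    def test_never_returns_benign(self):
        assert {classify(s) for s in SPS_GRID} == {"high", "uncertain"}

    def test_threshold_equivalence_on_raw_scale(self):
        # high call <=> raw >= 8.5 * scale_max_sum / 16 (~1.7531 at defaults)
        cut = 8.5 * 3.3 / 16
        for raw in np.linspace(0, 3.3, 2000):
            assert (classify(scale_sps(raw)) == "high") == (raw >= cut - 1e-12)


def _flat_tables():
    """Tables making A = B = 0 for K<->R (identical values for K and R)."""
    vals = {aa: float(i) for i, aa in enumerate(CANONICAL_AA)}
    vals["R"] = vals["K"]
    size = PropertyTable("s", "size", vals)
    hyd = PropertyTable("h", "hydrophobicity", vals)
    return [size], [hyd]


class TestScoreVariant:
    def test_unresolved_position_forces_ac_mode(self, helix_ctx, rotamer_lib):
        bd = score_variant("G903R", ctx=helix_ctx, lib=rotamer_lib)
        assert bd.mode == "A-C"
        assert bd.D == 0.0 and bd.E == 0.0
        assert bd.raw_sum == pytest.approx(bd.A + bd.B + bd.C)

    def test_all_zero_components_score_one_uncertain(self):
        size, hyd = _flat_tables()
        cfg = ScoringConfig(size_tables=size, hydrophobicity_scales=hyd)
        bd = score_variant("K903R", cfg=cfg)
        assert (bd.A, bd.B, bd.C) == (0.0, 0.0, 0.0)
        assert bd.sps == 1.0 and bd.risk == "uncertain"

    def test_structural_mode_on_fixture(self, helix_ctx, rotamer_lib):
        from spscore.structure import RegionMap

        regions = RegionMap(unresolved=((100, 200),))
        reg = PathogenicRegistry(positions=frozenset({7, 13}))
        bd = score_variant("A10W", ctx=helix_ctx, lib=rotamer_lib,
                           registry=reg, regions=regions)
        assert bd.mode == "A-E"
        assert bd.D >= 0 and bd.E > 0
        assert bd.sps >= bd.sps_ac  # non-negative D,E never lower the score

    def test_sequence_mismatch_is_an_error(self, helix_ctx, rotamer_lib):
        from spscore.structure import RegionMap

        regions = RegionMap(unresolved=((100, 200),))
        with pytest.raises(ValueError, match="mismatch"):
            score_variant("G10W", ctx=helix_ctx, lib=rotamer_lib,
                          regions=regions)

    def test_ae_mode_without_structure_rejected(self):
        with pytest.raises(ValueError, match="A-E"):
            score_variant("A561V", mode="ae")

    def test_gly_arg_swaps_hit_screen_threshold(self):
        # under the default tables, G<->R substitutions in A-C mode land
        # exactly on 3.25, the behavior driving the structure-free screen
        for text in ("G873R", "R885G", "G903R", "G306W"):
            bd = score_variant(text)
            assert bd.mode == "A-C"
        for text in ("G873R", "R885G", "G903R"):
            bd = score_variant(text)
            assert bd.sps_ac == 3.25
            assert bd.risk == "high"

    def test_pore_flag_is_advisory(self):
        bd = score_variant("A561V")
        assert bd.domain == "pore" and bd.in_pore
        assert bd.pore_call in ("high", "uncertain")
        assert bd.risk == "uncertain"  # primary call unaffected


class TestBatchScore:
    def test_shape_and_order(self):
        df = batch_score(["G903R", "A561V", "E698K"])
        assert list(df["variant"]) == ["G903R", "A561V", "E698K"]
        for col in ("A", "B", "C", "D", "E", "raw_sum", "sps_ac", "sps",
                    "mode", "risk"):
            assert col in df.columns

    def test_malformed_rows_kept_with_error(self):
        df = batch_score(["G903R", "garbage", "p.G12G", "X9A", "A561V"])
        assert len(df) == 5
        assert (df["error"] != "").sum() == 3
        assert df.loc[0, "error"] == "" and df.loc[4, "error"] == ""

    def test_row_count_conserved_random_tables(self):
        from spscore.fixtures import make_variant_table

        for seed in range(5):
            table = make_variant_table(17, seed=seed)
            out = batch_score(table)
            assert len(out) == len(table)

    def test_extra_columns_carried_through(self):
        table = pd.DataFrame({"variant": ["G903R", "A561V"],
                              "acmg_class": [3, 4]})
        out = batch_score(table)
        assert list(out["acmg_class"]) == [3, 4]

    def test_detail_reports_written(self, tmp_path, helix_ctx, rotamer_lib):
        from spscore.structure import RegionMap

        regions = RegionMap(unresolved=((100, 200),))
        out = batch_score(["A10M"], ctx=helix_ctx, lib=rotamer_lib,
                          regions=regions, details_dir=tmp_path)
        assert len(out) == 1
        report = json.loads((tmp_path / "A10M.json").read_text())
        assert report["scores"]["mode"] == "A-E"
        assert len(report["rotamers"]) == 9  # full methionine library
        assert all("probability" in r for r in report["rotamers"])
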