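"""Structure-independent scores: size, hydrophobicity, charge."""

import numpy as np
import pytest

from spscore.properties import (
    CANONICAL_AA,
    ChargeAssignment,
    PropertyTable,
    UnknownResidueError,
    default_hydrophobicity_scales,
    default_size_tables,
    load_property_table,
    normalize_residue,
    score_A,
    score_B,
    score_C,
)
from conftest import ALL_ORDERED_PAIRS


def _uniform_table(name, kind, overrides, lo_res="G", hi_res="W"):
    """Table with values 0.5 everywhere except anchors lo=0, hi=1 and
    explicit overrides, so max_pair_diff is exactly 1."""
    vals = {aa: 0.5 for aa in CANONICAL_AA}
    vals[lo_res] = 0.0
    vals[hi_res] = 1.0
    vals.update(overrides)
    return PropertyTable(name=name, kind=kind, values=vals)


class TestResidueCodes:
    @pytest.mark.parametrize("code,expected", [
        ("C", "C"), ("c", "C"), ("Phe", "F"), ("GLY", "G"), ("arg", "R"),
    ])
    def test_normalization(self, code, expected):
        assert normalize_residue(code) == expected

    @pytest.mark.parametrize("bad", ["X", "B", "Xaa", "", "ZZ", "SEC"])
    def test_rejection_names_code(self, bad):
        with pytest.raises(UnknownResidueError) as exc:
            normalize_residue(bad)
        assert repr(bad) in str(exc.value)

    def test_exactly_twenty(self):
        assert len(CANONICAL_AA) == 20


class TestPropertyTables:
    def test_defaults_cover_all_residues(self):
        for t in default_size_tables() + default_hydrophobicity_scales():
            assert set(t.values) == set(CANONICAL_AA)
            assert t.max_pair_diff > 0

    def test_normalization_attains_one(self):
        # for each table some ordered pair hits normalized difference 1
        for t in default_size_tables() + default_hydrophobicity_scales():
            diffs = [t.normalized_diff(w, m) for w, m in ALL_ORDERED_PAIRS]
            assert max(diffs) == pytest.approx(1.0)
            assert all(0.0 <= d <= 1.0 for d in diffs)

    def test_constant_table_rejected(self):
        with pytest.raises(ValueError):
            PropertyTable("flat", "size", {aa: 1.0 for aa in CANONICAL_AA})

    def test_tsv_round_trip(self, tmp_path):
        src = default_size_tables()[0]
        p = tmp_path / "vol.tsv"
        p.write_text("residue\tvalue\n" + "\n".join(
            f"{aa}\t{src.values[aa]}" for aa in CANONICAL_AA))
        again = load_property_table(p, "vol", "size")
        assert again.values == dict(src.values)
        assert again.max_pair_diff == src.max_pair_diff


class TestScoreSymmetryAndRange:
    def test_symmetry_identity_range_all_pairs(self):
        size = default_size_tables()
        hydro = default_hydrophobicity_scales()
        charges = ChargeAssignment()
        for w, m in ALL_ORDERED_PAIRS:
            a, b, c = score_A(w, m, size), score_B(w, m, hydro), score_C(w, m, charges)
            assert a == pytest.approx(score_A(m, w, size))
            assert b == pytest.approx(score_B(m, w, hydro))
            assert c == score_C(m, w, charges)
            assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0
            assert c in (0.0, 0.5, 1.0)
        for aa in CANONICAL_AA:
            assert score_A(aa, aa, size) == 0.0
            assert score_B(aa, aa, hydro) == 0.0
            assert score_C(aa, aa, charges) == 0.0


class TestScoreAB:
    def test_maximizing_pair_matches_enumeration_oracle(self):
        # independent oracle: recompute medians from the raw table values
        tables = default_size_tables()
        raw = {}
        for w, m in ALL_ORDERED_PAIRS:
            diffs = sorted(
                abs(t.values[m] - t.values[w]) / t.max_pair_diff for t in tables
            )
            raw[(w, m)] = (diffs[0] + diffs[1]) / 2  # two tables -> mean
        best = max(raw, key=raw.get)
        w, m = best
        assert score_A(w, m) == pytest.approx(raw[best])
        assert raw[(m, w)] == raw[best]  # maximizer is symmetric
        assert max(score_A(a, b) for a, b in ALL_ORDERED_PAIRS) == pytest.approx(raw[best])

    def test_even_median_is_mean_of_central_values(self):
        # four scales engineered to give normalized diffs 0.1, 0.3, 0.5, 0.9
        scales = [
            _uniform_table(f"s{i}", "hydrophobicity", {"L": 0.2, "R": 0.2 + d})
            for i, d in enumerate([0.1, 0.3, 0.5, 0.9])
        ]
        assert score_B("L", "R", scales) == pytest.approx(0.4)

    def test_printed_size_example_under_override_tables(self):
        # engineered override set whose median normalized difference for
        # C->F is 0.3798 by construction (surface+volume style pair)
        tables = [
            _uniform_table("vol", "size", {"C": 0.1, "F": 0.1 + 0.3548}),
            _uniform_table("surf", "size", {"C": 0.1, "F": 0.1 + 0.4048}),
        ]
        assert score_A("C", "F", tables) == pytest.approx(0.3798)
        assert score_A("F", "C", tables) == pytest.approx(0.3798)

    def test_printed_hydrophobicity_example_under_override_scales(self):
        diffs = [0.70, 0.7700, 0.8022, 0.90]  # median = 0.7861
        scales = [
            _uniform_table(f"h{i}", "hydrophobicity", {"L": 0.05, "R": 0.05 + d})
            for i, d in enumerate(diffs)
        ]
        assert score_B("L", "R", scales) == pytest.approx(0.7861)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_A("A", "G", default_hydrophobicity_scales())
        with pytest.raises(ValueError):
            score_B("A", "G", default_size_tables())

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            score_A("A", "G", [])


class TestScoreC:
    @pytest.mark.parametrize("wt,mut,expected", [
        ("E", "K", 1.0),   # full charge inversion
        ("D", "A", 0.5),   # loss of one negative charge
        ("A", "L", 0.0),   # neutral to neutral
        ("K", "R", 0.0),   # charge conserved
        ("R", "E", 1.0),
        ("G", "R", 0.5),
    ])
    def test_charge_rule(self, wt, mut, expected):
        assert score_C(wt, mut) == expected

    def test_histidine_switch(self):
        assert score_C("H", "A") == 0.0
        assert score_C("H", "A", ChargeAssignment(histidine_positive=True)) == 0.5
        assert score_C("H", "K", ChargeAssignment(histidine_positive=True)) == 0.0

    def test_charge_values_complete(self):
        ca = ChargeAssignment()
        assert set(ca.charges) == set(CANONICAL_AA)
        assert set(ca.charges.values()) <= {-1, 0, 1}
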