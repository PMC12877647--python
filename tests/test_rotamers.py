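"""Rotamer library, placement, clash detection/relief and the clash score."""

import numpy as np
import pytest

from spscore import (
    ClashCriterion,
    ReliefConfig,
    StructureContext,
    Variant,
    detect_clashes,
    place_rotamers,
    relieve_clashes,
    score_D,
)
from spscore.rotamers import PlacedRotamer, RotamerLibrary
from conftest import brute_force_overlaps


def _two_atom_ctx(d, elements=("C", "C"), radii=None):
    radii = radii or [{"C": 1.70, "N": 1.55, "O": 1.52}[e] for e in elements]
    return StructureContext(
        [[0, 0, 0], [d, 0, 0]], radii, list(elements), ["CA", "CA"],
        ["A", "B"], [1, 1], ["G", "G"],
    )


def _bare_rotamer(atom_xyz, name="CG", chain="A", resnum=1):
    return PlacedRotamer(chain=chain, resnum=resnum, res_type="V", chi=(0.0,),
                         probability=1.0, atoms={name: np.asarray(atom_xyz, float)})


class TestRotamerLibrary:
    def test_default_library_invariants(self, rotamer_lib):
        for res, rots in rotamer_lib.entries.items():
            probs = [p for _, p in rots]
            assert all(0 < p <= 1 for p in probs)
            assert sum(probs) <= 1 + 1e-6
            assert probs == sorted(probs, reverse=True)
        # glycine/alanine have one trivial chi-free entry
        for res in ("G", "A"):
            assert rotamer_lib.rotamers(res) == (((), 1.0),)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            RotamerLibrary(entries={"S": (((60.0,), 1.5),)})

    def test_probability_sum_capped(self):
        with pytest.raises(ValueError, match="sum"):
            RotamerLibrary(entries={"S": (((60.0,), 0.7), ((180.0,), 0.7))})

    def test_wrong_chi_count_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            RotamerLibrary(entries={"M": (((60.0,), 0.5),)})


class TestPlaceRotamers:
    def test_glycine_mutant_single_empty_rotamer(self, helix_ctx, rotamer_lib):
        rots = place_rotamers(helix_ctx, Variant(10, "A", "G"), rotamer_lib)
        assert len(rots) == 1
        assert rots[0].probability == 1.0
        assert rots[0].atoms == {}

    @pytest.mark.parametrize("mut", list("SVMLKRFWH"))
    def test_min_prob_zero_returns_full_library(self, helix_ctx, rotamer_lib, mut):
        rots = place_rotamers(helix_ctx, Variant(10, "A", mut), rotamer_lib,
                              min_prob=0.0)
        assert len(rots) == len(rotamer_lib.rotamers(mut))
        probs = [r.probability for r in rots]
        assert probs == sorted(probs, reverse=True)

    def test_min_prob_filters(self, helix_ctx, rotamer_lib):
        all_m = place_rotamers(helix_ctx, Variant(10, "A", "M"), rotamer_lib, 0.0)
        kept = place_rotamers(helix_ctx, Variant(10, "A", "M"), rotamer_lib, 0.10)
        assert [r.chi for r in kept] == [r.chi for r in all_m if r.probability >= 0.10]

    def test_unresolved_position_rejected(self, helix_ctx, rotamer_lib):
        with pytest.raises(Exception, match="A-C"):
            place_rotamers(helix_ctx, Variant(99, "A", "M"), rotamer_lib)

    def test_determinism(self, helix_ctx, rotamer_lib):
        a = place_rotamers(helix_ctx, Variant(10, "A", "W"), rotamer_lib)
        b = place_rotamers(helix_ctx, Variant(10, "A", "W"), rotamer_lib)
        for ra, rb in zip(a, b):
            assert ra.chi == rb.chi and ra.probability == rb.probability
            for name in ra.atoms:
                np.testing.assert_array_equal(ra.atoms[name], rb.atoms[name])

    def test_missing_cb_reconstructed_with_warning(self, tmp_path, rotamer_lib):
        from spscore.fixtures import FixtureSpec, make_structure
        from spscore import load_structure

        p = make_structure(FixtureSpec(n_residues=5, geometry="helix",
                                       sequence="AAGAA"), tmp_path / "g.pdb")
        ctx = load_structure(p, fmt="pdb")
        with pytest.warns(UserWarning, match="no CB"):
            rots = place_rotamers(ctx, Variant(3, "G", "S"), rotamer_lib)
        assert all("CB" in r.atoms for r in rots)


class TestDetectClashes:
    def test_overlap_arithmetic_carbon_pair(self):
        # two C atoms r=1.70: d=2.0 -> overlap 1.40 >= 0.60 -> clash
        ctx = _two_atom_ctx(2.0)
        rot = _bare_rotamer(ctx.coords[0])
        clashes = detect_clashes(ctx, rot)
        assert len(clashes) == 1
        assert clashes[0].overlap == pytest.approx(1.40)

    def test_no_clash_at_touching_distance(self):
        ctx = _two_atom_ctx(3.40)
        assert detect_clashes(ctx, _bare_rotamer(ctx.coords[0])) == []

    def test_hbond_allowance_spares_polar_pair(self):
        # N vs O: raw overlap 0.80, allowance 0.40 -> effective 0.40 < 0.60
        d = 1.55 + 1.52 - 0.80
        ctx = _two_atom_ctx(d, elements=("N", "O"))
        rot = _bare_rotamer(ctx.coords[0], name="ND1")
        assert detect_clashes(ctx, rot) == []
        # the same overlap between two carbons is a clash
        ctx2 = _two_atom_ctx(1.70 + 1.70 - 0.80)
        assert len(detect_clashes(ctx2, _bare_rotamer(ctx2.coords[0]))) == 1

    def test_own_residue_excluded(self, helix_ctx, rotamer_lib):
        rots = place_rotamers(helix_ctx, Variant(1, "A", "S"), rotamer_lib)
        for rot in rots:
            for clash in detect_clashes(helix_ctx, rot):
                assert clash.atom_b[:2] != ("A", 1)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        elems = [str(e) for e in rng.choice(["C", "N", "O", "S"], size=n)]
        radii = [{"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}[e] for e in elems]
        coords = rng.uniform(0, 12, size=(n, 3))
        ctx = StructureContext(coords, radii, elems, ["X"] * n, ["A"] * n,
                               list(range(2, n + 2)), ["G"] * n)
        rot_atoms = {"CB": rng.uniform(0, 12, size=3),
                     "OG": rng.uniform(0, 12, size=3)}
        rot = PlacedRotamer(chain="A", resnum=1, res_type="S", chi=(0.0,),
                            probability=1.0, atoms=rot_atoms)
        # own residue (A,1) is not in ctx, so everything is environment
        got = {(c.atom_a[2], c.atom_b[1]): c.overlap
               for c in detect_clashes(ctx, rot)}
        names = list(rot_atoms)
        ov = brute_force_overlaps(
            [rot_atoms[nm] for nm in names],
            [1.70 if nm == "CB" else 1.52 for nm in names],
            ["C" if nm == "CB" else "O" for nm in names],
            coords, radii, elems, hbond_allowance=0.4)
        expected = {(names[i], int(ctx.resnums[j])): ov[i, j]
                    for i, j in zip(*np.nonzero(ov >= 0.6))}
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])


class TestRelief:
    def test_engineered_neighbor_turn_relieves(self, relief_ctx, rotamer_lib):
        rots = place_rotamers(relief_ctx, Variant(1, "A", "V"), rotamer_lib)
        top = rots[0]
        assert detect_clashes(relief_ctx, top)
        out = relieve_clashes(relief_ctx, top)
        assert out.relieved is True
        assert out.clashes_before and not out.clashes_after

    def test_enclosed_cavity_cannot_be_relieved(self, cavity_ctx, rotamer_lib):
        rots = place_rotamers(cavity_ctx, Variant(5, "A", "W"), rotamer_lib)
        for rot in rots:
            assert detect_clashes(cavity_ctx, rot)
            out = relieve_clashes(cavity_ctx, rot)
            assert out.relieved is False
            assert out.clashes_after

    def test_clash_free_rotamer_passes_through(self, helix_ctx, rotamer_lib):
        rots = place_rotamers(helix_ctx, Variant(1, "A", "S"), rotamer_lib)
        clean = [r for r in rots if not detect_clashes(helix_ctx, r)]
        assert clean
        out = relieve_clashes(helix_ctx, clean[0])
        assert out.relieved is True
        assert out.chi == clean[0].chi  # untouched


class TestScoreD:
    def test_exposed_site_scores_zero(self, helix_ctx, rotamer_lib):
        assert score_D(helix_ctx, Variant(1, "A", "S"), rotamer_lib) == 0.0

    def test_cavity_scores_one(self, cavity_ctx, rotamer_lib):
        d = score_D(cavity_ctx, Variant(5, "A", "W"), rotamer_lib)
        assert d == pytest.approx(1.0)

    def test_range_and_determinism(self, helix_ctx, rotamer_lib):
        for mut in "MVFWR":
            d1 = score_D(helix_ctx, Variant(10, "A", mut), rotamer_lib)
            d2 = score_D(helix_ctx, Variant(10, "A", mut), rotamer_lib)
            assert 0.0 <= d1 <= 1.0
            assert d1 == d2

    def test_weaker_relief_never_decreases_score(self, helix_ctx, cavity_ctx,
                                                 relief_ctx, rotamer_lib):
        no_relief = ReliefConfig(max_iterations=0)
        cases = [
            (helix_ctx, Variant(10, "A", "V")),
            (helix_ctx, Variant(10, "A", "W")),
            (cavity_ctx, Variant(5, "A", "W")),
            (relief_ctx, Variant(1, "A", "V")),
        ]
        for ctx, v in cases:
            strong = score_D(ctx, v, rotamer_lib)
            weak = score_D(ctx, v, rotamer_lib, relief=no_relief)
            assert weak >= strong - 1e-12

    def test_relieved_weight_is_configurable(self, relief_ctx, rotamer_lib):
        d_half = score_D(relief_ctx, Variant(1, "A", "V"), rotamer_lib,
                         w_relieved=0.5)
        d_zero = score_D(relief_ctx, Variant(1, "A", "V"), rotamer_lib,
                         w_relieved=0.0)
        assert d_zero <= d_half
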