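"""Stand-in energy bookkeeping, mutation modelling, and scans."""

import numpy as np
import pytest

from abtriage.fixtures import (FixtureSpec, PlantedInteraction,
                               default_fixture_spec, make_toy_complex)
from abtriage.interface import count_cross_clashes, detect_interactions
from abtriage.scoring import (AMINO_ACIDS, EnergyParams, Mutation, alanine_scan,
                              apply_mutation, binding_energy, ddE,
                              saturation_scan, species_switch)
from abtriage.structures import Atom, Complex, Residue, RigidTransform, transform_apply


class TestMutationNotation:
    @pytest.mark.parametrize("text", ["H:S28R", "L:K36A", "A:R25Q", "H:T110W"])
    def test_parse_format_round_trip(self, text):
        assert str(Mutation.parse(text)) == text

    @pytest.mark.parametrize("text", ["X:S28R", "H:S28", "HS28R", "H:s28r"])
    def test_bad_notation_rejected(self, text):
        with pytest.raises(ValueError):
            Mutation.parse(text)


class TestBindingEnergy:
    def test_separated_chains_score_zero(self, toy, params):
        cx, _ = toy
        apart = transform_apply(cx, ["A"],
                                RigidTransform(np.eye(3), np.array([0.0, 100.0, 0.0])))
        assert binding_energy(apart, params) == 0.0

    def test_single_salt_bridge_is_minus_two(self, params):
        spec = FixtureSpec(planted=[PlantedInteraction("salt_bridge", "H", 3, 3, 3.0)])
        cx, _ = make_toy_complex(spec)
        assert binding_energy(cx, params) == pytest.approx(-2.0, abs=1e-9)

    def test_equals_recomputation_from_interaction_table(self, toy, params):
        """Bookkeeping oracle: energy == sum of weights + clash census."""
        cx, _ = toy
        expected = sum(params.weights[r.kind] for r in detect_interactions(cx))
        expected += params.clash_penalty * count_cross_clashes(cx, params.clash_distance)
        assert binding_energy(cx, params) == pytest.approx(expected, abs=1e-12)

    def test_removing_each_planted_interaction_changes_energy_by_its_weight(
            self, params):
        base = default_fixture_spec(0)
        e_full = binding_energy(make_toy_complex(base)[0], params)
        for drop in base.planted:
            spec = FixtureSpec(planted=[p for p in base.planted if p is not drop],
                               control_positions=base.control_positions)
            e_less = binding_energy(make_toy_complex(spec)[0], params)
            assert e_full - e_less == pytest.approx(params.weights[drop.kind],
                                                    abs=1e-9)


class TestApplyMutation:
    def test_self_mutation_is_identity(self, toy):
        cx, _ = toy
        out = apply_mutation(cx, Mutation.parse("H:R3R"))
        np.testing.assert_allclose(out.heavy_atom_table()[0],
                                   cx.heavy_atom_table()[0])

    def test_alanine_removes_planted_salt_bridge(self, toy):
        cx, _ = toy
        mut = apply_mutation(cx, Mutation.parse("A:D3A"))
        kinds = {r.kind for r in detect_interactions(mut)
                 if r.target_residue == ("A", 3, "")}
        assert "salt_bridge" not in kinds

    def test_wild_type_mismatch_rejected(self, toy):
        with pytest.raises(ValueError, match="mismatch"):
            apply_mutation(toy[0], Mutation.parse("H:Y3A"))

    def test_unknown_position_rejected(self, toy):
        with pytest.raises(KeyError):
            apply_mutation(toy[0], Mutation.parse("H:S99A"))

    def test_ser_to_arg_gains_pi_cation_through_pseudo_centroid(self):
        """Pseudo side-chain centroid pointed at an aromatic ring."""
        ser = Residue("H", 1, "SER", [
            Atom("N", "N", [-1.2, -0.5, 0.0]), Atom("CA", "C", [0.0, 0.0, 0.0]),
            Atom("C", "C", [1.2, -0.5, 0.0]), Atom("O", "O", [1.2, -1.7, 0.0]),
            Atom("CB", "C", [0.0, 1.53, 0.0]), Atom("OG", "O", [0.0, 2.5, 0.0]),
        ])
        ring = [Atom(n, "C", [1.39 * np.cos(a), 8.0, 1.39 * np.sin(a)])
                for n, a in zip(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
                                np.radians(np.arange(0, 360, 60)))]
        tyr = Residue("A", 1, "TYR", [
            Atom("N", "N", [-1.2, 8.5, 0.0]), Atom("CA", "C", [0.0, 9.0, 0.0]),
            Atom("CB", "C", [0.0, 7.5, 3.0]), *ring])
        cx = Complex({"H": [ser], "A": [tyr]}, {"H": "heavy", "A": "antigen"})
        assert not [r for r in detect_interactions(cx) if r.kind == "pi_cation"]
        result = ddE(cx, Mutation.parse("H:S1R"))
        mut = apply_mutation(cx, Mutation.parse("H:S1R"))
        assert [r.kind for r in detect_interactions(mut)
                if r.kind == "pi_cation"]
        assert result.ddE_binding < 0


class TestDdE:
    def test_alanine_at_salt_bridge_costs_plus_two(self, toy, params):
        cx, _ = toy
        r = ddE(cx, Mutation.parse("H:R3A"), params=params)
        assert r.ddE_binding == pytest.approx(2.0, abs=1e-9)

    def test_non_interface_position_is_exactly_zero(self, params):
        # antigen of length 5 leaves the far binder positions >8 A away
        spec = FixtureSpec(antigen_length=5,
                           planted=[PlantedInteraction("salt_bridge", "H", 3, 3, 3.0)])
        cx, _ = make_toy_complex(spec)
        for mode in ("rigid", "tolerant"):
            r = ddE(cx, Mutation.parse("H:A12R"), mode=mode, params=params)
            assert r.ddE_binding == 0.0 and r.ddE_stability == 0.0

    def test_rigid_stability_penalises_crowded_pocket_tolerant_forgives(self):
        """Large mutation clashing only with neighbour side chains."""
        def res(chain, pos, aa3, x, extra=()):
            atoms = [Atom("N", "N", [x - 1.2, -0.5, 0.0]),
                     Atom("CA", "C", [x, 0.0, 0.0]),
                     Atom("C", "C", [x + 1.2, -0.5, 0.0]),
                     Atom("O", "O", [x + 1.2, -1.7, 0.0]),
                     Atom("CB", "C", [x, 1.53, 0.0])]
            atoms += list(extra)
            return Residue(chain, pos, aa3, atoms)

        # a bulky neighbour side-chain atom sits right where the pseudo
        # centroid of a Trp mutation at position 2 will land
        blocker = Atom("CD1", "C", [3.8, 1.53 + 2.6, 0.5])
        chain = [res("H", 1, "ALA", 0.0),
                 res("H", 2, "ALA", 3.8),
                 res("H", 4, "LEU", 7.6, extra=[blocker])]  # non-adjacent
        antigen = [res("A", 1, "ALA", 50.0)]
        cx = Complex({"H": chain, "A": antigen}, {"H": "heavy", "A": "antigen"})
        rigid = ddE(cx, Mutation.parse("H:A2W"), mode="rigid")
        tolerant = ddE(cx, Mutation.parse("H:A2W"), mode="tolerant")
        assert rigid.ddE_stability > 0
        assert tolerant.ddE_stability == 0.0


class TestAlanineScan:
    def test_hotspots_all_strictly_positive(self, toy, params):
        cx, truth = toy
        positions = [(c, str(p)) for c, p in sorted(truth.hotspot_positions)]
        results = alanine_scan(cx, positions, params)
        assert len(results) == 3
        assert all(r.ddE_binding > 0 for r in results)

    def test_non_interface_scan_all_zero(self, toy, params):
        cx, _ = toy
        results = alanine_scan(cx, [("H", "11"), ("L", "9")], params)
        assert all(r.ddE_binding == 0.0 and r.ddE_stability == 0.0
                   for r in results)

    def test_scan_equals_individual_ddE_calls(self, toy, params):
        cx, truth = toy
        positions = [(c, str(p)) for c, p, _wt in truth.panel]
        results = alanine_scan(cx, positions, params)
        for r in results:
            if r.mutation.wt_aa in ("A", "G"):
                continue
            single = ddE(cx, r.mutation, params=params)
            assert r.ddE_binding == pytest.approx(single.ddE_binding, abs=1e-12)

    def test_antigen_positions_rejected(self, toy):
        with pytest.raises(ValueError):
            alanine_scan(toy[0], [("A", "3")])


class TestSpeciesSwitch:
    def test_empty_substitution_list_is_zero(self, toy):
        assert species_switch(toy[0], []) == 0.0

    def test_removing_planted_interactions_sums_weights(self, toy, params):
        cx, _ = toy
        # knock out the salt bridge (-2.0) and the H-bond (-1.0) partners
        subs = [Mutation.parse("A:D3A"), Mutation.parse("A:N16A")]
        assert species_switch(cx, subs, params) == pytest.approx(3.0, abs=1e-9)

    def test_simultaneous_equals_sum_of_singles_for_independent_sites(
            self, toy, params):
        cx, _ = toy
        subs = [Mutation.parse("A:D3A"), Mutation.parse("A:N16A")]
        total = species_switch(cx, subs, params)
        singles = sum(species_switch(cx, [m], params) for m in subs)
        assert total == pytest.approx(singles, abs=1e-9)

    def test_non_antigen_mutation_rejected(self, toy):
        with pytest.raises(ValueError):
            species_switch(toy[0], [Mutation.parse("H:R3A")])


class TestSaturationScan:
    def test_row_count_and_self_mutations(self, toy):
        cx, _ = toy
        table = saturation_scan(cx, [("H", "3"), ("L", "6")])
        assert len(table) == 2 * 20 * 2
        selfs = table[table["mutation"].isin(["H:R3R", "L:L6L"])]
        assert len(selfs) == 4
        assert (selfs["ddE_binding_AU"] == 0).all()
        assert (selfs["ddE_stability_AU"] == 0).all()

    def test_rigid_stability_dominates_tolerant(self, toy):
        cx, _ = toy
        table = saturation_scan(cx, [("H", "3")])
        wide = table.pivot_table(index="mutation", columns="mode",
                                 values="ddE_stability_AU")
        assert (wide["rigid"] >= wide["tolerant"] - 1e-12).all()

    def test_deleting_favourable_positive_adding_negative(self, toy, params):
        """Sign convention: losses cost, clash-free gains stabilise."""
        cx, _ = toy
        loss = ddE(cx, Mutation.parse("H:R3A"), params=params)
        assert loss.ddE_binding > 0
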