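"""Phenotype-consistency filtering, knockout ranking and panel design."""

import numpy as np
import pandas as pd
import pytest

from abtriage.datasets import redock_panel_ddE, redock_panel_phenotypes
from abtriage.fixtures import default_fixture_spec, make_toy_complex
from abtriage.interface import InterfaceProfile, interaction_profile, detect_interactions
from abtriage.scoring import Mutation, apply_mutation
from abtriage.triage import (PhenotypeTable, TriageCriteria, consistency_filter,
                             design_validation_panel, interaction_loss_score,
                             rank_partial_knockout)


def _brute_force_filter(matrix, phenotypes, criteria):
    passing, violations = [], {}
    for pose in matrix.index:
        viol = []
        for mut, label in phenotypes.entries.items():
            v = float(matrix.loc[pose, mut])
            if label in ("non_binding", "reduced") and v < criteria.deleterious_min:
                viol.append((mut, "deleterious>=min"))
            if label == "retained" and v > criteria.neutral_max:
                viol.append((mut, "retained<=max"))
        violations[pose] = viol
        if not viol:
            passing.append(pose)
    return passing, violations


class TestConsistencyFilter:
    def test_published_panel_rejects_all_five_poses(self):
        """Worked example: the 10-mutation redock panel fails every pose."""
        matrix = redock_panel_ddE()
        phenotypes = redock_panel_phenotypes()
        passing, violations = consistency_filter(matrix, phenotypes)
        assert passing == []
        v1904 = {(v.mutation, round(v.value, 2)) for v in violations[1904]}
        assert ("L:K36A", -0.17) in v1904
        assert ("L:Y31A", 3.55) in v1904
        # hand-derived full violation sets per pose
        expect = _brute_force_filter(matrix, phenotypes, TriageCriteria())[1]
        for pose in matrix.index:
            assert {(v.mutation, v.rule) for v in violations[pose]} \
                == set(expect[pose])
            assert len(violations[pose]) > 0

    def test_clean_profile_passes_with_no_violations(self):
        phen = PhenotypeTable({"H:Y1A": "non_binding", "L:S2A": "retained"})
        matrix = pd.DataFrame({"H:Y1A": [1.0], "L:S2A": [0.0]}, index=["p"])
        passing, violations = consistency_filter(matrix, phen)
        assert passing == ["p"] and violations["p"] == []

    def test_matches_enumeration_on_random_matrices(self, rng):
        muts = [f"H:Y{i}A" for i in range(1, 7)] + [f"L:S{i}A" for i in range(1, 5)]
        labels = ["non_binding"] * 5 + ["reduced"] + ["retained"] * 4
        phen = PhenotypeTable(dict(zip(muts, labels)))
        for _ in range(20):
            matrix = pd.DataFrame(rng.normal(scale=1.5, size=(50, 10)),
                                  columns=muts)
            passing, violations = consistency_filter(matrix, phen)
            bf_pass, bf_viol = _brute_force_filter(matrix, phen, TriageCriteria())
            assert passing == bf_pass
            for pose in matrix.index:
                assert {(v.mutation, v.rule) for v in violations[pose]} \
                    == set(bf_viol[pose])

    def test_threshold_monotonicity(self, rng):
        muts = ["H:Y1A", "H:Y2A", "L:S3A"]
        phen = PhenotypeTable({"H:Y1A": "non_binding", "H:Y2A": "reduced",
                               "L:S3A": "retained"})
        matrix = pd.DataFrame(rng.normal(size=(30, 3)), columns=muts)
        previous = None
        for dmin in (-1.0, 0.0, 0.5, 1.0):
            passing, _ = consistency_filter(matrix, phen,
                                            TriageCriteria(deleterious_min=dmin))
            if previous is not None:
                assert set(passing) <= set(previous)
            previous = passing

    def test_missing_entry_names_pose_and_mutation(self):
        phen = PhenotypeTable({"H:Y1A": "non_binding"})
        matrix = pd.DataFrame({"H:Y9A": [1.0]}, index=["pose7"])
        with pytest.raises(KeyError, match="pose7.*H:Y1A"):
            consistency_filter(matrix, phen)

    def test_all_retained_phenotypes_rejected(self):
        phen = PhenotypeTable({"H:Y1A": "retained"})
        matrix = pd.DataFrame({"H:Y1A": [0.0]})
        with pytest.raises(ValueError, match="non-retained"):
            consistency_filter(matrix, phen)


class TestRankPartialKnockout:
    def test_lower_reduced_ddE_ranks_first(self):
        matrix = pd.DataFrame({"L:K1A": [0.2, 1.5], "H:Y2A": [2.0, 2.2],
                               "H:Y3A": [2.5, 2.0]}, index=["a", "b"])
        order = rank_partial_knockout(["a", "b"], matrix, {"L:K1A"},
                                      {"H:Y2A", "H:Y3A"})
        assert order == ["a", "b"]

    def test_reduced_above_all_knockouts_ranks_last(self):
        matrix = pd.DataFrame({"L:K1A": [5.0, 0.5], "H:Y2A": [2.0, 2.0]},
                              index=["high", "low"])
        order = rank_partial_knockout(["high", "low"], matrix, {"L:K1A"},
                                      {"H:Y2A"})
        assert order == ["low", "high"]

    def test_empty_reduced_set_keeps_input_order(self):
        matrix = pd.DataFrame({"H:Y2A": [1.0, 2.0]}, index=["x", "y"])
        assert rank_partial_knockout(["y", "x"], matrix, set(), {"H:Y2A"}) \
            == ["y", "x"]

    def test_matches_naive_margin_sort(self, rng):
        muts = ["L:K1A", "L:K2A", "H:Y3A", "H:Y4A"]
        reduced, knockouts = {"L:K1A", "L:K2A"}, {"H:Y3A", "H:Y4A"}
        matrix = pd.DataFrame(rng.normal(size=(25, 4)), columns=muts)
        poses = list(matrix.index)
        got = rank_partial_knockout(poses, matrix, reduced, knockouts)

        def naive_key(p):
            ko = min(matrix.loc[p, m] for m in knockouts)
            red = [matrix.loc[p, m] for m in reduced]
            return (0 if max(red) < ko else 1,
                    float(np.mean([r - ko for r in red])), p)

        assert got == sorted(poses, key=naive_key)


class TestInteractionLossScore:
    def test_every_hotspot_explains_one_interaction(self, toy):
        cx, truth = toy
        positions = sorted(truth.hotspot_positions)
        explained, total = interaction_loss_score(cx, positions)
        assert (explained, total) == (len(positions), len(positions))

    def test_off_interface_positions_explain_nothing(self, toy):
        cx, _ = toy
        assert interaction_loss_score(cx, [("H", 11), ("L", 9)]) == (0, 0)

    def test_matches_set_difference_recomputation(self, toy):
        cx, truth = toy
        positions = sorted(truth.hotspot_positions | truth.weak_positions)
        explained, total = interaction_loss_score(cx, positions)
        exp2 = tot2 = 0
        for chain, pos in positions:
            res = cx.get_residue(chain, pos)
            before = {(r.kind, r.binder_residue, r.target_residue)
                      for r in detect_interactions(cx)
                      if r.binder_residue == res.key}
            tot2 += len(before)
            mut = apply_mutation(cx, Mutation(chain, str(pos), res.aa1, "A"))
            after = {(r.kind, r.binder_residue, r.target_residue)
                     for r in detect_interactions(mut)
                     if r.binder_residue == res.key}
            exp2 += len(before - after)
        assert (explained, total) == (exp2, tot2)


def _panel_annotations(labels, wt="Y", cdr=True):
    return {l: {"wt_aa": wt, "annotation": {"CDRH1" if cdr else "FR"}}
            for l in labels}


class TestDesignValidationPanel:
    @pytest.mark.filterwarnings("ignore:no qualifying control")
    def test_unique_interaction_position_emitted(self):
        labels = ["H:1", "H:2", "H:3"]
        matrix = pd.DataFrame(np.zeros((3, 3)), columns=labels)
        profiles = [InterfaceProfile(0, {("H:1", "salt_bridge"): 1}),
                    InterfaceProfile(1, {}), InterfaceProfile(2, {})]
        panel = design_validation_panel(matrix, profiles,
                                        _panel_annotations(labels))
        uniques = {str(v.mutations[0]) for v in panel.by_category("unique")}
        assert uniques == {"H:Y1A"}

    def test_flat_position_is_control_not_single(self):
        labels = ["H:1", "H:2", "L:3"]
        matrix = pd.DataFrame(
            {"H:1": [2.0, 0.1, 0.1], "H:2": [0.01, -0.02, 0.0],
             "L:3": [0.0, 0.01, -0.01]})
        profiles = [InterfaceProfile(i, {}) for i in range(3)]
        panel = design_validation_panel(matrix, profiles,
                                        _panel_annotations(labels))
        singles = {str(v.mutations[0]) for v in panel.by_category("single")}
        controls = {str(v.mutations[0]) for v in panel.by_category("control")}
        assert "H:Y1A" in singles
        assert "H:Y2A" in controls and "L:Y3A" in controls

    @pytest.mark.filterwarnings("ignore:no qualifying control")
    def test_matches_independent_rule_enumeration(self, rng):
        """Full panel reproduced by a direct re-statement of the rules."""
        n_poses, labels = 5, [f"H:{i}" for i in range(1, 7)] \
            + [f"L:{i}" for i in range(1, 7)]
        matrix = pd.DataFrame(rng.normal(scale=0.8, size=(n_poses, 12)),
                              columns=labels)
        profiles = []
        for i in range(n_poses):
            counts = {}
            for l in labels:
                if rng.random() < 0.25:
                    counts[(l, "hbond")] = 1
            profiles.append(InterfaceProfile(i, counts))
        ann = _panel_annotations(labels)
        delta, min_disc, eps = 0.5, 2, 0.05
        panel = design_validation_panel(matrix, profiles, ann,
                                        discrimination_delta=delta,
                                        min_discordant_poses=min_disc,
                                        control_epsilon=eps)
        # independent enumeration of the three rules
        unique = [l for l in labels
                  if sum(1 for p in profiles if p.count_at(l) > 0) == 1]
        singles = []
        for l in labels:
            if l in unique:
                continue
            vals = matrix[l].to_numpy()
            if any(np.sum(np.abs(np.delete(vals, i) - vals[i]) >= delta)
                   >= min_disc for i in range(n_poses)):
                singles.append(l)
        controls = []
        for chain in "HL":
            cands = [(float(np.max(np.abs(matrix[l]))), l) for l in labels
                     if l.startswith(chain) and l not in unique and l not in singles
                     and float(np.max(np.abs(matrix[l]))) <= eps]
            if cands:
                controls.append(min(cands)[1])
        got_unique = {f"{m.chain}:{m.pos}" for v in panel.by_category("unique")
                      for m in v.mutations}
        got_singles = {f"{m.chain}:{m.pos}" for v in panel.by_category("single")
                       for m in v.mutations}
        got_controls = {f"{m.chain}:{m.pos}" for v in panel.by_category("control")
                        for m in v.mutations}
        assert got_unique == set(unique)
        assert got_singles == set(singles)
        assert got_controls == set(controls)
        # triples are 3-combinations of singles, disjoint as variants
        for v in panel.by_category("triple"):
            assert len(v.mutations) == 3
            assert {f"{m.chain}:{m.pos}" for m in v.mutations} <= set(singles)

    def test_controls_satisfy_epsilon_in_every_pose(self, rng):
        labels = [f"H:{i}" for i in range(1, 5)] + [f"L:{i}" for i in range(1, 5)]
        matrix = pd.DataFrame(rng.normal(scale=0.3, size=(4, 8)), columns=labels)
        matrix["H:4"] = 0.0
        matrix["L:4"] = 0.01
        profiles = [InterfaceProfile(i, {}) for i in range(4)]
        panel = design_validation_panel(matrix, profiles,
                                        _panel_annotations(labels))
        for v in panel.by_category("control"):
            label = f"{v.mutations[0].chain}:{v.mutations[0].pos}"
            assert float(np.max(np.abs(matrix[label]))) <= 0.05

    def test_warns_when_no_control_qualifies(self):
        labels = ["H:1", "L:1"]
        matrix = pd.DataFrame({"H:1": [3.0, 0.1], "L:1": [2.0, 0.2]})
        profiles = [InterfaceProfile(i, {}) for i in range(2)]
        with pytest.warns(UserWarning, match="control"):
            panel = design_validation_panel(matrix, profiles,
                                            _panel_annotations(labels))
        assert panel.by_category("control") == []

    def test_categories_disjoint(self, toy_parts):
        cx, truth, binder, target = toy_parts
        from abtriage.workflow import build_ddE_matrix
        from abtriage.fixtures import make_decoy_set
        poses = make_decoy_set(truth, binder, target, 4, seed=9)
        positions = [f"{c}:{p}" for c, p, _wt in truth.panel]
        matrix = build_ddE_matrix(binder, target, poses, positions)
        matrix.columns = [f"{m[0]}:{m[2:-1].lstrip('ACDEFGHIKLMNPQRSTVWY')}"
                          for m in matrix.columns]
        from abtriage.posegen import realise_pose
        profiles = [interaction_profile(realise_pose(binder, target, p.transform),
                                        p.pose_id) for p in poses]
        ann = {}
        for res in cx.residues(cx.binder_chains):
            letter = "H" if cx.roles[res.chain_id] == "heavy" else "L"
            ann[f"{letter}:{res.author_pos}"] = {"wt_aa": res.aa1,
                                                 "annotation": set(res.annotations)}
        panel = design_validation_panel(matrix, profiles, ann)
        seen = {}
        for v in panel.variants:
            if v.category == "triple":
                continue
            label = str(v.mutations[0])
            assert label not in seen, f"{label} in {seen.get(label)} and {v.category}"
            seen[label] = v.category
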