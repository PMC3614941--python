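import numpy as np
import pandas as pd
import pytest

import mpcluster as mpc
from mpcluster.selection import (
    CandidateSet,
    SelectionRules,
    choose_versions,
    full_partition,
    hierarchy,
    select_candidates,
    summarize,
)
from mpcluster.persistence import build_grid, compute_grid, persistence_regions

from conftest import random_model


@pytest.fixture(scope="module")
def analyzed():
    rng = np.random.default_rng(42)
    model = random_model(rng, 14)
    D = mpc.commute_time_matrix(model)
    grid = build_grid(model, D, m=7, q=7)
    gc = compute_grid(model, D, grid)
    regions = persistence_regions(gc)
    return model, D, gc, regions


class TestSummarize:
    def test_one_row_per_region(self, analyzed):
        model, D, gc, regions = analyzed
        summary = summarize(regions, gc)
        assert len(summary) == len(regions)
        assert set(summary.columns) >= {
            "label",
            "scale_persistence",
            "density_persistence",
            "max_size",
            "birth_level",
        }

    def test_full_grid_label_maximal(self, analyzed):
        model, D, gc, regions = analyzed
        summary = summarize(regions, gc).set_index("label")
        argmin = int(np.argmin(model.E))
        row = summary.loc[argmin]
        assert row["scale_persistence"] == gc.grid.q
        assert row["density_persistence"] == gc.grid.m - row["birth_level"]
        assert row["max_size"] == model.populations.sum()


class TestSelectCandidates:
    def summary(self):
        return pd.DataFrame(
            {
                "label": [0, 1, 2, 3],
                "scale_persistence": [10, 10, 1, 10],
                "density_persistence": [10, 9, 10, 10],
                "max_size": [1000, 40, 1000, 900],
                "birth_level": [0, 6, 0, 1],
            }
        )

    def test_three_principles(self):
        rules = SelectionRules(5, 5, 100, min_rare_size=10, min_rare_scale_persistence=8)
        cands = select_candidates(self.summary(), rules)
        assert cands.selected == [0, 3]  # big, persistent in both
        assert cands.rare_state_candidates == [1]  # late-born, small, far from all
        # label 2 fails scale persistence outright

    def test_low_scale_persistence_never_selected(self):
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(self.summary(), rules)
        assert 2 not in cands.selected + cands.rare_state_candidates

    def test_fallback_to_deepest(self):
        rules = SelectionRules(99, 99, 99)
        with pytest.warns(UserWarning, match="no label passed"):
            cands = select_candidates(self.summary(), rules)
        assert cands.selected == [0]  # birth level 0 = deepest

    def test_global_label_selected_on_random_instance(self, analyzed):
        model, D, gc, regions = analyzed
        summary = summarize(regions, gc)
        rules = SelectionRules.defaults(gc.grid.m, gc.grid.q, int(model.populations.sum()))
        cands = select_candidates(summary, rules)
        assert int(np.argmin(model.E)) in cands.selected


class TestChooseVersions:
    def test_versions_disjoint_and_maximal(self, analyzed):
        model, D, gc, regions = analyzed
        summary = summarize(regions, gc)
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(summary, rules)
        by_label = {r.label: r for r in regions}
        cands = choose_versions(cands, by_label, gc)
        seen = np.zeros(model.n_states, dtype=bool)
        for lab, (j, l, members) in cands.versions.items():
            assert lab in members
            assert not seen[members].any()
            seen[members] = True
            # the chosen version is an actual component of the chosen cell
            np.testing.assert_array_equal(
                np.sort(members), gc.component_members(j, l, lab)
            )

    def test_processing_order_descends_in_free_energy(self, analyzed):
        model, D, gc, regions = analyzed
        order = sorted([3, 1, 0], key=lambda c: -model.E[c])
        assert model.E[order[0]] >= model.E[order[-1]]


class TestFullPartition:
    def setup_method(self):
        self.D = np.array(
            [
                [0.0, 9.0, 1.0, 4.0],
                [9.0, 0.0, 9.0, 4.0],
                [1.0, 9.0, 0.0, 9.0],
                [4.0, 4.0, 9.0, 0.0],
            ]
        )
        self.E = np.array([0.1, 0.2, 0.5, 0.6])
        self.cands = CandidateSet(
            selected=[0, 1],
            rare_state_candidates=[],
            versions={0: (0, 0, np.array([0])), 1: (0, 0, np.array([1]))},
        )

    def test_members_keep_label_and_rest_by_distance(self):
        part = full_partition(self.cands, self.D, self.E, mode="full")
        assert part.assignment[0] == 0 and part.assignment[1] == 1
        assert part.assignment[2] == 0  # d(2,0)=1 < d(2,1)=9
        assert part.assignment[3] == 0  # tie 4 vs 4 -> lower-E label 0

    def test_core_mode_leaves_unassigned(self):
        part = full_partition(self.cands, self.D, self.E, mode="core")
        assert part.assignment[2] == -1 and part.assignment[3] == -1

    def test_every_state_assigned_on_random_instance(self, analyzed):
        model, D, gc, regions = analyzed
        summary = summarize(regions, gc)
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(summary, rules)
        cands = choose_versions(cands, {r.label: r for r in regions}, gc)
        part = full_partition(cands, D.D, model.E, mode="full")
        assert np.all(part.assignment >= 0)
        assert set(np.unique(part.assignment)) <= set(cands.versions)


class TestHierarchy:
    def test_two_candidate_tree_shape(self, analyzed):
        model, D, gc, regions = analyzed
        by_label = {r.label: r for r in regions}
        summary = summarize(regions, gc)
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(summary, rules)
        cands = choose_versions(cands, by_label, gc)
        if len(cands.versions) < 2:
            pytest.skip("instance yielded a single candidate")
        tree = hierarchy(cands, gc, by_label)
        leaves = tree.leaves()
        assert {leaf.label for leaf in leaves} == set(cands.versions)
        for leaf in leaves:
            assert leaf.height == by_label[leaf.label].birth_level

    def test_heights_monotone_on_root_paths(self, analyzed):
        model, D, gc, regions = analyzed
        by_label = {r.label: r for r in regions}
        summary = summarize(regions, gc)
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(summary, rules)
        cands = choose_versions(cands, by_label, gc)
        if len(cands.versions) < 2:
            pytest.skip("instance yielded a single candidate")
        tree = hierarchy(cands, gc, by_label)

        def walk(node):
            for child in node.children:
                assert node.height >= child.height
                walk(child)

        walk(tree)

    def test_newick_parses_with_standard_reader(self, analyzed):
        import dendropy

        model, D, gc, regions = analyzed
        by_label = {r.label: r for r in regions}
        summary = summarize(regions, gc)
        rules = SelectionRules(2, 1, 1, min_rare_size=1, min_rare_scale_persistence=2)
        cands = select_candidates(summary, rules)
        cands = choose_versions(cands, by_label, gc)
        if len(cands.versions) < 2:
            pytest.skip("instance yielded a single candidate")
        tree = hierarchy(cands, gc, by_label)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == len(cands.versions)

    def test_single_candidate_raises(self, analyzed):
        model, D, gc, regions = analyzed
        cands = CandidateSet(selected=[0], rare_state_candidates=[], versions={0: (0, 0, np.array([0]))})
        with pytest.raises(ValueError):
            hierarchy(cands, gc, {r.label: r for r in regions})
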