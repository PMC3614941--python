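import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import mpcluster as mpc
from mpcluster.persistence import (
    ParameterGrid,
    PersistenceRegion,
    build_grid,
    compute_grid,
    max_persistences,
    neighborhood_clusters,
    persistence_regions,
    superlevel_set,
)

from conftest import random_distance_matrix, random_model


def small_grid(model, D, m=6, q=6):
    grid = build_grid(model, D, m=m, q=q)
    return compute_grid(model, D, grid)


class TestBuildGrid:
    def test_quantile_thetas_cover_E_range(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, 6)
        D = mpc.commute_time_matrix(model)
        grid = build_grid(model, D, m=3, q=4)
        np.testing.assert_allclose(grid.thetas[[0, -1]], [model.E.min(), model.E.max()])
        assert np.all(np.diff(grid.thetas) > 0)

    @pytest.mark.parametrize("strategy", ["log", "quantile", "linear"])
    def test_epsilons_within_bounds(self, strategy):
        rng = np.random.default_rng(1)
        model = random_model(rng, 8)
        D = mpc.commute_time_matrix(model)
        grid = build_grid(model, D, m=5, q=7, strategy=strategy)
        assert grid.epsilons[0] >= D.d_min - 1e-12
        assert grid.epsilons[-1] <= D.D_star + 1e-12
        assert np.all(np.diff(grid.epsilons) > 0)

    def test_too_small_grid_raises(self):
        rng = np.random.default_rng(2)
        model = random_model(rng, 4)
        D = mpc.commute_time_matrix(model)
        with pytest.raises(ValueError):
            build_grid(model, D, m=1, q=5)


class TestSuperlevelSet:
    @pytest.mark.parametrize(
        "theta,expected",
        [(2.0, [0, 1]), (0.5, []), (3.0, [0, 1, 2])],
    )
    def test_membership(self, theta, expected):
        E = np.array([1.0, 2.0, 3.0])
        if expected:
            np.testing.assert_array_equal(superlevel_set(E, theta), expected)
        else:
            with pytest.warns(UserWarning, match="empty level set"):
                assert superlevel_set(E, theta).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=25),
        st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=6),
    )
    def test_nesting(self, energies, thresholds):
        E = np.asarray(energies)
        sets = [set(superlevel_set(E, t).tolist()) for t in sorted(thresholds)]
        for a, b in zip(sets, sets[1:]):
            assert a <= b


class TestNeighborhoodClusters:
    def setup_method(self):
        self.D = np.array([[0.0, 1.0, 6.0], [1.0, 0.0, 5.0], [6.0, 5.0, 0.0]])
        self.E = np.array([0.3, 0.2, 0.1])

    def test_small_epsilon_splits(self):
        comps = neighborhood_clusters(np.arange(3), self.D, 2.0, self.E)
        assert {tuple(sorted(v)) for v in comps.values()} == {(0, 1), (2,)}
        # label = min-E member: state 1 labels {0,1}
        assert set(comps) == {1, 2}

    def test_chaining_at_larger_epsilon(self):
        comps = neighborhood_clusters(np.arange(3), self.D, 5.0, self.E)
        assert list(comps) == [2]
        np.testing.assert_array_equal(comps[2], [0, 1, 2])

    def test_label_tie_breaks_to_lowest_index(self):
        E = np.array([0.5, 0.5])
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        comps = neighborhood_clusters(np.arange(2), D, 2.0, E)
        assert list(comps) == [0]

    def test_matches_single_linkage_cut(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = rng.integers(3, 16)
            D = random_distance_matrix(rng, n)
            E = rng.uniform(size=n)
            eps = rng.uniform(0.01, D.max() * 1.1)
            comps = neighborhood_clusters(np.arange(n), D, eps, E)
            Z = linkage(squareform(D, checks=False), method="single")
            flat = fcluster(Z, t=eps, criterion="distance")
            ours = {tuple(sorted(v)) for v in comps.values()}
            theirs = {
                tuple(sorted(np.flatnonzero(flat == c))) for c in np.unique(flat)
            }
            assert ours == theirs


class TestComputeGrid:
    def test_components_coarsen_with_scale(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 12)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        for j in range(gc.grid.m):
            ncomp = [
                len(np.unique(gc.labels[j, l][gc.labels[j, l] >= 0]))
                for l in range(gc.grid.q)
            ]
            assert all(a >= b for a, b in zip(ncomp, ncomp[1:]))

    def test_partition_at_next_scale_coarsens(self):
        rng = np.random.default_rng(6)
        model = random_model(rng, 10)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        for j in range(gc.grid.m):
            for l in range(gc.grid.q - 1):
                fine, coarse = gc.labels[j, l], gc.labels[j, l + 1]
                members = np.flatnonzero(fine >= 0)
                # same fine component => same coarse component
                for lab in np.unique(fine[members]):
                    group = np.flatnonzero(fine == lab)
                    assert len(np.unique(coarse[group])) == 1

    def test_sizes_sum_to_level_set_population(self):
        rng = np.random.default_rng(7)
        model = random_model(rng, 9)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        for j in range(gc.grid.m):
            members = np.flatnonzero(model.E <= gc.grid.thetas[j])
            expected = int(model.populations[members].sum())
            for l in range(gc.grid.q):
                assert sum(gc.cell_sizes(j, l).values()) == expected

    def test_single_component_at_dstar_full_density(self):
        rng = np.random.default_rng(8)
        model = random_model(rng, 8)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        top = gc.labels[-1, -1]
        assert len(np.unique(top)) == 1  # epsilon_q = D_star joins everything


class TestPersistenceRegions:
    def test_global_minimum_label_covers_subgrid(self):
        rng = np.random.default_rng(9)
        model = random_model(rng, 10)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        regions = {r.label: r for r in persistence_regions(gc)}
        argmin = int(np.argmin(model.E))
        region = regions[argmin]
        expected = {
            (j, l)
            for j in range(region.birth_level, gc.grid.m)
            for l in range(gc.grid.q)
        }
        assert region.cells == expected

    def test_never_minimal_state_has_no_region(self):
        rng = np.random.default_rng(10)
        model = random_model(rng, 10)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        labels_with_regions = {r.label for r in persistence_regions(gc)}
        never_label = set(range(model.n_states)) - set(np.unique(gc.labels))
        assert labels_with_regions.isdisjoint(never_label)

    def test_regions_are_4_connected_on_random_models(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_model(rng, int(rng.integers(4, 15)))
            D = mpc.commute_time_matrix(model)
            gc = small_grid(model, D, m=5, q=5)
            persistence_regions(gc)  # raises AssertionError on a split region

    def test_merge_events_recorded(self):
        rng = np.random.default_rng(12)
        model = random_model(rng, 10)
        D = mpc.commute_time_matrix(model)
        gc = small_grid(model, D)
        regions = persistence_regions(gc)
        # at least one non-global label must eventually be merged by a deeper one
        merged = [
            e
            for r in regions
            for e in r.merge_events
            if e.kind == "merged_by"
        ]
        assert merged
        for r in regions:
            for e in r.merge_events:
                if e.kind == "merged_by":
                    assert all(model.E[o] < model.E[r.label] for o in e.others)


class TestMaxPersistences:
    def make_gc(self, m=5, q=6, n=3):
        grid = ParameterGrid(np.arange(m, dtype=float), np.arange(q, dtype=float))
        labels = np.zeros((m, q, n), dtype=np.int64)
        return mpc.GridClustering(
            grid=grid, labels=labels, E=np.arange(n, dtype=float), populations=np.ones(n, dtype=int)
        )

    def test_full_grid_region(self):
        gc = self.make_gc()
        cells = frozenset((j, l) for j in range(5) for l in range(6))
        region = PersistenceRegion(label=0, cells=cells, birth_level=0)
        sp, dp, size = max_persistences(region, gc)
        assert (sp, dp) == (6, 5)
        assert size == 3  # all three unit-population states labeled 0

    def test_single_cell(self):
        gc = self.make_gc()
        region = PersistenceRegion(label=0, cells=frozenset({(2, 3)}), birth_level=2)
        assert max_persistences(region, gc)[:2] == (1, 1)

    def test_rectangle(self):
        gc = self.make_gc(m=8, q=10)
        cells = frozenset((j, l) for j in range(3, 6) for l in range(2, 10))
        region = PersistenceRegion(label=0, cells=cells, birth_level=3)
        assert max_persistences(region, gc)[:2] == (8, 3)

    def test_empty_region_raises(self):
        gc = self.make_gc()
        with pytest.raises(ValueError):
            max_persistences(PersistenceRegion(0, frozenset(), 0), gc)
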