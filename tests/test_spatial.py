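"""Spatial structure indices: hand-computed units, oracles, Monte-Carlo."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_stand
from standstruct.simulate import StandSpec, generate_stand
from standstruct.spatial import (
    StructureUnit,
    apply_edge_buffer,
    class_competition,
    compute_indices,
    dominance,
    find_neighbors,
    grade_distribution,
    hegyi,
    mingling,
    uniform_angle,
    voronoi_units,
)
from standstruct.diversity import diameter_class_labels


def unit(azimuths, distances=None, ids=None):
    return StructureUnit(
        center_id=0,
        neighbor_ids=np.array(ids if ids is not None else [1, 2, 3, 4]),
        distances=np.asarray(distances if distances is not None else [1.0] * 4),
        azimuths=np.asarray(azimuths, dtype=float),
    )


class TestEdgeBuffer:
    def test_examples(self):
        stand = make_stand([(1.0, 12.0), (12.5, 12.5)])
        core = apply_edge_buffer(stand, plot_size=25.0, buffer=2.5)
        assert list(core) == [False, True]

    def test_matches_distance_to_edge_oracle(self, poisson_stand):
        core = apply_edge_buffer(poisson_stand, 25.0, 2.5)
        xy = poisson_stand[["x_m", "y_m"]].to_numpy()
        edge_dist = np.minimum(xy, 25.0 - xy).min(axis=1)
        assert np.array_equal(core.to_numpy(), edge_dist >= 2.5)

    def test_oversized_buffer_rejected(self, poisson_stand):
        with pytest.raises(ValueError):
            apply_edge_buffer(poisson_stand, 25.0, buffer=13.0)


class TestFindNeighbors:
    def test_line_example(self):
        stand = make_stand([(0, 0), (1, 0), (2, 0), (3, 0), (10, 0)])
        u = find_neighbors(stand, central=1, k=4)
        assert set(u.neighbor_ids) == {2, 3, 4, 5}
        assert np.allclose(np.sort(u.distances), [1, 2, 3, 10])

    def test_azimuth_convention(self):
        stand = make_stand([(0, 0), (0, 1), (1, 0), (0, -1), (-1, 0)])
        u = find_neighbors(stand, central=1, k=4)
        az = dict(zip(u.neighbor_ids, u.azimuths))
        assert az[2] == pytest.approx(0.0)  # due north
        assert az[3] == pytest.approx(90.0)  # due east
        assert az[4] == pytest.approx(180.0)
        assert az[5] == pytest.approx(270.0)

    def test_matches_brute_force_sort(self, poisson_stand):
        ids = poisson_stand["tree_id"].to_numpy()
        xy = poisson_stand[["x_m", "y_m"]].to_numpy()
        for central in ids[:50]:
            u = find_neighbors(poisson_stand, central, k=4)
            ci = np.flatnonzero(ids == central)[0]
            d = np.hypot(*(xy - xy[ci]).T)
            d[ci] = np.inf
            expected = ids[np.lexsort((ids, d))[:4]]
            assert np.array_equal(u.neighbor_ids, expected)

    def test_coincident_positions_rejected(self):
        stand = make_stand([(0, 0), (0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(ValueError):
            find_neighbors(stand, central=1)


class TestVoronoi:
    def test_centre_of_square_touches_all_corners(self):
        stand = make_stand([(0, 0), (2, 0), (2, 2), (0, 2), (1, 1)])
        adj = voronoi_units(stand)
        assert adj[5] == {1, 2, 3, 4}

    def test_collinear_rejected(self):
        stand = make_stand([(i, i) for i in range(5)])
        with pytest.raises(ValueError):
            voronoi_units(stand)

    def test_adjacency_is_symmetric(self, poisson_stand):
        adj = voronoi_units(poisson_stand)
        for i, nbrs in adj.items():
            assert all(i in adj[j] for j in nbrs)


class TestIndices:
    @pytest.mark.parametrize(
        "azimuths, expected",
        [
            ([0, 90, 180, 270], 0.0),  # all gaps 90 >= 72
            ([0, 72, 144, 216], 0.0),  # gaps exactly 72: strict threshold
            ([0, 60, 120, 180], 0.75),  # gaps 60,60,60,180
            ([0, 10, 20, 30], 1.0),  # clumped: 10,10,10, gap 330 folds to 30
        ],
    )
    def test_uniform_angle(self, azimuths, expected):
        assert uniform_angle(unit(azimuths)) == expected

    def test_mingling(self):
        sp = {0: "a", 1: "a", 2: "b", 3: "c", 4: "a"}
        assert mingling(unit([0, 90, 180, 270]), sp) == 0.5
        assert mingling(unit([0, 90, 180, 270]), {k: "a" for k in range(5)}) == 0.0

    def test_dominance_strict_ties(self):
        u = unit([0, 90, 180, 270])
        big_centre = {0: 50.0, 1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}
        assert dominance(u, big_centre) == 0.0
        small_centre = {0: 5.0, 1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}
        assert dominance(u, small_centre) == 1.0
        all_equal = {k: 20.0 for k in range(5)}
        assert dominance(u, all_equal) == 0.0

    def test_hegyi_hand_example(self):
        u = unit([0, 90, 180, 270], distances=[2, 4, 5, 8])
        dbh = {0: 20.0, 1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}
        assert hegyi(u, dbh) == pytest.approx(1.05)

    def test_hegyi_single_neighbour_unit_contribution(self):
        u = StructureUnit(0, np.array([1]), np.array([1.0]), np.array([0.0]))
        assert hegyi(u, {0: 20.0, 1: 20.0}) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        stretch=st.floats(0.1, 10.0),
    )
    def test_hegyi_scaling_laws(self, scale, stretch):
        """DBH rescaling leaves CI unchanged; distances scale inversely."""
        u = unit([0, 90, 180, 270], distances=[2, 4, 5, 8])
        dbh = {0: 20.0, 1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}
        base = hegyi(u, dbh)
        assert hegyi(u, {k: v * scale for k, v in dbh.items()}) == pytest.approx(base)
        u2 = unit([0, 90, 180, 270], distances=np.array([2, 4, 5, 8]) * stretch)
        assert hegyi(u2, dbh) == pytest.approx(base / stretch)


class TestGradeDistribution:
    def test_uniform_example(self):
        g = grade_distribution([0, 0.25, 0.5, 0.75, 1])
        assert np.allclose(g.to_numpy(), 0.2)

    def test_single_grade(self):
        g = grade_distribution([0.5, 0.5, 0.5])
        assert g[0.5] == 1.0 and g.sum() == 1.0

    def test_rejects_empty_and_off_grid(self):
        with pytest.raises(ValueError):
            grade_distribution([])
        with pytest.raises(ValueError):
            grade_distribution([0.3])
        with pytest.raises(ValueError):
            grade_distribution([1.2])


class TestClassCompetition:
    def test_conservation_and_trend(self):
        stand = generate_stand(StandSpec(n_trees=300, pattern="poisson", seed=21))
        idx = compute_indices(stand, 25.0)
        labels = diameter_class_labels(idx["dbh_cm"])
        totals, mean_ci = class_competition(idx, labels)
        assert totals.sum() == pytest.approx(idx["CI"].sum())
        assert mean_ci == pytest.approx(idx["CI"].mean())
        # inverse-J stand: the small-diameter class carries the most total CI
        assert totals["I"] == totals.max()
        assert totals["I"] > totals[totals.index[-1]]

    def test_species_subset_single_tree(self):
        stand = make_stand(
            [(10, 10), (12, 10), (10, 12), (8, 10), (10, 8), (14, 14)],
            dbh=[20, 10, 10, 10, 10, 10],
            species=["tea", "o", "o", "o", "o", "o"],
        )
        idx = compute_indices(stand, 25.0)
        labels = diameter_class_labels(idx["dbh_cm"])
        totals, _ = class_competition(idx, labels, species="tea")
        tea_ci = idx.loc[idx["species"] == "tea", "CI"].iloc[0]
        assert totals.to_dict() == {"II": pytest.approx(tea_ci)}


class TestMonteCarloProperties:
    def test_index_values_on_grade_grid(self, poisson_stand):
        idx = compute_indices(poisson_stand, 25.0)
        for col in ("W", "U", "M"):
            assert set(np.round(idx[col] * 4).astype(int)) <= {0, 1, 2, 3, 4}
            grade_distribution(idx[col])  # must not raise

    def test_mean_dominance_half_for_iid_dbh(self):
        # continuous i.i.d. DBH: each neighbour is larger with prob 1/2
        stand = generate_stand(
            StandSpec(n_trees=700, plot_size=50.0, pattern="poisson", seed=31)
        )
        idx = compute_indices(stand, 50.0)
        assert len(idx) >= 500
        assert abs(idx["U"].mean() - 0.5) < 0.05

    def test_mean_uniform_angle_half_on_poisson(self):
        means = []
        for seed in range(5):
            stand = generate_stand(StandSpec(
                n_trees=700, plot_size=50.0, pattern="poisson", seed=100 + seed
            ))
            idx = compute_indices(stand, 50.0)
            means.append(idx["W"].mean())
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_pattern_ordering_of_mean_w(self):
        """Regular < random < clustered mean uniform angle (20 reps each)."""
        means = {}
        for pattern in ("grid", "poisson", "cluster"):
            reps = []
            for seed in range(20):
                stand = generate_stand(StandSpec(
                    pattern=pattern, n_trees=200, plot_size=25.0,
                    cluster_sd=1.0, seed=500 + seed,
                ))
                if pattern == "grid":  # jitter breaks exact ties only
                    rng = np.random.default_rng(seed)
                    stand = stand.copy()
                    stand[["x_m", "y_m"]] += rng.normal(0, 1e-3, (len(stand), 2))
                idx = compute_indices(stand, 25.0)
                reps.append(idx["W"].mean())
            means[pattern] = np.mean(reps)
        assert means["grid"] < means["poisson"] < means["cluster"]

    def test_compute_indices_matches_per_tree_functions(self, poisson_stand):
        idx = compute_indices(poisson_stand, 25.0)
        species = dict(zip(poisson_stand["tree_id"], poisson_stand["species"]))
        dbh = dict(zip(poisson_stand["tree_id"], poisson_stand["dbh_cm"]))
        sample = idx.sample(20, random_state=0)
        for row in sample.itertuples(index=False):
            u = find_neighbors(poisson_stand, row.tree_id, k=4)
            assert uniform_angle(u) == row.W
            assert mingling(u, species) == row.M
            assert dominance(u, dbh) == row.U
            assert hegyi(u, dbh) == pytest.approx(row.CI)
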