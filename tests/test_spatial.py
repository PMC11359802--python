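import numpy as np
import pytest

from chai.assignments import align_ensemble, to_binary_similarity
from chai.consensus import chai_avgsim, chai_snf
from chai.errors import ValidationError
from chai.fusion import SNFParams, average_similarity
from chai.metrics import adjusted_rand_index
from chai.spatial import (
    SpatialCoordinates,
    chai_avgsim_st,
    chai_snf_first_level,
    chai_snf_second_level,
    read_coordinates,
    spatial_binary_adjacency,
    write_coordinates,
)
from chai.synthetic import (
    SyntheticScenario,
    simulate_noisy_views,
    simulate_spatial,
    simulate_truth,
)


def brute_force_knn_adjacency(coords, K):
    """Independent oracle: pairwise distances, per-row top-K, union symmetrisation."""
    m = len(coords)
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    A = np.zeros((m, m), dtype=int)
    for i in range(m):
        order = sorted((j for j in range(m) if j != i), key=lambda j: (D[i, j], j))
        for j in order[:K]:
            A[i, j] = 1
    A = ((A + A.T) > 0).astype(int)
    np.fill_diagonal(A, 1)
    return A


class TestSpatialAdjacency:
    def test_collinear_points(self):
        coords = SpatialCoordinates(
            cell_ids=("a", "b", "c"), coords=np.array([[0.0, 0], [1, 0], [10, 0]])
        )
        A = spatial_binary_adjacency(coords, K=1)
        # b's nearest is a; c's nearest is b (union adds the b–c edge); a–c absent
        np.testing.assert_array_equal(A.values, [[1, 1, 0], [1, 1, 1], [0, 1, 1]])

    def test_complete_graph_at_k_max(self, rng):
        coords = SpatialCoordinates(
            cell_ids=tuple(f"c{i}" for i in range(6)), coords=rng.random((6, 2))
        )
        A = spatial_binary_adjacency(coords, K=5)
        assert (A.values == 1).all()

    def test_matches_brute_force(self, rng):
        pts = rng.random((20, 2))
        coords = SpatialCoordinates(tuple(f"c{i}" for i in range(20)), pts)
        A = spatial_binary_adjacency(coords, K=3)
        np.testing.assert_array_equal(A.values, brute_force_knn_adjacency(pts, 3))

    def test_permutation_equivariance(self, rng):
        pts = rng.random((12, 2))
        ids = tuple(f"c{i}" for i in range(12))
        A = spatial_binary_adjacency(SpatialCoordinates(ids, pts), K=3).values
        perm = rng.permutation(12)
        Ap = spatial_binary_adjacency(
            SpatialCoordinates(tuple(ids[p] for p in perm), pts[perm]), K=3
        ).values
        np.testing.assert_array_equal(Ap, A[np.ix_(perm, perm)])

    def test_scale_invariance(self, rng):
        pts = rng.random((15, 2))
        ids = tuple(f"c{i}" for i in range(15))
        A1 = spatial_binary_adjacency(SpatialCoordinates(ids, pts), K=3).values
        A2 = spatial_binary_adjacency(SpatialCoordinates(ids, pts * 137.0), K=3).values
        np.testing.assert_array_equal(A1, A2)

    def test_k_too_large_rejected(self, rng):
        coords = SpatialCoordinates(("a", "b"), rng.random((2, 2)))
        with pytest.raises(ValidationError):
            spatial_binary_adjacency(coords, K=2)

    def test_min_degree_after_union(self, rng):
        pts = rng.random((25, 2))
        A = spatial_binary_adjacency(
            SpatialCoordinates(tuple(f"c{i}" for i in range(25)), pts), K=3
        ).values
        off_degree = A.sum(axis=1) - 1
        assert (off_degree >= 3).all()


class TestCoordinateIO:
    def test_round_trip(self, tmp_path, rng):
        coords = SpatialCoordinates(
            cell_ids=tuple(f"c{i}" for i in range(10)), coords=rng.random((10, 2))
        )
        p = tmp_path / "coords.csv"
        write_coordinates(coords, p)
        back = read_coordinates(p)
        assert back.cell_ids == coords.cell_ids
        np.testing.assert_allclose(back.coords, coords.coords)


@pytest.fixture
def noisy_label_clean_spatial():
    """Noisy views (flip 0.2) over a truth whose coordinates separate the
    clusters essentially perfectly: the regime where spatial signal is
    stronger than label noise."""
    scenario = SyntheticScenario(
        m=150, k_true=3, flip_rate=0.2, spatial_separation=10.0, seed=21
    )
    truth = simulate_truth(scenario)
    views = simulate_noisy_views(truth, 3, 0.2, seed=22)
    coords = simulate_spatial(truth, 10.0, seed=23)
    return truth, align_ensemble(views), coords


class TestSTDrivers:
    def test_avgsim_st_mean_of_two(self, noisy_label_clean_spatial):
        truth, ensemble, coords = noisy_label_clean_spatial
        single = align_ensemble([ensemble.assignments[0]])
        result = chai_avgsim_st(single, coords, k=3, seed=0)
        assert result.method == "avgsim-st"
        # fused matrix is the entry-wise mean of assignment matrix and adjacency
        M1 = to_binary_similarity(single.assignments[0])
        A = spatial_binary_adjacency(coords.reindex(single.cell_ids), K=3)
        fused = average_similarity([M1, A]).values
        np.testing.assert_allclose(
            fused, (M1.values.astype(float) + A.values.astype(float)) / 2
        )

    def test_duplicate_spatial_view_keeps_avgsim_result(self):
        # spatial adjacency identical to every assignment matrix: the mean
        # is unchanged, so the ST result equals plain avgsim
        truth = simulate_truth(SyntheticScenario(m=30, k_true=3, seed=31))
        ensemble = align_ensemble(
            simulate_noisy_views(truth, 3, 0.0, seed=32)
        )
        M = to_binary_similarity(ensemble.assignments[0])
        plain = chai_avgsim(ensemble, k=3, seed=0)
        # coordinates that reproduce M exactly: clusters far apart, K big
        coords = simulate_spatial(truth, 1000.0, seed=33)
        st = chai_avgsim_st(ensemble, coords, k=3, seed=0, spatial_K=9)
        assert adjusted_rand_index(st.labels, plain.labels) == 1.0

    def test_first_level_perfect_recovery(self):
        truth = simulate_truth(SyntheticScenario(m=30, k_true=3, seed=41))
        ensemble = align_ensemble(simulate_noisy_views(truth, 2, 0.0, seed=42))
        coords = simulate_spatial(truth, 1000.0, seed=43)
        result = chai_snf_first_level(ensemble, coords, k=3, seed=0, spatial_K=9)
        assert adjusted_rand_index(result.labels, truth.labels) == 1.0

    def test_first_level_determinism(self, noisy_label_clean_spatial):
        truth, ensemble, coords = noisy_label_clean_spatial
        r1 = chai_snf_first_level(ensemble, coords, k=3, seed=5)
        r2 = chai_snf_first_level(ensemble, coords, k=3, seed=5)
        assert r1 == r2

    def test_second_level_perfect_recovery(self):
        truth = simulate_truth(SyntheticScenario(m=30, k_true=3, seed=51))
        ensemble = align_ensemble(simulate_noisy_views(truth, 2, 0.0, seed=52))
        coords = simulate_spatial(truth, 1000.0, seed=53)
        result = chai_snf_second_level(ensemble, coords, k=3, seed=0, spatial_K=9)
        assert adjusted_rand_index(result.labels, truth.labels) == 1.0
        assert result.method == "snf-second-level"

    def test_second_level_needs_two_assignments(self, noisy_label_clean_spatial):
        truth, ensemble, coords = noisy_label_clean_spatial
        single = align_ensemble([ensemble.assignments[0]])
        with pytest.raises(ValidationError):
            chai_snf_second_level(single, coords, k=3)

    def test_id_mismatch_rejected(self, noisy_label_clean_spatial, rng):
        truth, ensemble, _ = noisy_label_clean_spatial
        bad = SpatialCoordinates(("x", "y", "z"), rng.random((3, 2)))
        with pytest.raises(ValidationError):
            chai_avgsim_st(ensemble, bad, k=3)

    def test_spatial_helps_under_label_noise(self):
        """Clean spatial signal should not hurt, and usually helps, when
        labels are noisy (checked across 5 seeds)."""
        for seed in range(5):
            scenario = SyntheticScenario(
                m=150, k_true=3, flip_rate=0.2, spatial_separation=10.0, seed=60 + seed
            )
            truth = simulate_truth(scenario)
            ensemble = align_ensemble(
                simulate_noisy_views(truth, 3, 0.2, seed=70 + seed)
            )
            coords = simulate_spatial(truth, 10.0, seed=80 + seed)
            plain = chai_snf(ensemble, k=3, seed=0)
            st = chai_snf_first_level(ensemble, coords, k=3, seed=0)
            ari_plain = adjusted_rand_index(plain.labels, truth.labels)
            ari_st = adjusted_rand_index(st.labels, truth.labels)
            assert ari_st >= ari_plain - 1e-9
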