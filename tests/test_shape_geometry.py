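import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingmorph import (
    LandmarkConfiguration,
    LandmarkDataset,
    SyntheticSpec,
    centroid_size,
    generate,
    gpa,
    mirror,
    opa_align,
    procrustes_distance_matrix,
    tangent_adequacy,
    tangent_project,
)
from wingmorph.exceptions import DegenerateShapeError, WingmorphError
from wingmorph.shape_geometry import optimal_rotation
from wingmorph.synthetic_data import Nuisance, Taxonomy

from conftest import SMALL_TAXONOMY, random_shape, similarity_transform


def brute_force_opa_distance(a, b, step=1e-3):
    """Independent oracle: minimize over a dense grid of rotation angles."""
    a = a - a.mean(0)
    a /= np.sqrt((a**2).sum())
    b = b - b.mean(0)
    b /= np.sqrt((b**2).sum())
    best = np.inf
    for theta in np.arange(0.0, 2 * np.pi, step):
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        best = min(best, np.sqrt(((a @ rot.T - b) ** 2).sum()))
    return best


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(
        c=st.floats(0.01, 100),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_homogeneity_and_translation_invariance(self, c, tx, ty):
        shape = np.array([[0, 0], [2, 1], [1, 3], [4, 0]], dtype=float)
        base = centroid_size(shape)
        assert centroid_size(shape * c) == pytest.approx(base * c, rel=1e-9)
        assert centroid_size(shape + [tx, ty]) == pytest.approx(base, rel=1e-9)

    def test_coincident_landmarks_degenerate(self):
        with pytest.raises(DegenerateShapeError):
            centroid_size(np.ones((5, 2)))


class TestOpa:
    def test_self_alignment_distance_zero(self, rng):
        shape = random_shape(rng)
        _, dist = opa_align(shape, shape)
        assert dist == pytest.approx(0.0, abs=1e-10)

    def test_similarity_transformed_copy_distance_zero(self, rng):
        shape = random_shape(rng)
        moved = similarity_transform(rng, shape)
        _, dist = opa_align(moved, shape)
        assert dist == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_rotation_grid(self, rng):
        for _ in range(20):
            a, b = random_shape(rng), random_shape(rng)
            _, dist = opa_align(a, b)
            assert dist == pytest.approx(
                brute_force_opa_distance(a, b), abs=1e-5
            )

    def test_rotation_is_always_proper(self, rng):
        for _ in range(20):
            a = random_shape(rng)
            b = random_shape(rng)
            b[:, 0] *= -1  # even a mirrored target gets a proper rotation
            rot = optimal_rotation(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-12)

    def test_mirror_negates_x(self, rng):
        shape = random_shape(rng)
        np.testing.assert_allclose(mirror(shape)[:, 0], -shape[:, 0])
        np.testing.assert_allclose(mirror(shape)[:, 1], shape[:, 1])


class TestGpa:
    def test_copies_of_one_shape_collapse_onto_consensus(self, rng):
        base = random_shape(rng, k=8)
        coords = np.stack(
            [similarity_transform(rng, base) for _ in range(6)]
        )
        aligned = gpa(coords)
        assert aligned.converged
        assert aligned.iterations <= 2
        for row in aligned.aligned:
            np.testing.assert_allclose(row, aligned.consensus, atol=1e-8)

    def test_invariance_under_per_specimen_similarity_transforms(self, rng):
        spec = SyntheticSpec(
            taxonomy=SMALL_TAXONOMY, nuisance=Nuisance.none(), seed=3
        )
        dataset, _ = generate(spec)
        coords = dataset.coords_array()
        transformed = np.stack(
            [similarity_transform(rng, c) for c in coords]
        )
        t1 = tangent_project(gpa(coords, tol=1e-12))
        t2 = tangent_project(gpa(transformed, tol=1e-12))
        np.testing.assert_allclose(t1.aligned, t2.aligned, atol=1e-8)
        np.testing.assert_allclose(t1.consensus, t2.consensus, atol=1e-8)

    def test_two_shapes_equidistant_from_consensus(self, rng):
        coords = np.stack([random_shape(rng, 6), random_shape(rng, 6)])
        aligned = gpa(coords, tol=1e-12)
        c = aligned.consensus.reshape(-1, 2)
        d = [opa_align(s, c)[1] for s in aligned.shapes()]
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_consensus_has_unit_centroid_size(self, small_dataset):
        aligned = gpa(small_dataset)
        assert centroid_size(aligned.consensus_shape()) == pytest.approx(
            1.0, abs=1e-9
        )
        # aligned rows centered at the origin
        means = aligned.shapes().mean(axis=1)
        assert np.abs(means).max() < 1e-9

    def test_centroid_sizes_are_pre_scaling_sizes(self, rng):
        base = random_shape(rng, k=6)
        coords = np.stack([base, base * 3.0 + 2.0])
        aligned = gpa(coords)
        ratio = aligned.centroid_sizes[1] / aligned.centroid_sizes[0]
        assert ratio == pytest.approx(3.0, rel=1e-9)


class TestTangentSpace:
    def test_consensus_projects_to_itself(self, small_dataset):
        aligned = gpa(small_dataset)
        c = aligned.consensus
        proj = c - (np.dot(c, c) - 1.0) * c
        np.testing.assert_allclose(proj, c, atol=1e-12)

    def test_projected_deviations_orthogonal_to_consensus(self, small_tangent):
        dev = small_tangent.aligned - small_tangent.consensus
        dots = dev @ small_tangent.consensus
        assert np.abs(dots).max() < 1e-10

    def test_projection_is_mathematically_idempotent(self, small_tangent):
        c = small_tangent.consensus
        x = small_tangent.aligned
        again = x - np.outer(x @ c - 1.0, c)
        np.testing.assert_allclose(again, x, atol=1e-12)

    def test_double_projection_rejected(self, small_tangent):
        with pytest.raises(WingmorphError, match="already"):
            tangent_project(small_tangent)

    def test_distances_on_tangent_input_rejected(self, small_tangent):
        with pytest.raises(WingmorphError):
            procrustes_distance_matrix(small_tangent)


@pytest.fixture(scope="module")
def aligned20():
    spec = SyntheticSpec(
        taxonomy=Taxonomy(1, 1, 1, 2, 2, 5), noise_sd=0.02, seed=11
    )
    dataset, _ = generate(spec)
    return gpa(dataset)


class TestDistanceMatrix:

    def test_symmetric_zero_diagonal(self, aligned20):
        d = procrustes_distance_matrix(aligned20)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_matches_pairwise_opa(self, aligned20):
        d = procrustes_distance_matrix(aligned20)
        shapes = aligned20.shapes()
        for i in range(0, 20, 5):
            for j in range(0, 20, 3):
                if i == j:
                    continue
                _, dij = opa_align(shapes[j], shapes[i])
                assert d[i, j] == pytest.approx(dij, abs=1e-10)

    def test_triangle_inequality_all_triples(self, aligned20):
        d = procrustes_distance_matrix(aligned20)
        n = d.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                for m in range(n):
                    assert d[i, j] <= d[i, m] + d[m, j] + 1e-12


class TestAdequacy:
    def test_low_variation_slope_and_correlation(self):
        spec = SyntheticSpec(
            taxonomy=SMALL_TAXONOMY, noise_sd=0.001, seed=5
        )
        dataset, _ = generate(spec)
        aligned = gpa(dataset)
        report = tangent_adequacy(aligned, tangent_project(aligned))
        n = len(dataset)
        assert report.n_pairs == n * (n - 1) // 2
        assert report.slope >= 0.999
        assert report.correlation >= 0.999
        assert 0.99 <= report.slope <= 1.001

    def test_three_shapes_give_three_pairs(self, rng):
        a = random_shape(rng, 6)
        coords = np.stack([a, a, random_shape(rng, 6)])
        aligned = gpa(coords)
        report = tangent_adequacy(aligned, tangent_project(aligned))
        assert report.n_pairs == 3
        assert np.isfinite(report.slope)

    def test_identical_shapes_undefined(self, rng):
        a = random_shape(rng, 6)
        aligned = gpa(np.stack([a, a, a]))
        with pytest.raises(DegenerateShapeError):
            tangent_adequacy(aligned, tangent_project(aligned))

    def test_mismatched_inputs_rejected(self, small_dataset):
        aligned = gpa(small_dataset)
        with pytest.raises(WingmorphError):
            tangent_adequacy(aligned, aligned)
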