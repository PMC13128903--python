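"""Morphospace PCA, projection, theoretical grid and the impossible-space
(self-intersection) mask."""

import numpy as np
import pytest

from conftest import ellipse, star_polygon
from wingmorph.efa import efa_forward, from_feature_vector, standardise_size, to_feature_vector
from wingmorph.errors import ParameterError
from wingmorph.morphospace import (
    build_grid,
    fit_morphospace,
    inverse_map,
    project,
    self_intersects,
)
from wingmorph.outline import Outline, canonicalise


@pytest.fixture(scope="module")
def ellipse_model():
    """Specimens varying along a single synthetic axis (ellipse aspect)."""
    hs = [efa_forward(ellipse(1.0, b, 200), H=3) for b in np.linspace(0.3, 0.9, 12)]
    return hs, fit_morphospace(hs)


class TestFit:
    def test_single_axis_variation_loads_on_pc1(self, ellipse_model):
        _, model = ellipse_model
        assert model.explained_variance_ratio_[0] > 0.99

    def test_variance_decomposition(self, ellipse_model):
        _, model = ellipse_model
        evr = model.explained_variance_ratio_
        assert np.all(evr >= 0) and evr.sum() <= 1 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)

    def test_loadings_orthonormal(self, ellipse_model):
        _, model = ellipse_model
        G = model.components_ @ model.components_.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-9)

    def test_scores_reproduce_inputs(self, ellipse_model):
        hs, model = ellipse_model
        X = np.vstack([to_feature_vector(h) for h in hs])
        back = model.mean_ + model.scores_ @ model.components_
        assert np.allclose(back, X, atol=1e-9)

    def test_duplicated_specimens_give_same_model_up_to_sign(self, ellipse_model):
        hs, model = ellipse_model
        model2 = fit_morphospace(hs + hs)
        assert np.allclose(
            model2.explained_variance_ratio_[:3],
            model.explained_variance_ratio_[:3],
            atol=1e-9,
        )
        dots = np.abs(np.sum(model.components_[:2] * model2.components_[:2], axis=1))
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_mixed_harmonic_counts_rejected(self):
        hs = [efa_forward(ellipse(1, 0.5, 100), H=3), efa_forward(ellipse(1, 0.6, 100), H=4)]
        hs.append(efa_forward(ellipse(1, 0.7, 100), H=3))
        with pytest.raises(ParameterError):
            fit_morphospace(hs)


class TestProject:
    def test_mean_specimen_projects_to_origin(self, ellipse_model):
        hs, model = ellipse_model
        mean_h = from_feature_vector(model.mean_, H=3)
        assert np.allclose(project(model, mean_h), 0.0, atol=1e-9)

    def test_training_specimen_recovers_stored_score(self, ellipse_model):
        hs, model = ellipse_model
        for k in (0, 5, 11):
            assert np.allclose(project(model, hs[k]), model.scores_[k], atol=1e-9)

    def test_dimension_mismatch_raises(self, ellipse_model):
        _, model = ellipse_model
        with pytest.raises(ParameterError):
            project(model, efa_forward(ellipse(1, 0.5, 100), H=4))


class TestInverseMap:
    def test_origin_is_the_standardised_mean_shape(self, ellipse_model):
        _, model = ellipse_model
        from wingmorph.efa import efa_inverse

        o = inverse_map(model, 0.0, 0.0, n_points=240)
        expected = efa_inverse(
            standardise_size(from_feature_vector(model.mean_, H=3)), 240
        )
        assert np.allclose(o.points, expected.points, atol=1e-9)

    def test_coefficient_arithmetic_matches_direct_construction(self, ellipse_model):
        _, model = ellipse_model
        from wingmorph.efa import efa_inverse

        pc1, pc2 = 0.03, -0.02
        vec = model.mean_ + pc1 * model.components_[0] + pc2 * model.components_[1]
        expected = efa_inverse(standardise_size(from_feature_vector(vec, H=3)), 240)
        got = inverse_map(model, pc1, pc2, n_points=240)
        assert np.allclose(got.points, expected.points, atol=1e-9)

    def test_linear_in_pc_before_restandardisation(self, ellipse_model):
        _, model = ellipse_model
        v0 = model.mean_ + 0.0 * model.components_[0]
        va = model.mean_ + 0.02 * model.components_[0]
        vb = model.mean_ + 0.04 * model.components_[0]
        assert np.allclose(vb - va, va - v0, atol=1e-12)


class TestGrid:
    def test_node_count_is_nx_times_ny(self, ellipse_model):
        _, model = ellipse_model
        grid = build_grid(model, nx=5, ny=4, expansion=0.2, n_points=120)
        assert grid.n_nodes == 20
        assert grid.valid.shape == (5, 4)

    def test_zero_expansion_corners_hit_empirical_extremes(self, ellipse_model):
        _, model = ellipse_model
        grid = build_grid(model, nx=4, ny=3, expansion=0.0, n_points=120)
        s = model.scores_
        assert grid.pc1_values[0] == pytest.approx(s[:, 0].min())
        assert grid.pc1_values[-1] == pytest.approx(s[:, 0].max())
        assert grid.pc2_values[0] == pytest.approx(s[:, 1].min())
        assert grid.pc2_values[-1] == pytest.approx(s[:, 1].max())

    def test_all_elliptical_training_set_gives_all_valid_nodes(self, ellipse_model):
        _, model = ellipse_model
        grid = build_grid(model, nx=6, ny=5, expansion=0.2, n_points=120)
        assert grid.valid.all()

    def test_expansion_never_shrinks_impossible_space(self, fitted_space):
        _, model = fitted_space
        counts = [
            build_grid(model, nx=10, ny=9, expansion=e, n_points=200).n_invalid
            for e in (0.0, 0.2, 0.6)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    @pytest.mark.filterwarnings("ignore:invalid value encountered")
    def test_degenerate_axis_raises(self, ellipse_model):
        hs, _ = ellipse_model
        same = fit_morphospace([hs[0]] * 3 + hs[:1])
        with pytest.raises(ParameterError):
            build_grid(same, nx=3, ny=3)


def brute_force_self_intersects(outline: Outline) -> bool:
    """All-pairs O(n^2) proper-intersection test over non-adjacent segments."""
    pts = outline.closed_points()
    segs = [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    n = len(segs)

    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    def seg_intersect(a, b, c, d):
        d1, d2 = orient(c, d, a), orient(c, d, b)
        d3, d4 = orient(a, b, c), orient(a, b, d)
        if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
            return True
        return False

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if seg_intersect(*segs[i], *segs[j]):
                return True
    return False


class TestSelfIntersects:
    def test_convex_polygon_is_simple(self):
        assert not self_intersects(canonicalise([[0, 0], [2, 0], [2, 1], [0, 1]]))

    def test_bowtie_quadrilateral_intersects(self):
        bow = Outline(np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]]))
        assert self_intersects(bow)

    def test_agrees_with_brute_force_on_random_polygons(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(4, 51))
            pts = rng.uniform(-1, 1, size=(n, 2))
            try:
                o = canonicalise(pts)
            except Exception:
                continue
            assert self_intersects(o) == brute_force_self_intersects(o)
            checked += 1
        assert checked >= 190
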