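"""Min-max standardization, thin-plate grid fits, consensus and deformation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticalmap import synthetic as syn
from corticalmap.errors import FitError, GridMismatchError, ParameterError
from corticalmap.gridmap import (GridSpec, ThinPlateSmoother, consensus_map,
                                 deformation_map, fit_map, normalize_thickness)
from corticalmap.thickness import ThicknessCloud


def make_cloud(z, x=None, y=None, standardized=False, n=None):
    n = n or len(z)
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, n) if x is None else x
    y = rng.uniform(0, 1, n) if y is None else y
    return ThicknessCloud(x, y, np.asarray(z, dtype=float), "t",
                          standardized=standardized)


def bump_field(x, y, cy=0.25):
    dy = (y - cy + 0.5) % 1.0 - 0.5
    return 0.3 + 0.5 * np.exp(-0.5 * (((x - 0.5) / 0.1) ** 2
                                      + (dy / 0.08) ** 2))


@pytest.fixture(scope="module")
def sampled_cloud():
    rng = np.random.default_rng(1)
    x, y = rng.uniform(0, 1, 5000), rng.uniform(0, 1, 5000)
    return ThicknessCloud(x, y, bump_field(x, y), "planted",
                          standardized=True)


class TestNormalize:
    def test_minmax_endpoints(self):
        cloud = normalize_thickness(make_cloud([2.0, 3.0, 4.0] * 20))
        assert set(np.round(np.unique(cloud.z), 12)) == {0.0, 0.5, 1.0}
        assert cloud.standardized

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        z = np.linspace(1.0, 4.0, 30)
        ref = normalize_thickness(make_cloud(z))
        scaled = normalize_thickness(make_cloud(a * z + b))
        assert np.allclose(ref.z, scaled.z, atol=1e-9)

    def test_constant_field_degenerates_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            cloud = normalize_thickness(make_cloud(np.full(60, 3.0)))
        assert np.all(cloud.z == 0.5)


class TestFitMap:
    def test_default_long_form_has_20000_rows(self, sampled_cloud):
        m = fit_map(sampled_cloud)
        assert len(m.long_form) == 20000
        assert list(m.long_form.columns) == ["x", "y", "z"]

    def test_long_form_rows_equal_m_times_k(self, sampled_cloud, small_grid):
        m = fit_map(sampled_cloud, small_grid)
        assert len(m.long_form) == small_grid.M * small_grid.K

    def test_planted_field_recovered(self, sampled_cloud):
        m = fit_map(sampled_cloud)
        gs = m.gridspec
        gx, gy = np.meshgrid(gs.x, gs.y)
        assert np.max(np.abs(m.grid - bump_field(gx, gy))) <= 0.05

    def test_seam_bump_reconstructed_contiguously(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 1, 5000), rng.uniform(0, 1, 5000)
        cloud = ThicknessCloud(x, y, bump_field(x, y, cy=0.0), "seam",
                               standardized=True)
        m = fit_map(cloud)
        gs = m.gridspec
        gx, gy = np.meshgrid(gs.x, gs.y)
        # same accuracy as away from the seam: one contiguous wrapped bump
        assert np.max(np.abs(m.grid - bump_field(gx, gy, cy=0.0))) <= 0.05
        # the two seam-adjacent rows both carry the near-peak value
        assert m.grid[0].max() > 0.7 and m.grid[-1].max() > 0.7

    def test_smoother_linearity_in_z(self, small_grid):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0, 1, 800), rng.uniform(0, 1, 800)
        z = bump_field(x, y)
        a = fit_map(ThicknessCloud(x, y, z, "a"), small_grid)
        b = fit_map(ThicknessCloud(x, y, 2.0 * z, "b"), small_grid)
        assert np.allclose(b.grid, 2.0 * a.grid, atol=1e-8)

    def test_gcv_approaches_interpolation_as_noise_vanishes(self, small_grid):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0, 1, 2000), rng.uniform(0, 1, 2000)
        z = bump_field(x, y)
        clean = fit_map(ThicknessCloud(x, y, z, "clean", standardized=True),
                        small_grid)
        noisy = fit_map(ThicknessCloud(
            x, y, np.clip(z + rng.normal(0, 0.1, len(z)), 0, 1), "noisy",
            standardized=True), small_grid)
        gx, gy = np.meshgrid(small_grid.x, small_grid.y)
        truth = bump_field(gx, gy)
        err_clean = np.abs(clean.grid - truth).max()
        err_noisy = np.abs(noisy.grid - truth).max()
        assert err_clean < err_noisy
        assert err_clean <= 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match="50"):
            fit_map(make_cloud(np.linspace(0, 1, 20)))

    def test_standardized_maps_are_clipped_to_unit_interval(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        z = np.clip(bump_field(x, y) + rng.normal(0, 0.15, 500), 0, 1)
        m = fit_map(ThicknessCloud(x, y, z, "c", standardized=True))
        assert m.grid.min() >= 0.0 and m.grid.max() <= 1.0


class TestConsensus:
    def test_single_cloud_consensus_equals_fit(self, sampled_cloud, small_grid):
        single = fit_map(sampled_cloud, small_grid)
        cons = consensus_map([sampled_cloud], small_grid)
        assert np.allclose(cons.grid, single.grid, atol=1e-12)

    def test_duplicated_clouds_equal_single_fit(self, sampled_cloud,
                                                small_grid):
        single = fit_map(sampled_cloud, small_grid)
        cons = consensus_map([sampled_cloud] * 3, small_grid)
        assert np.allclose(cons.grid, single.grid, atol=1e-8)

    def test_two_opposite_bumps_average(self, small_grid):
        rng = np.random.default_rng(6)
        clouds = []
        for cy in (0.25, 0.75):
            x, y = rng.uniform(0, 1, 3000), rng.uniform(0, 1, 3000)
            clouds.append(ThicknessCloud(x, y, bump_field(x, y, cy=cy),
                                         f"g{cy}", standardized=True))
        cons = consensus_map(clouds, small_grid)
        gx, gy = np.meshgrid(small_grid.x, small_grid.y)
        mean_field = (bump_field(gx, gy, 0.25) + bump_field(gx, gy, 0.75)) / 2
        # the pooled fit approximates the average field, and is far closer
        # to it than to either contributing field
        rmse = lambda a, b: float(np.sqrt(np.mean((a - b) ** 2)))  # noqa: E731
        assert rmse(cons.grid, mean_field) <= 0.02
        assert np.max(np.abs(cons.grid - mean_field)) <= 0.10
        for cy in (0.25, 0.75):
            assert rmse(cons.grid, mean_field) < 0.25 * rmse(
                cons.grid, bump_field(gx, gy, cy))

    def test_empty_pool_rejected(self):
        with pytest.raises(ParameterError):
            consensus_map([])


class TestDeformation:
    def test_self_difference_is_zero_and_antisymmetric(self, sampled_cloud,
                                                       small_grid):
        a = fit_map(sampled_cloud, small_grid)
        b = consensus_map([sampled_cloud], small_grid)
        assert np.all(deformation_map(a, a) == 0.0)
        assert np.allclose(deformation_map(a, b), -deformation_map(b, a))

    def test_grid_mismatch_rejected(self, sampled_cloud, small_grid):
        a = fit_map(sampled_cloud, small_grid)
        b = fit_map(sampled_cloud, GridSpec(M=20, K=40))
        with pytest.raises(GridMismatchError):
            deformation_map(a, b)


def test_gridspec_validation_and_nodes():
    with pytest.raises(ParameterError):
        GridSpec(M=2, K=10)
    gs = GridSpec(M=4, K=6)
    nodes = gs.nodes()
    assert nodes.shape == (24, 2)
    assert nodes[0] == pytest.approx([1 / 8, 1 / 12])
    # row-major: x varies fastest
    assert nodes[1] == pytest.approx([3 / 8, 1 / 12])
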