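"""Central-place foraging: kernels, visitation, collected resources.

The vectorized (FFT) implementation is checked against a brute-force
double loop over all source/destination cell pairs.
"""

import math

import numpy as np
import pytest

from beescape import ModelParams, resources_per_nest, truncation_radius, visitation_rates
from beescape.foraging import kernel_stencil, kernel_weight


# ---------------------------------------------------------------- oracles
def brute_force_visits(X, F, params, cell_size):
    """Direct evaluation of the visitation sum over all (source, dest) pairs."""
    n_r, n_c = X.shape
    r_trunc = truncation_radius(params.beta, params.kernel_quantile)
    V = np.zeros_like(F, dtype=float)
    for jr in range(n_r):
        for jc in range(n_c):
            if X[jr, jc] == 0:
                continue
            w = np.zeros_like(F)
            for ir in range(n_r):
                for ic in range(n_c):
                    d = cell_size * math.hypot(ir - jr, ic - jc)
                    if d <= r_trunc:
                        w[ir, ic] = F[ir, ic] * math.exp(-d / params.beta)
            Z = w.sum()
            if Z == 0:
                continue
            for ir in range(n_r):
                for ic in range(n_c):
                    d = cell_size * math.hypot(ir - jr, ic - jc)
                    if d <= r_trunc:
                        V[ir, ic] += X[jr, jc] * w[ir, ic] / Z * params.rho_F**d
    return V


def brute_force_resources(X, N, F, params, cell_size):
    """Direct evaluation of foragers-per-nest x kernel-weighted mean F."""
    n_r, n_c = X.shape
    r_trunc = truncation_radius(params.beta, params.kernel_quantile)
    R = np.zeros_like(F, dtype=float)
    for ir in range(n_r):
        for ic in range(n_c):
            if N[ir, ic] == 0:
                continue
            num = den = 0.0
            for jr in range(n_r):
                for jc in range(n_c):
                    d = cell_size * math.hypot(ir - jr, ic - jc)
                    if d <= r_trunc:
                        k = math.exp(-d / params.beta)
                        num += F[jr, jc] * k
                        den += k
            R[ir, ic] = X[ir, ic] / N[ir, ic] * num / den
    return R


# ---------------------------------------------------------------- kernels
class TestKernel:
    def test_weight_at_zero_distance(self):
        assert kernel_weight(0.0, 530.0) == 1.0

    def test_weight_at_mean_distance(self):
        assert kernel_weight(530.0, 530.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_weight_zero_beyond_truncation(self):
        r = truncation_radius(530.0, 0.99)
        assert kernel_weight(r + 1.0, 530.0) == 0.0
        assert kernel_weight(r - 1.0, 530.0) > 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_weight(-1.0, 530.0)

    @pytest.mark.parametrize(
        "beta,q,expected",
        [(530.0, 0.99, -530.0 * math.log(0.01)), (1000.0, 0.99, -1000.0 * math.log(0.01))],
    )
    def test_truncation_radius_closed_form(self, beta, q, expected):
        assert truncation_radius(beta, q) == pytest.approx(expected, rel=1e-12)

    def test_truncation_radius_vanishes_at_zero_quantile(self):
        assert truncation_radius(530.0, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_truncation_radius_rejects_bad_quantile(self):
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                truncation_radius(530.0, q)

    def test_stencil_center_and_symmetry(self, params):
        k = kernel_stencil(params.beta, 25.0)
        c = k.shape[0] // 2
        assert k[c, c] == 1.0
        np.testing.assert_allclose(k, k[::-1, :])
        np.testing.assert_allclose(k, k[:, ::-1])
        np.testing.assert_allclose(k, k.T)


# ---------------------------------------------------------------- visitation
class TestVisitation:
    def test_equal_distance_allocation_proportional_to_flowers(self, params):
        # one source with 10 foragers, two equidistant flower cells F = 2 and 1
        X = np.zeros((3, 3))
        X[1, 1] = 10.0
        F = np.zeros((3, 3))
        F[1, 0], F[1, 2] = 2.0, 1.0
        V = visitation_rates(X, F, params).V
        assert V[1, 0] == pytest.approx(20.0 / 3.0, rel=1e-9)
        assert V[1, 2] == pytest.approx(10.0 / 3.0, rel=1e-9)

    def test_no_flowers_no_visits(self, params, rng):
        X = rng.random((6, 6))
        V = visitation_rates(X, np.zeros((6, 6)), params).V
        assert np.all(V == 0)

    def test_matches_brute_force_oracle(self, rng):
        params = ModelParams()
        X = rng.integers(0, 10, size=(12, 12)).astype(float)
        F = rng.random((12, 12))
        V = visitation_rates(X, F, params).V
        V_oracle = brute_force_visits(X, F, params, 25.0)
        assert np.max(np.abs(V - V_oracle)) < 1e-10

    def test_matches_brute_force_with_mortality(self, rng):
        params = ModelParams(rho_F=0.999)
        X = rng.integers(0, 10, size=(9, 9)).astype(float)
        F = rng.random((9, 9))
        V = visitation_rates(X, F, params).V
        V_oracle = brute_force_visits(X, F, params, 25.0)
        assert np.max(np.abs(V - V_oracle)) < 1e-10

    def test_forager_conservation_without_mortality(self, params, rng):
        X = rng.random((20, 20)) * 5
        F = rng.random((20, 20)) + 0.01
        V = visitation_rates(X, F, params).V
        assert V.sum() == pytest.approx(X.sum(), rel=1e-9)

    def test_mortality_loses_foragers(self, rng):
        params = ModelParams(rho_F=0.999)
        X = rng.random((20, 20)) * 5
        F = rng.random((20, 20)) + 0.01
        assert visitation_rates(X, F, params).V.sum() < X.sum()

    def test_raising_local_flowers_redistributes_finite_foragers(self, params, rng):
        X = rng.random((15, 15))
        F = rng.random((15, 15)) + 0.1
        V0 = visitation_rates(X, F, params).V
        F2 = F.copy()
        F2[7, 7] *= 3.0
        V1 = visitation_rates(X, F2, params).V
        assert V1[7, 7] > V0[7, 7]
        others = np.ones_like(F, dtype=bool)
        others[7, 7] = False
        assert np.all(V1[others] <= V0[others] + 1e-12)

    def test_rotation_reflection_symmetry_on_homogeneous_landscape(self, params):
        # centered source on uniform flowers: visits invariant under the
        # symmetries of the square grid
        F = np.ones((21, 21))
        X = np.zeros((21, 21)); X[10, 10] = 4.0
        V = visitation_rates(X, F, params).V
        np.testing.assert_allclose(V, V[::-1, :], atol=1e-12)
        np.testing.assert_allclose(V, V[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        np.testing.assert_allclose(V, np.rot90(V), atol=1e-12)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            visitation_rates(-np.ones((3, 3)), np.ones((3, 3)), params)
        with pytest.raises(ValueError):
            visitation_rates(np.ones((3, 3)), -np.ones((3, 3)), params)

    def test_per_flower_rate(self, params):
        X = np.zeros((3, 3)); X[1, 1] = 6.0
        F = np.zeros((3, 3)); F[1, 1] = 1.0
        cover = np.zeros((3, 3)); cover[1, 1] = 0.5
        vis = visitation_rates(X, F, params, cover=cover)
        # all visits land on the only flower cell: 6 visits / (0.5 * 0.0625 ha)
        assert vis.per_flower[1, 1] == pytest.approx(6.0 / 0.03125, rel=1e-9)
        assert vis.per_flower[0, 0] == 0.0


# ---------------------------------------------------------------- resources
class TestResourcesPerNest:
    def test_uniform_landscape_gives_ratio_times_constant(self, params):
        X = np.full((10, 10), 3.0)
        N = np.full((10, 10), 1.5)
        F = np.full((10, 10), 0.7)
        R = resources_per_nest(X, N, F, params)
        np.testing.assert_allclose(R, 2.0 * 0.7, rtol=1e-9)

    def test_zero_flowers_zero_resources(self, params):
        X = np.ones((5, 5))
        R = resources_per_nest(X, X, np.zeros((5, 5)), params)
        assert np.all(R == 0)

    def test_matches_brute_force_oracle(self, rng):
        params = ModelParams()
        X = rng.integers(0, 8, size=(12, 12)).astype(float)
        N = np.maximum(X, 1.0)
        F = rng.random((12, 12))
        R = resources_per_nest(X, N, F, params)
        R_oracle = brute_force_resources(X, N, F, params, 25.0)
        assert np.max(np.abs(R - R_oracle)) < 1e-10

    def test_foragers_without_nests_rejected(self, params):
        X = np.ones((3, 3))
        N = np.ones((3, 3)); N[0, 0] = 0.0
        with pytest.raises(ValueError, match="without nests"):
            resources_per_nest(X, N, np.ones((3, 3)), params)
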