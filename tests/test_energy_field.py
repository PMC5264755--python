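import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placenav import (
    EnergyField,
    FieldParams,
    NumericInputError,
    WeightDomainError,
    build_arena,
    composite_field,
    field_gradient,
    init_weights,
    isolated_power,
    modulated_power,
    navigation_field,
    nearest_cell,
    power_integral,
    record_transition,
)

PEAK_32PI = 1.0 / (32.0 * math.pi)


class TestIsolatedPower:
    def test_peak_at_center(self, params4):
        assert isolated_power(params4, (5.0, 5.0), (5.0, 5.0)) == pytest.approx(PEAK_32PI)

    @pytest.mark.parametrize("d", [0.1, 1.0, 3.7, 10.0])
    def test_mirror_symmetry(self, params4, d):
        east = isolated_power(params4, (5.0, 5.0), (5.0 + d, 5.0))
        west = isolated_power(params4, (5.0, 5.0), (5.0 - d, 5.0))
        assert east == pytest.approx(west, rel=1e-12)

    def test_monotone_decay_along_rays(self, params4):
        for theta in np.linspace(0.0, 2.0 * math.pi, 9):
            ray = np.array([math.cos(theta), math.sin(theta)])
            values = [
                isolated_power(params4, (5.0, 5.0), (5.0, 5.0) + r * ray)
                for r in np.linspace(0.0, 8.0, 30)
            ]
            assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("sigma", [3.52, 4.00])
    def test_density_normalization(self, sigma):
        params = FieldParams(sigma1=sigma, sigma2=sigma)
        integral = power_integral(params, center=(10.0, 10.0))
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_non_finite_rejected(self, params4):
        with pytest.raises(NumericInputError):
            isolated_power(params4, (0.0, 0.0), (math.inf, 0.0))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(NumericInputError):
            FieldParams(sigma1=-1.0, sigma2=4.0)


class TestKernelFunctionalEquations:
    """The log-power of the 1-D factor satisfies the defining functional
    equations of the squared-exponential: additivity over orthogonal
    displacements and quadratic scaling.  Together with continuity these
    force the Gaussian form, so checking them certifies the kernel."""

    @staticmethod
    def h(sigma, x):
        params = FieldParams(sigma1=sigma, sigma2=sigma)
        center = (0.0, 0.0)
        return math.log(
            isolated_power(params, center, (x, 0.0))
            / isolated_power(params, center, center)
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(-8, 8),
        y=st.floats(-8, 8),
        sigma=st.sampled_from([3.52, 4.0]),
    )
    def test_pythagorean_additivity(self, x, y, sigma):
        lhs = self.h(sigma, x) + self.h(sigma, y)
        rhs = self.h(sigma, math.hypot(x, y))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(-5, 5),
        r=st.floats(-2.5, 2.5),
        sigma=st.sampled_from([3.52, 4.0]),
    )
    def test_quadratic_scaling(self, x, r, sigma):
        assert self.h(sigma, r * x) == pytest.approx(
            r * r * self.h(sigma, x), rel=1e-9, abs=1e-12
        )


class TestModulatedPower:
    def test_zero_weights_reduce_to_isolated(self, params4):
        iso = isolated_power(params4, (5.0, 5.0), (6.0, 7.0))
        assert modulated_power(params4, (5.0, 5.0), (6.0, 7.0), 0.0, 0.0) == iso

    def test_half_weight_sum_at_center(self, params4):
        value = modulated_power(params4, (5.0, 5.0), (5.0, 5.0), 0.5, 0.0)
        assert value == pytest.approx(1.5 * PEAK_32PI)

    def test_linearity_in_synaptic_factor(self, params4):
        base = modulated_power(params4, (5.0, 5.0), (8.0, 3.0), 0.25, 0.25)
        double = modulated_power(params4, (5.0, 5.0), (8.0, 3.0), 1.0, 1.0)
        # synaptic factors 1.5 and 3.0: doubling the factor doubles the power
        assert double == pytest.approx(2.0 * base, rel=1e-12)

    def test_negative_weights_rejected(self, params4):
        with pytest.raises(WeightDomainError):
            modulated_power(params4, (5.0, 5.0), (5.0, 5.0), -0.1, 0.0)


class TestCompositeField:
    def test_zero_weights_target_off_is_single_bump(self, lattice15, params4):
        weights = init_weights(lattice15)
        pos = (7.0, 7.0)
        fld = composite_field(lattice15, params4, weights, pos, (10.0, 10.0), False)
        expected = [
            isolated_power(params4, lattice15.centers[i], pos)
            for i in range(lattice15.n_cells)
        ]
        np.testing.assert_allclose(fld.values, expected, rtol=1e-12)
        assert np.argmax(fld.values) == nearest_cell(lattice15, pos)

    def test_coincident_source_and_target_peak(self, lattice15, params4):
        weights = init_weights(lattice15)
        fld = composite_field(lattice15, params4, weights, (10.0, 10.0), (10.0, 10.0), True)
        peak_cell = nearest_cell(lattice15, (10.0, 10.0))
        assert fld.values[peak_cell] == pytest.approx(2.0 * PEAK_32PI)

    def test_weight_increase_is_local_to_one_cell(self, lattice15, params4):
        pos, tgt = (7.0, 7.0), (10.0, 10.0)
        weights = init_weights(lattice15, learning_increment=1.0)
        before = composite_field(lattice15, params4, weights, pos, tgt, True).values.copy()
        boosted = nearest_cell(lattice15, (8.0, 7.0))
        record_transition(weights, lattice15.neighbors[boosted][0], boosted, 1.0, 1.0)
        after = composite_field(lattice15, params4, weights, pos, tgt, True).values
        assert after[boosted] > before[boosted]
        mask = np.arange(lattice15.n_cells) != boosted
        np.testing.assert_array_equal(after[mask], before[mask])

    def test_all_values_positive_and_finite(self, lattice15, params4):
        weights = init_weights(lattice15)
        fld = composite_field(lattice15, params4, weights, (1.0, 1.0), (15.0, 15.0), True)
        assert np.all(np.isfinite(fld.values)) and np.all(fld.values > 0)


class TestNavigationField:
    def test_equals_composite_minus_unit_packet(self, lattice15, params4):
        weights = init_weights(lattice15, learning_increment=1.0)
        record_transition(weights, 0, 1, 0.5, 0.5)
        pos, tgt = (4.3, 9.1), (10.0, 10.0)
        comp = composite_field(lattice15, params4, weights, pos, tgt, True).values
        nav = navigation_field(lattice15, params4, weights, pos, tgt, True).values
        packet = [
            isolated_power(params4, lattice15.centers[i], pos)
            for i in range(lattice15.n_cells)
        ]
        np.testing.assert_allclose(comp - nav, packet, rtol=1e-12)

    def test_zero_weights_is_pure_target_gaussian(self, lattice15, params4):
        weights = init_weights(lattice15)
        nav = navigation_field(lattice15, params4, weights, (3.0, 3.0), (10.0, 10.0), True)
        expected = [
            isolated_power(params4, lattice15.centers[i], (10.0, 10.0))
            for i in range(lattice15.n_cells)
        ]
        np.testing.assert_allclose(nav.values, expected, rtol=1e-12)


def brute_force_gradient(lattice, values, cell):
    """Independent per-axis two-point estimate on the row/col grid."""
    grid = values.reshape(lattice.grid_rows, lattice.grid_cols)
    r, c = divmod(cell, lattice.grid_cols)
    h = lattice.cell_spacing

    def axis(arr, k):
        if 0 < k < len(arr) - 1:
            return (arr[k + 1] - arr[k - 1]) / (2 * h)
        if k == 0:
            return (arr[1] - arr[0]) / h
        return (arr[-1] - arr[-2]) / h

    return np.array([axis(grid[r, :], c), axis(grid[:, c], r)])


class TestFieldGradient:
    def test_constant_field_has_zero_gradient_everywhere(self, lattice15):
        fld = EnergyField(values=np.full(225, 3.7), source_position=(1, 1),
                          target_position=(10, 10))
        for cell in range(225):
            np.testing.assert_array_equal(field_gradient(lattice15, fld, cell), [0.0, 0.0])

    def test_gradient_points_toward_target_bump(self, lattice15, params4):
        weights = init_weights(lattice15)
        nav = navigation_field(lattice15, params4, weights, (3.0, 10.0), (10.0, 10.0), True)
        west_cell = nearest_cell(lattice15, (5.0, 10.0))
        gx, gy = field_gradient(lattice15, nav, west_cell)
        assert gx > 0
        assert gy == pytest.approx(0.0, abs=1e-15)

    def test_matches_analytic_gradient_within_second_order(self, lattice15):
        # smooth analytic field f = exp(-((x-10)^2 + (y-10)^2) / 32)
        x, y = lattice15.centers[:, 0], lattice15.centers[:, 1]
        f = np.exp(-((x - 10) ** 2 + (y - 10) ** 2) / 32.0)
        fld = EnergyField(values=f, source_position=(10, 10), target_position=(10, 10))
        cell = nearest_cell(lattice15, (5.0, 5.0))
        grad = field_gradient(lattice15, fld, cell)

        def analytic(px, py):
            val = math.exp(-((px - 10) ** 2 + (py - 10) ** 2) / 32.0)
            return np.array([-(px - 10) / 16.0 * val, -(py - 10) / 16.0 * val])

        # central-difference error bound: h^2/6 * max |third derivative|
        def third(u):  # d^3/dx^3 of exp(-(u^2+25)/32) along one axis at offset u
            g = math.exp(-(u ** 2 + 25.0) / 32.0)
            return (-(u ** 3) / 4096.0 + 3.0 * u / 256.0) * g

        m3 = max(abs(third(u)) for u in np.linspace(-6.0, -4.0, 201))
        bound = lattice15.cell_spacing ** 2 / 6.0 * m3
        err = np.abs(grad - analytic(5.0, 5.0))
        assert np.all(err <= bound)

    def test_agrees_with_brute_force_two_point_oracle(self, lattice15, rng):
        values = rng.random(225)
        fld = EnergyField(values=values, source_position=(1, 1), target_position=(10, 10))
        for cell in [0, 7, 14, 112, 210, 224, 15, 29]:
            np.testing.assert_allclose(
                field_gradient(lattice15, fld, cell),
                brute_force_gradient(lattice15, values, cell),
                rtol=1e-12,
            )

    def test_invalid_cell_rejected(self, lattice15):
        fld = EnergyField(values=np.zeros(225), source_position=(1, 1),
                          target_position=(10, 10))
        with pytest.raises(IndexError):
            field_gradient(lattice15, fld, 225)
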