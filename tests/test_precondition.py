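import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import irdecide as ir

GRID = ir.make_grid(2000, 1000, 4)  # 251 points


def gaussian(grid, center, fwhm, amp=1.0):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((grid.values - center) / sigma) ** 2)


class TestBaselineCorrect:
    def test_zero_spectrum(self):
        assert np.allclose(ir.baseline_correct(np.zeros(GRID.count), GRID), 0)

    def test_linear_ramp_removed(self):
        ramp = 0.3 + 0.001 * GRID.values
        assert np.allclose(ir.baseline_correct(ramp, GRID), 0, atol=1e-9)

    def test_gaussian_on_ramp_recovered(self):
        band = gaussian(GRID, 1500, 40, amp=0.8)
        ramp = 0.2 + 2e-4 * GRID.values
        out = ir.baseline_correct(band + ramp, GRID)
        assert np.abs(out - band).max() <= 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = np.abs(rng.normal(size=GRID.count)).cumsum() / 50
            once = ir.baseline_correct(y, GRID)
            assert np.abs(ir.baseline_correct(once, GRID) - once).max() <= 1e-9

    def test_nonfinite_errors(self):
        y = np.zeros(GRID.count)
        y[3] = np.nan
        with pytest.raises(ValueError):
            ir.baseline_correct(y, GRID)

    def test_output_nonnegative_and_zero_at_endpoints(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=GRID.count)
        out = ir.baseline_correct(y, GRID)
        assert out.min() >= -1e-9
        assert abs(out[0]) <= 1e-9 and abs(out[-1]) <= 1e-9


class TestNormalize:
    def test_unit_norm(self):
        y = gaussian(GRID, 1600, 30) + 0.1
        assert np.isclose(np.linalg.norm(ir.normalize(y, GRID)), 1.0)

    def test_scale_invariance(self):
        y = gaussian(GRID, 1600, 30)
        assert np.allclose(ir.normalize(3 * y, GRID), ir.normalize(y, GRID),
                           rtol=1e-14, atol=0)

    def test_three_four_five(self):
        g2 = ir.make_grid(1002, 1000, 2)
        out = ir.normalize(np.array([3.0, 4.0]), g2)
        assert np.allclose(out, [0.6, 0.8])

    def test_area_norm(self):
        y = np.abs(gaussian(GRID, 1500, 50))
        out = ir.normalize(y, GRID, norm="area")
        assert np.isclose(np.sum(np.abs(out)) * GRID.step, 1.0)

    def test_zero_errors(self):
        with pytest.raises(ValueError):
            ir.normalize(np.zeros(GRID.count), GRID)


class TestAmideRatio:
    def test_peak_becomes_one(self):
        y = gaussian(GRID, 1656, 30, amp=0.8)
        out = ir.amide_ratio(y, GRID)
        mask = (GRID.values >= 1600) & (GRID.values <= 1700)
        assert np.isclose(out[mask].max(), 1.0)

    def test_idempotent_after_first(self):
        y = gaussian(GRID, 1656, 30, amp=0.8) + 0.05
        once = ir.amide_ratio(y, GRID)
        assert np.allclose(ir.amide_ratio(once, GRID), once)

    def test_flat_positive_all_ones(self):
        assert np.allclose(ir.amide_ratio(np.full(GRID.count, 0.4), GRID), 1.0)

    def test_nonpositive_peak_errors(self):
        with pytest.raises(ValueError):
            ir.amide_ratio(-np.ones(GRID.count), GRID)


class TestApplyOption:
    def test_raw_is_identity(self):
        rng = np.random.default_rng(0)
        cube = ir.SpectrumCube(GRID, rng.normal(size=(3, 3, GRID.count)), "c1")
        out = ir.apply_option(cube, ir.PreconditionOption("raw"))
        assert np.array_equal(out.data, cube.data)
        assert out.precondition_tag == "raw"

    def test_bc_on_ramp_cube_is_zero(self):
        ramp = 0.1 + 1e-4 * GRID.values
        cube = ir.SpectrumCube(GRID, np.tile(ramp, (2, 2, 1)), "c1")
        out = ir.apply_option(cube, ir.PreconditionOption("bc"))
        assert np.allclose(out.data, 0, atol=1e-9)
        assert out.precondition_tag == "bc"

    def test_bc_norm_removes_thickness(self):
        band = gaussian(GRID, 1650, 40) + gaussian(GRID, 1240, 30, 0.4)
        ramp = 0.2 + 1e-4 * GRID.values
        data = np.stack([[band + ramp, 2 * (band + ramp)]])
        cube = ir.SpectrumCube(GRID, data, "c1")
        out = ir.apply_option(cube, ir.PreconditionOption("bc_norm"))
        assert np.abs(out.data[0, 0] - out.data[0, 1]).max() <= 1e-9

    def test_failing_pixel_excluded_from_labeled(self):
        spectra = np.vstack([gaussian(GRID, 1650, 40), np.zeros(GRID.count)])
        lab = ir.LabeledSpectra(spectra, [1, -1], ["A", "A"], GRID)
        out = ir.apply_option(lab, ir.PreconditionOption("bc_norm"))
        assert out.n == 1 and out.labels.tolist() == [1]


class TestScaler:
    def test_scale_of_mean_is_zero(self, small_labeled):
        sc = ir.fit_scaler(small_labeled)
        z = ir.scale(small_labeled.spectra.mean(axis=0), sc)
        assert np.allclose(z, 0)

    def test_two_point_hand_arithmetic(self):
        g1 = ir.make_grid(1000, 1000, 2)
        lab = ir.LabeledSpectra([[0.0], [2.0]], [-1, 1], ["A", "B"], g1)
        sc = ir.fit_scaler(lab)
        assert sc.mean[0] == 1.0
        assert np.isclose(sc.sd[0], np.sqrt(2))
        z = ir.scale(lab.spectra, sc)
        assert np.allclose(z.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_step_scales_to_zero(self):
        g = ir.make_grid(1004, 1000, 2)
        spectra = np.array([[1.0, 5.0, 2.0], [1.0, 7.0, 3.0]])
        lab = ir.LabeledSpectra(spectra, [1, -1], ["A", "B"], g)
        z = ir.scale(spectra, ir.fit_scaler(lab))
        assert np.allclose(z[:, 0], 0)  # constant channel, sd floor guards
        assert np.all(np.isfinite(z))

    def test_single_row_errors(self):
        g1 = ir.make_grid(1000, 1000, 2)
        lab = ir.LabeledSpectra([[0.0]], [1], ["A"], g1)
        with pytest.raises(ValueError):
            ir.fit_scaler(lab)


class TestSecondDerivative:
    def test_linear_is_zero(self):
        y = 0.5 + 0.01 * GRID.values
        assert np.allclose(ir.second_derivative(y, GRID), 0, atol=1e-9)

    def test_quadratic_exact(self):
        a = 3e-4
        y = a * GRID.values**2
        out = ir.second_derivative(y, GRID, display_scale=-250)
        assert np.allclose(out, 2 * a * -250)

    def test_gaussian_band_center_peak(self):
        y = gaussian(GRID, 1548, 40)
        out = ir.second_derivative(y, GRID)  # x -250 flips sign: max at center
        center_idx = ir.nearest_index(GRID, 1548)
        assert np.argmax(out) == center_idx

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, GRID.count))
        lhs = ir.second_derivative(3 * x - 2 * y, GRID)
        rhs = 3 * ir.second_derivative(x, GRID) - 2 * ir.second_derivative(y, GRID)
        assert np.allclose(lhs, rhs)

    def test_too_short_errors(self):
        g = ir.make_grid(1006, 1000, 2)
        with pytest.raises(ValueError):
            ir.second_derivative(np.zeros(4), g)


@given(
    scale_factor=st.floats(0.1, 10.0),
    slope=st.floats(-1e-3, 1e-3),
    offset=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=25, deadline=None)
def test_bc_norm_invariant_to_scaling_and_linear_baseline(scale_factor, slope, offset, seed):
    """bc_norm output depends only on band shape, not thickness or baseline."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(1100, 1900, size=3)
    y = sum(gaussian(GRID, c, 40, a) for c, a in zip(centers, rng.uniform(0.2, 1, 3)))
    plain = ir.apply_option(
        ir.LabeledSpectra([y], [1], ["A"], GRID), ir.PreconditionOption("bc_norm")
    ).spectra[0]
    dressed_y = scale_factor * y + offset + slope * GRID.values
    dressed = ir.apply_option(
        ir.LabeledSpectra([dressed_y], [1], ["A"], GRID), ir.PreconditionOption("bc_norm")
    ).spectra[0]
    assert np.abs(plain - dressed).max() <= 1e-7
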