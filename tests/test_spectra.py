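"""Spectrum container, file I/O and spectral-algebra behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specresolve import (
    DEFAULT_GRID,
    DerivativeConfig,
    GridError,
    MaskedValueError,
    Spectrum,
    SpectrumParseError,
    WavelengthGrid,
    derivative,
    ratio_spectrum,
    read_spectrum,
    subtract,
    value_at,
    write_spectrum,
)


def spectrum_from(grid, fn):
    return Spectrum(grid, fn(grid.wavelengths))


class TestGrid:
    def test_scan_grid_has_751_points(self, grid):
        assert grid.n_points == 751
        assert grid.wavelengths[0] == 200.0
        assert grid.wavelengths[-1] == pytest.approx(350.0)

    @pytest.mark.parametrize(
        "start,stop,step", [(300, 200, 0.2), (200, 300, -1.0), (200, 300.1, 0.2)]
    )
    def test_invalid_grids_rejected(self, start, stop, step):
        with pytest.raises(GridError):
            WavelengthGrid(start, stop, step)


class TestIO:
    def test_write_read_round_trip(self, tmp_path, grid):
        rng = np.random.default_rng(0)
        s = Spectrum(grid, rng.uniform(0, 2, grid.n_points))
        path = tmp_path / "s.csv"
        write_spectrum(s, path)
        back = read_spectrum(path, grid=grid)
        assert np.max(np.abs(back.values - s.values)) <= 1e-9

    def test_coarse_csv_is_resampled_by_linear_interpolation(self, tmp_path, grid):
        # 1 nm sampling of a line: interpolation must be exact everywhere
        x = np.arange(200.0, 351.0, 1.0)
        y = 0.01 * (x - 200.0)
        path = tmp_path / "coarse.csv"
        np.savetxt(path, np.c_[x, y], delimiter=",", header="wavelength_nm,absorbance")
        s = read_spectrum(path, grid=grid)
        assert s.grid.n_points == 751
        for lam in (210.3, 275.5, 349.9):
            assert value_at(s, lam) == pytest.approx(0.01 * (lam - 200.0), abs=1e-9)

    def test_empty_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SpectrumParseError):
            read_spectrum(path)

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("wavelength_nm,absorbance\n200,0.1\n200,0.2\n201,0.3\n")
        with pytest.raises(SpectrumParseError):
            read_spectrum(path)

    def test_non_numeric_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("200,0.1\n201,oops\n202,0.3\n")
        with pytest.raises(SpectrumParseError):
            read_spectrum(path)

    def test_out_of_range_points_clipped_with_warning(self, tmp_path):
        grid = WavelengthGrid(200.0, 210.0, 1.0)
        x = np.arange(195.0, 216.0, 1.0)
        path = tmp_path / "wide.csv"
        np.savetxt(path, np.c_[x, 0.1 * x], delimiter=",")
        with pytest.warns(UserWarning, match="clipped"):
            s = read_spectrum(path, grid=grid)
        assert s.grid == grid

    def test_jcamp_xydata_matches_csv(self, tmp_path):
        grid = WavelengthGrid(200.0, 204.0, 1.0)
        y = [0.10, 0.20, 0.15, 0.05, 0.00]
        jdx = tmp_path / "s.jdx"
        jdx.write_text(
            "##TITLE=synthetic example\n##JCAMP-DX=4.24\n##XUNITS=NANOMETERS\n"
            "##YUNITS=ABSORBANCE\n##FIRSTX=200\n##LASTX=204\n##NPOINTS=5\n"
            "##XFACTOR=1\n##YFACTOR=0.01\n"
            "##XYDATA=(X++(Y..Y))\n200 10 20 15\n203 5 0\n##END=\n"
        )
        s = read_spectrum(jdx, grid=grid)
        assert np.allclose(s.values, y, atol=1e-12)


class TestAlgebra:
    def test_subtract_self_gives_zero_and_zero_is_identity(self, grid):
        s = spectrum_from(grid, lambda w: np.exp(-((w - 260) ** 2) / 800))
        zero = Spectrum(grid, np.zeros(grid.n_points))
        assert np.allclose(subtract(s, s).values, 0.0)
        assert np.allclose(subtract(s, zero).values, s.values)

    def test_subtract_requires_matching_grids(self, grid):
        other = WavelengthGrid(200.0, 350.0, 0.5)
        with pytest.raises(GridError):
            subtract(
                Spectrum(grid, np.zeros(grid.n_points)),
                Spectrum(other, np.zeros(other.n_points)),
            )

    def test_ratio_of_spectrum_with_itself_is_one(self, grid):
        s = spectrum_from(grid, lambda w: 0.5 + np.exp(-((w - 260) ** 2) / 800))
        rs = ratio_spectrum(s, s)
        assert np.allclose(rs.values[rs.mask], 1.0)

    def test_ratio_reflects_beer_lambert_proportionality(self, grid):
        s = spectrum_from(grid, lambda w: 0.05 + np.exp(-((w - 260) ** 2) / 800))
        rs = ratio_spectrum(2.0 * s, s)
        assert np.allclose(rs.values[rs.mask], 2.0)

    def test_ratio_times_divisor_recovers_numerator(self, grid):
        rng = np.random.default_rng(1)
        num = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        div = Spectrum(grid, rng.uniform(0, 0.5, grid.n_points))
        rs = ratio_spectrum(num, div)
        recon = rs.values[rs.mask] * div.values[rs.mask]
        assert np.max(np.abs(recon - num.values[rs.mask])) <= 1e-9

    def test_weak_divisor_points_are_masked_and_refuse_evaluation(self, grid):
        div = spectrum_from(grid, lambda w: np.exp(-((w - 260) ** 2) / (2 * 15**2)))
        num = spectrum_from(grid, lambda w: np.ones_like(w))
        rs = ratio_spectrum(num, div, guard=0.01)
        assert not rs.mask.all() and rs.mask.any()
        with pytest.raises(MaskedValueError):
            value_at(rs, 200.0)

    def test_divisor_below_guard_everywhere_is_an_error(self, grid):
        tiny = Spectrum(grid, np.full(grid.n_points, 1e-6))
        with pytest.raises(ValueError, match="guard"):
            ratio_spectrum(tiny, tiny, guard=0.01)


class TestDerivative:
    def test_constant_trace_has_zero_derivative(self, grid):
        s = Spectrum(grid, np.full(grid.n_points, 0.7))
        d = derivative(s)
        assert np.all(d.values[d.mask] == 0.0)

    @pytest.mark.parametrize("method", ["central", "savgol"])
    def test_linear_ramp_gives_slope_times_scale(self, grid, method):
        m = 0.004  # AU/nm
        s = spectrum_from(grid, lambda w: m * (w - 200.0))
        cfg = DerivativeConfig(delta_lambda=4.0, scale=10.0, method=method)
        d = derivative(s, cfg)
        for lam in (220.0, 275.0, 330.0):
            assert value_at(d, lam) == pytest.approx(m * 10.0, rel=1e-9)

    def test_gaussian_peak_derivative_crosses_zero_at_centre(self, grid):
        s = spectrum_from(grid, lambda w: np.exp(-((w - 270.0) ** 2) / (2 * 12**2)))
        d = derivative(s)
        assert value_at(d, 270.0) == pytest.approx(0.0, abs=1e-12)
        assert value_at(d, 266.0) > 0 > value_at(d, 274.0)

    def test_edges_within_half_window_are_masked(self, grid):
        d = derivative(Spectrum(grid, np.zeros(grid.n_points)))
        with pytest.raises(MaskedValueError):
            value_at(d, 200.0)
        with pytest.raises(MaskedValueError):
            value_at(d, 349.9)

    def test_unrepresentable_window_is_an_error(self, grid):
        with pytest.raises(GridError):
            derivative(
                Spectrum(grid, np.zeros(grid.n_points)),
                DerivativeConfig(delta_lambda=0.5),
            )

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 2**16)
    )
    def test_derivative_is_linear(self, a, b, seed):
        grid = WavelengthGrid(200.0, 220.0, 0.2)
        rng = np.random.default_rng(seed)
        f = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        g = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        combo = Spectrum(grid, a * f.values + b * g.values)
        lhs = derivative(combo).values
        rhs = a * derivative(f).values + b * derivative(g).values
        mask = derivative(f).mask
        assert np.max(np.abs(lhs[mask] - rhs[mask])) <= 1e-9


class TestValueAt:
    def test_on_grid_returns_stored_value(self, grid):
        s = Spectrum(grid, np.arange(grid.n_points, dtype=float))
        assert value_at(s, 200.0) == 0.0
        assert value_at(s, 200.2) == 1.0

    def test_midpoint_interpolates_linearly(self, grid):
        vals = np.zeros(grid.n_points)
        vals[0], vals[1] = 0.2, 0.4
        s = Spectrum(grid, vals)
        assert value_at(s, 200.1) == pytest.approx(0.3)

    def test_outside_grid_is_an_error(self, grid):
        s = Spectrum(grid, np.zeros(grid.n_points))
        with pytest.raises(GridError):
            value_at(s, 199.0)
        with pytest.raises(GridError):
            value_at(s, 351.0)
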