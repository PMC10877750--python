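"""Ratio-difference and derivative-ratio methods."""

import numpy as np
import pytest

from specresolve import (
    BandModel,
    ComponentModel,
    DerivativeConfig,
    MixtureSpec,
    Spectrum,
    basis_spectrum,
    make_mixture,
)
from specresolve.dw import WavelengthPair, dw_calibrate, dw_predict
from specresolve.published import ASPIRIN_DD, ASPIRIN_RD, ROX_DD, ROX_RD
from specresolve.ratio_methods import (
    DDConfig,
    DivisorSpec,
    RDConfig,
    dd_calibrate,
    dd_candidate_wavelengths,
    dd_predict,
    dd_signal,
    optimize_divisor,
    rd_calibrate,
    rd_predict,
    rd_signal,
)
from specresolve.synthetic import ASP_LABEL, ROX_LABEL


def _rd_cfg(protocol, label):
    return RDConfig(*protocol[label].rd_wavelengths)


def _dd_cfg(protocol, label):
    return DDConfig(protocol[label].dd_wavelength)


class TestRDSignal:
    def test_sample_proportional_to_divisor_gives_zero(self, bases, divisors, protocol):
        sample = 7.0 * bases[ROX_LABEL]  # same shape as the ASP-analyte divisor
        sig = rd_signal(sample, divisors[ASP_LABEL], _rd_cfg(protocol, ASP_LABEL))
        assert abs(sig) < 1e-12

    def test_added_divisor_component_cancels_exactly(
        self, models, divisors, protocol
    ):
        cfg = _rd_cfg(protocol, ASP_LABEL)
        base = make_mixture(models, MixtureSpec({ASP_LABEL: 12.0}))
        s0 = rd_signal(base, divisors[ASP_LABEL], cfg)
        for k in (1.0, 5.0, 20.0):
            mixed = make_mixture(models, MixtureSpec({ASP_LABEL: 12.0, ROX_LABEL: k}))
            assert abs(rd_signal(mixed, divisors[ASP_LABEL], cfg) - s0) < 1e-9

    def test_published_rox_fit_inverts_a_measured_amplitude_difference(self):
        assert ROX_RD.predict(1.5935) == pytest.approx(10.0, abs=1e-9)

    def test_published_asp_fit_is_loadable_with_reported_coefficients(self):
        assert ASPIRIN_RD.slope == 0.0221
        assert ASPIRIN_RD.intercept == -0.0099
        assert ASPIRIN_RD.divisor_concentration == 20.0


class TestRDCalibrate:
    def test_noise_free_calibration_perfectly_linear(self, standards, divisors, protocol):
        cal = rd_calibrate(
            standards[ROX_LABEL], divisors[ROX_LABEL], _rd_cfg(protocol, ROX_LABEL)
        )
        assert abs(cal.r) >= 1 - 1e-12

    def test_doubling_divisor_concentration_halves_slope(
        self, standards, bases, protocol, grid
    ):
        cfg = _rd_cfg(protocol, ASP_LABEL)
        div1 = DivisorSpec(ROX_LABEL, 20.0, Spectrum(grid, 20.0 * bases[ROX_LABEL].values))
        div2 = DivisorSpec(ROX_LABEL, 40.0, Spectrum(grid, 40.0 * bases[ROX_LABEL].values))
        cal1 = rd_calibrate(standards[ASP_LABEL], div1, cfg)
        cal2 = rd_calibrate(standards[ASP_LABEL], div2, cfg)
        assert cal2.slope == pytest.approx(cal1.slope / 2, rel=1e-9)


class TestDDSignal:
    def test_divisor_component_alone_gives_zero_derivative(
        self, bases, divisors, protocol
    ):
        sample = 15.0 * bases[ASP_LABEL]  # pure divisor component of the ROX assay
        sig = dd_signal(sample, divisors[ROX_LABEL], _dd_cfg(protocol, ROX_LABEL))
        assert abs(sig) < 1e-9

    def test_published_asp_fit_inverts_a_measured_amplitude(self):
        assert ASPIRIN_DD.predict(-0.2783) == pytest.approx(10.0, abs=1e-9)

    def test_published_rox_fit_inverts_a_measured_amplitude(self):
        assert ROX_DD.predict(5.2227) == pytest.approx(10.0, abs=1e-9)

    def test_matches_analytic_ratio_derivative_to_second_order(self, grid):
        """The windowed central difference converges to the analytic
        derivative of the ratio trace at O(delta_lambda^2)."""
        a = ComponentModel("a", (BandModel(250.0, 14.0, 0.04),))
        d = ComponentModel("d", (BandModel(262.0, 20.0, 0.03),))
        sample = 10.0 * basis_spectrum(a, grid)
        divisor = DivisorSpec("d", 8.0, 8.0 * basis_spectrum(d, grid))

        lam = 248.0
        def ratio(l):
            fa = 10 * 0.04 * np.exp(-0.5 * ((l - 250) / 14) ** 2)
            fd = 8 * 0.03 * np.exp(-0.5 * ((l - 262) / 20) ** 2)
            return fa / fd
        h = 1e-5
        analytic = 10.0 * (ratio(lam + h) - ratio(lam - h)) / (2 * h)

        errors = []
        for dl in (4.0, 2.0, 0.8):
            cfg = DDConfig(lam, DerivativeConfig(delta_lambda=dl, scale=10.0))
            errors.append(abs(dd_signal(sample, divisor, cfg) - analytic))
        assert errors[0] < 1e-2 * abs(analytic)
        # quartering of the error under halving of the window
        assert errors[1] < errors[0] / 3
        assert errors[2] < errors[1] / 3


class TestDDCandidates:
    def test_gaussian_over_flat_divisor_has_exactly_two_extrema(self, grid):
        analyte = ComponentModel("a", (BandModel(270.0, 15.0, 0.05),))
        flat = DivisorSpec("flat", 1.0, Spectrum(grid, np.ones(grid.n_points)))
        standards = [
            (c, c * basis_spectrum(analyte, grid)) for c in (4.0, 8.0, 16.0)
        ]
        cands = dd_candidate_wavelengths(standards, flat, DDConfig(270.0))
        assert len(cands) == 2
        # derivative of a Gaussian peaks at centre -/+ sigma
        assert sorted(round(c.wavelength) for c in cands) == [255, 285]

    def test_analyte_proportional_to_divisor_yields_no_extrema(self, grid):
        shape = ComponentModel("s", (BandModel(260.0, 18.0, 0.05),))
        basis = basis_spectrum(shape, grid)
        div = DivisorSpec("s", 10.0, 10.0 * basis)
        standards = [(c, c * basis) for c in (4.0, 8.0, 16.0)]
        assert dd_candidate_wavelengths(standards, div, DDConfig(260.0)) == []

    def test_first_candidate_has_largest_slope_among_qualifying(
        self, standards, divisors, protocol
    ):
        cands = dd_candidate_wavelengths(
            standards[ROX_LABEL], divisors[ROX_LABEL], _dd_cfg(protocol, ROX_LABEL)
        )
        qual = [c for c in cands if c.qualifies]
        assert qual and abs(qual[0].slope) == max(abs(c.slope) for c in qual)


class TestOptimizeDivisor:
    def test_identical_candidates_tie_break_to_the_first(
        self, standards, divisors, protocol
    ):
        div = divisors[ASP_LABEL]
        best, diags = optimize_divisor(
            standards[ASP_LABEL], [div, div], "rd", _rd_cfg(protocol, ASP_LABEL)
        )
        assert best is div
        assert all(d.error is None for d in diags)

    def test_noise_free_tie_break_prefers_lowest_concentration_divisor(
        self, standards, bases, protocol, grid
    ):
        # slope scales as 1/divisor level, so the most dilute divisor is
        # the most sensitive; with zero LOO RSD everywhere it must win
        cands = [
            DivisorSpec(ROX_LABEL, c, Spectrum(grid, c * bases[ROX_LABEL].values))
            for c in (40.0, 20.0, 10.0)
        ]
        best, diags = optimize_divisor(
            standards[ASP_LABEL], cands, "rd", _rd_cfg(protocol, ASP_LABEL)
        )
        assert best.concentration == 10.0
        assert max(d.loo_rsd for d in diags) < 1e-6

    def test_near_zero_divisor_is_rejected_but_run_continues(
        self, standards, divisors, protocol, grid
    ):
        dead = DivisorSpec(ROX_LABEL, 1.0, Spectrum(grid, np.full(grid.n_points, 1e-6)))
        best, diags = optimize_divisor(
            standards[ASP_LABEL],
            [dead, divisors[ASP_LABEL]],
            "rd",
            _rd_cfg(protocol, ASP_LABEL),
        )
        assert best is divisors[ASP_LABEL]
        assert diags[0].error is not None


class TestMethodAgreement:
    def test_three_methods_agree_with_truth_on_noise_free_mixtures(
        self, models, standards, divisors, protocol
    ):
        """DW, RD and 1DD all recover truth within 0.5% across a 5x5 grid
        of noise-free binary mixtures."""
        cals = {}
        for label, p in protocol.items():
            cals[(label, "dw")] = dw_calibrate(standards[label], WavelengthPair(*p.dw_pair))
            cals[(label, "rd")] = rd_calibrate(
                standards[label], divisors[label], RDConfig(*p.rd_wavelengths)
            )
            cals[(label, "dd")] = dd_calibrate(
                standards[label], divisors[label], DDConfig(p.dd_wavelength)
            )
        for ca in (4.0, 8.0, 16.0, 24.0, 40.0):
            for cr in (2.0, 4.0, 8.0, 12.0, 20.0):
                mix = make_mixture(models, MixtureSpec({ASP_LABEL: ca, ROX_LABEL: cr}))
                for label, truth in ((ASP_LABEL, ca), (ROX_LABEL, cr)):
                    preds = (
                        dw_predict(mix, cals[(label, "dw")]),
                        rd_predict(mix, divisors[label], cals[(label, "rd")]),
                        dd_predict(mix, divisors[label], cals[(label, "dd")]),
                    )
                    for pred in preds:
                        assert pred == pytest.approx(truth, rel=5e-3)
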