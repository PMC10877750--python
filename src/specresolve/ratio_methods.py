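"""Ratio-difference (RD) and first-derivative-of-ratio (1DD) methods.

Both start from the ratio spectrum of a mixture against a standard spectrum
of the interfering component (the divisor): the interferent then
contributes only a wavelength-independent constant.  RD cancels that
constant by differencing the ratio amplitudes at two wavelengths — any two
in the linear range, which is the method's advantage over dual-wavelength.
1DD cancels it by differentiating the ratio spectrum, creating new peak
and trough signals proportional to the analyte alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .calibration import MethodCalibration, calibration_from_fit, fit_signals
from .spectra import (
    DerivativeConfig,
    MaskedValueError,
    Spectrum,
    derivative,
    ratio_spectrum,
    value_at,
)
from .validation import fit_line, precision_rsd, recovery_percent

DEFAULT_GUARD = 0.01


@dataclass(frozen=True)
class DivisorSpec:
    """The standard spectrum used as ratio denominator, at a known level."""

    component_label: str
    concentration: float
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("divisor concentration must be positive")


@dataclass(frozen=True)
class RDConfig:
    """Ratio-difference measurement wavelengths, in signal order.

    The signal is P(lambda_plus) - P(lambda_minus); storing the order
    explicitly keeps persisted calibrations unambiguous about sign.
    """

    lambda_plus: float
    lambda_minus: float
    guard: float = DEFAULT_GUARD

    def __post_init__(self) -> None:
        if self.lambda_plus == self.lambda_minus:
            raise ValueError("the two measurement wavelengths must differ")


@dataclass(frozen=True)
class DDConfig:
    """Derivative-ratio measurement settings."""

    measurement_wavelength: float
    derivative: DerivativeConfig = DerivativeConfig()
    guard: float = DEFAULT_GUARD


def _ratio(sample: Spectrum, divisor: DivisorSpec, guard: float):
    return ratio_spectrum(sample, divisor.spectrum, guard=guard)


def rd_signal(sample: Spectrum, divisor: DivisorSpec, cfg: RDConfig) -> float:
    """Amplitude difference delta P of the ratio spectrum.

    Raises MaskedValueError if either wavelength falls where the divisor is
    below the guard.
    """
    rs = _ratio(sample, divisor, cfg.guard)
    return value_at(rs, cfg.lambda_plus) - value_at(rs, cfg.lambda_minus)


def rd_calibrate(
    standards: Sequence[tuple[float, Spectrum]],
    divisor: DivisorSpec,
    cfg: RDConfig,
    analyte: str = "",
) -> MethodCalibration:
    signals = [(conc, rd_signal(s, divisor, cfg)) for conc, s in standards]
    fit = fit_signals(signals)
    return calibration_from_fit(
        fit,
        method="rd",
        analyte=analyte or standards[0][1].label,
        wavelengths=(cfg.lambda_plus, cfg.lambda_minus),
        divisor_label=divisor.component_label,
        divisor_concentration=divisor.concentration,
    )


def rd_predict(sample: Spectrum, divisor: DivisorSpec, cal: MethodCalibration) -> float:
    if cal.method != "rd":
        raise ValueError(f"expected an rd calibration, got {cal.method!r}")
    cfg = RDConfig(*cal.wavelengths)
    return cal.predict(rd_signal(sample, divisor, cfg))


def dd_signal(sample: Spectrum, divisor: DivisorSpec, cfg: DDConfig) -> float:
    """First-derivative-of-ratio amplitude P at the measurement wavelength."""
    trace = derivative(_ratio(sample, divisor, cfg.guard), cfg.derivative)
    return value_at(trace, cfg.measurement_wavelength)


def dd_calibrate(
    standards: Sequence[tuple[float, Spectrum]],
    divisor: DivisorSpec,
    cfg: DDConfig,
    analyte: str = "",
) -> MethodCalibration:
    signals = [(conc, dd_signal(s, divisor, cfg)) for conc, s in standards]
    fit = fit_signals(signals)
    return calibration_from_fit(
        fit,
        method="dd",
        analyte=analyte or standards[0][1].label,
        wavelengths=(cfg.measurement_wavelength,),
        divisor_label=divisor.component_label,
        divisor_concentration=divisor.concentration,
        delta_lambda=cfg.derivative.delta_lambda,
        scale=cfg.derivative.scale,
    )


def dd_predict(sample: Spectrum, divisor: DivisorSpec, cal: MethodCalibration) -> float:
    if cal.method != "dd":
        raise ValueError(f"expected a dd calibration, got {cal.method!r}")
    cfg = DDConfig(
        measurement_wavelength=cal.wavelengths[0],
        derivative=DerivativeConfig(
            delta_lambda=cal.delta_lambda or 4.0, scale=cal.scale or 10.0
        ),
    )
    return cal.predict(dd_signal(sample, divisor, cfg))


@dataclass(frozen=True)
class DDCandidate:
    wavelength: float
    slope: float
    r: float
    qualifies: bool


def dd_candidate_wavelengths(
    standards: Sequence[tuple[float, Spectrum]],
    divisor: DivisorSpec,
    cfg: DDConfig,
    min_r: float = 0.999,
    prominence: float = 1e-4,
) -> list[DDCandidate]:
    """Ranked peak/trough wavelengths of the mean derivative-ratio trace.

    Extrema are detected on the mean trace over the standards (sign change
    of the discrete first difference, minimum prominence to suppress noise
    wiggles).  Each extremum gets a per-wavelength calibration |slope| and
    r; candidates with |r| >= min_r are ranked first by |slope| descending,
    the rest follow in the same order.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration levels")
    traces = [
        derivative(_ratio(s, divisor, cfg.guard), cfg.derivative)
        for _, s in standards
    ]
    mask = np.logical_and.reduce([t.mask for t in traces])
    if not np.any(mask):
        return []
    mean_trace = np.mean([t.values for t in traces], axis=0)
    search = np.where(mask, mean_trace, 0.0)
    peaks, _ = find_peaks(search, prominence=prominence)
    troughs, _ = find_peaks(-search, prominence=prominence)
    grid = standards[0][1].grid
    concs = np.array([c for c, _ in standards])
    out: list[DDCandidate] = []
    for i in np.concatenate([peaks, troughs]):
        if not mask[i]:
            continue
        signals = np.array([t.values[i] for t in traces])
        fit = fit_line(concs, signals)
        out.append(
            DDCandidate(
                wavelength=float(grid.wavelengths[i]),
                slope=fit.slope,
                r=fit.r,
                qualifies=abs(fit.r) >= min_r,
            )
        )
    out.sort(key=lambda c: (not c.qualifies, -abs(c.slope)))
    return out


@dataclass(frozen=True)
class DivisorDiagnostics:
    divisor: DivisorSpec
    loo_rsd: float
    slope: float
    r: float
    error: str | None = None


def optimize_divisor(
    standards: Sequence[tuple[float, Spectrum]],
    divisor_candidates: Sequence[DivisorSpec],
    method: str,
    cfg: "RDConfig | DDConfig",
    rsd_tie_tolerance: float = 1e-6,
) -> tuple[DivisorSpec, list[DivisorDiagnostics]]:
    """Pick the divisor balancing noise and sensitivity.

    For each candidate the standards are re-predicted leave-one-out and the
    RSD% of the recoveries is taken as the noise figure; the candidate with
    the smallest RSD wins, ties (within `rsd_tie_tolerance`) broken by
    larger calibration |slope|, then by input order.  Candidates that fail
    (masked measurement wavelength, degenerate calibration) are recorded
    with their error and skipped.
    """
    if len(divisor_candidates) < 2:
        raise ValueError("need at least 2 divisor candidates")
    if method == "rd":
        signal = lambda s, div: rd_signal(s, div, cfg)  # noqa: E731
    elif method == "dd":
        signal = lambda s, div: dd_signal(s, div, cfg)  # noqa: E731
    else:
        raise ValueError(f"method must be 'rd' or 'dd', got {method!r}")

    diags: list[DivisorDiagnostics] = []
    for div in divisor_candidates:
        try:
            sig = [(c, signal(s, div)) for c, s in standards]
            full = fit_signals(sig)
            recoveries = []
            for i, (c_true, _) in enumerate(sig):
                rest = sig[:i] + sig[i + 1:]
                fit = fit_signals(rest)
                pred = (sig[i][1] - fit.intercept) / fit.slope
                recoveries.append(recovery_percent(pred, c_true))
            rsd = precision_rsd(recoveries)
            diags.append(
                DivisorDiagnostics(divisor=div, loo_rsd=rsd, slope=full.slope, r=full.r)
            )
        except (MaskedValueError, ValueError, ZeroDivisionError) as exc:
            diags.append(
                DivisorDiagnostics(
                    divisor=div,
                    loo_rsd=float("inf"),
                    slope=float("nan"),
                    r=float("nan"),
                    error=str(exc),
                )
            )
    usable = [d for d in diags if d.error is None]
    if not usable:
        raise ValueError("every divisor candidate failed calibration")
    best_rsd = min(d.loo_rsd for d in usable)
    tied = [d for d in usable if d.loo_rsd <= best_rsd + rsd_tie_tolerance]
    best = max(tied, key=lambda d: abs(d.slope))
    return best.divisor, diags
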