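"""Dual-wavelength (DW) method.

One analyte of a binary mixture is quantified from the absorbance
difference between two wavelengths chosen so that the interfering
component's difference is negligible while the analyte's difference is
large and linear in concentration.  The method works directly on
zero-order spectra — no transformation at all — which is its main appeal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import MethodCalibration, calibration_from_fit, fit_signals
from .spectra import Spectrum, value_at


@dataclass(frozen=True)
class WavelengthPair:
    """An ordered measurement pair; the signal is A(high) - A(low)."""

    lambda_low: float
    lambda_high: float

    def __post_init__(self) -> None:
        if not (self.lambda_low < self.lambda_high):
            raise ValueError("lambda_low must be below lambda_high")


@dataclass(frozen=True)
class PairSearchConfig:
    """What counts as a usable dual-wavelength pair.

    `interferent_tolerance` quantifies "negligible": the largest |delta A|
    the interferent may show at its top calibration level.  Pairs closer
    than `min_separation` nm are pruned; the search window defaults to the
    whole grid.
    """

    interferent_tolerance: float = 0.002
    min_analyte_signal: float = 0.0
    window: tuple[float, float] | None = None
    min_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.interferent_tolerance <= 0:
            raise ValueError("interferent_tolerance must be positive")


@dataclass(frozen=True)
class PairCandidate:
    pair: WavelengthPair
    analyte_delta: float
    interferent_delta: float


def delta_A(s: Spectrum, pair: WavelengthPair) -> float:
    """Absorbance difference A(lambda_high) - A(lambda_low)."""
    return value_at(s, pair.lambda_high) - value_at(s, pair.lambda_low)


def select_pair(
    analyte_set: Sequence[tuple[float, Spectrum]],
    interferent_top: Spectrum,
    cfg: PairSearchConfig = PairSearchConfig(),
    max_pairs: int | None = None,
) -> list[PairCandidate]:
    """Exhaustive ranked search for qualifying wavelength pairs.

    A pair qualifies when the interferent's |delta A| at its top level is
    within tolerance and the analyte's |delta A| at its top calibration
    level meets the minimum signal.  Qualifying pairs are ranked by analyte
    |delta A| descending; ties break by smaller interferent |delta A|, then
    by lower lambda_low.  An empty list is a valid outcome.
    """
    if not analyte_set:
        raise ValueError("analyte calibration set is empty")
    top_conc, top_spectrum = max(analyte_set, key=lambda cs: cs[0])
    grid = top_spectrum.grid
    if interferent_top.grid != grid:
        raise ValueError("analyte and interferent spectra are on different grids")

    wl = grid.wavelengths
    if cfg.window is not None:
        lo, hi = cfg.window
        keep = (wl >= lo) & (wl <= hi)
    else:
        keep = np.ones_like(wl, dtype=bool)
    idx = np.nonzero(keep)[0]
    w = wl[idx]
    a = top_spectrum.values[idx]
    b = interferent_top.values[idx]

    # all ordered pairs (j < k) at least min_separation apart
    jj, kk = np.triu_indices(w.size, k=1)
    sep_ok = (w[kk] - w[jj]) >= cfg.min_separation - 1e-9
    jj, kk = jj[sep_ok], kk[sep_ok]
    d_int = b[kk] - b[jj]
    d_ana = a[kk] - a[jj]
    ok = (np.abs(d_int) <= cfg.interferent_tolerance) & (
        np.abs(d_ana) >= cfg.min_analyte_signal
    )
    jj, kk, d_int, d_ana = jj[ok], kk[ok], d_int[ok], d_ana[ok]

    order = np.lexsort((w[jj], np.abs(d_int), -np.abs(d_ana)))
    if max_pairs is not None:
        order = order[:max_pairs]
    return [
        PairCandidate(
            pair=WavelengthPair(float(w[jj[i]]), float(w[kk[i]])),
            analyte_delta=float(d_ana[i]),
            interferent_delta=float(d_int[i]),
        )
        for i in order
    ]


def dw_calibrate(
    standards: Sequence[tuple[float, Spectrum]],
    pair: WavelengthPair,
    analyte: str = "",
) -> MethodCalibration:
    """OLS of delta A on concentration over the calibration standards."""
    signals = [(conc, delta_A(s, pair)) for conc, s in standards]
    fit = fit_signals(signals)
    return calibration_from_fit(
        fit,
        method="dw",
        analyte=analyte or standards[0][1].label,
        wavelengths=(pair.lambda_low, pair.lambda_high),
    )


def dw_predict(sample: Spectrum, cal: MethodCalibration) -> float:
    """Concentration of the calibrated analyte in `sample` (ug/mL)."""
    if cal.method != "dw":
        raise ValueError(f"expected a dw calibration, got {cal.method!r}")
    pair = WavelengthPair(*cal.wavelengths)
    return cal.predict(delta_A(sample, pair))
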