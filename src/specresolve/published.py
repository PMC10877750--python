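"""Published aspirin (ASP) / rivaroxaban (ROX) calibrations, as fixed constants.

The original method development reported one regression equation per
method and analyte, measured in methanol on 200-350 nm scans:

* dual wavelength — ASP: delta A(255.5, 242.5) = 0.0054 C + 0.001;
  ROX: delta A(286, 252) = 0.0291 C + 0.0003
* ratio difference — ASP (divisor 20 ug/mL ROX, 234 & 280 nm):
  delta P = 0.0221 C - 0.0099; ROX (divisor 36 ug/mL ASP, 254 & 297 nm):
  delta P = 0.1444 C + 0.1495
* derivative ratio (delta lambda 4 nm, scale 10) — ASP at 238.5 nm:
  P = -0.0306 C + 0.0277; ROX at 293 nm: P = 0.5056 C + 0.1667

These are usable as fixed calibrations for predicting concentrations from
measured signals; the r values and residual statistics are reported
metadata only (residual SD was not published and is stored as NaN).
"""

from __future__ import annotations

from .calibration import MethodCalibration

_NAN = float("nan")

ASPIRIN_DW = MethodCalibration(
    method="dw",
    analyte="ASP",
    wavelengths=(242.5, 255.5),
    slope=0.0054,
    intercept=0.001,
    r=0.9997,
    residual_sd=_NAN,
    n=7,
)

ROX_DW = MethodCalibration(
    method="dw",
    analyte="ROX",
    wavelengths=(252.0, 286.0),
    slope=0.0291,
    intercept=0.0003,
    r=0.9995,
    residual_sd=_NAN,
    n=6,
)

ASPIRIN_RD = MethodCalibration(
    method="rd",
    analyte="ASP",
    wavelengths=(234.0, 280.0),
    slope=0.0221,
    intercept=-0.0099,
    r=0.9997,
    residual_sd=_NAN,
    n=7,
    divisor_label="ROX",
    divisor_concentration=20.0,
)

ROX_RD = MethodCalibration(
    method="rd",
    analyte="ROX",
    wavelengths=(297.0, 254.0),
    slope=0.1444,
    intercept=0.1495,
    r=0.9998,
    residual_sd=_NAN,
    n=6,
    divisor_label="ASP",
    divisor_concentration=36.0,
)

ASPIRIN_DD = MethodCalibration(
    method="dd",
    analyte="ASP",
    wavelengths=(238.5,),
    slope=-0.0306,
    intercept=0.0277,
    r=0.9999,
    residual_sd=_NAN,
    n=7,
    divisor_label="ROX",
    divisor_concentration=20.0,
    delta_lambda=4.0,
    scale=10.0,
)

ROX_DD = MethodCalibration(
    method="dd",
    analyte="ROX",
    wavelengths=(293.0,),
    slope=0.5056,
    intercept=0.1667,
    r=0.9998,
    residual_sd=_NAN,
    n=6,
    divisor_label="ASP",
    divisor_concentration=36.0,
    delta_lambda=4.0,
    scale=10.0,
)

PUBLISHED_CALIBRATIONS = {
    ("ASP", "dw"): ASPIRIN_DW,
    ("ASP", "rd"): ASPIRIN_RD,
    ("ASP", "dd"): ASPIRIN_DD,
    ("ROX", "dw"): ROX_DW,
    ("ROX", "rd"): ROX_RD,
    ("ROX", "dd"): ROX_DD,
}

# Published validation summaries (recovery %) used for method comparison:
# mean, variance and n of each method series and of the official/reported
# comparators, for aspirin and rivaroxaban respectively.
PUBLISHED_SUMMARIES = {
    "ASP": {
        "dw": {"mean": 100.26, "variance": 1.00, "n": 10},
        "rd": {"mean": 100.11, "variance": 1.11, "n": 10},
        "dd": {"mean": 99.70, "variance": 0.79, "n": 10},
        "official": {"mean": 100.22, "variance": 0.90, "n": 10},
    },
    "ROX": {
        "dw": {"mean": 100.06, "variance": 0.94, "n": 8},
        "rd": {"mean": 100.24, "variance": 0.47, "n": 8},
        "dd": {"mean": 99.67, "variance": 0.49, "n": 8},
        "reported": {"mean": 100.48, "variance": 0.84, "n": 6},
    },
}
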