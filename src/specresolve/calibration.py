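"""Fitted method calibrations and their plain-text persistence."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .validation import LinearFit, fit_line

METHODS = ("dw", "rd", "dd")


@dataclass(frozen=True)
class MethodCalibration:
    """A fitted calibration line tied to one method's measurement settings.

    `wavelengths` holds the method's measurement wavelengths in signal
    order: (lambda_low, lambda_high) for dual-wavelength, (lambda_plus,
    lambda_minus) for ratio-difference, and a single wavelength for the
    derivative-ratio method.  Ratio methods also record their divisor;
    the derivative method its window and scale.
    """

    method: str
    analyte: str
    wavelengths: tuple[float, ...]
    slope: float
    intercept: float
    r: float
    residual_sd: float
    n: int
    divisor_label: str | None = None
    divisor_concentration: float | None = None
    delta_lambda: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))

    def predict(self, signal: float) -> float:
        """Concentration from a measured signal: C = (signal - b) / m."""
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (signal - self.intercept) / self.slope


def calibration_from_fit(
    fit: LinearFit,
    method: str,
    analyte: str,
    wavelengths: Sequence[float],
    **extra,
) -> MethodCalibration:
    return MethodCalibration(
        method=method,
        analyte=analyte,
        wavelengths=tuple(wavelengths),
        slope=fit.slope,
        intercept=fit.intercept,
        r=fit.r,
        residual_sd=fit.residual_sd,
        n=fit.n,
        **extra,
    )


def fit_signals(
    standards_signals: Sequence[tuple[float, float]],
) -> LinearFit:
    """OLS of signal on concentration for (concentration, signal) pairs.

    Requires >= 3 distinct concentration levels.
    """
    if len(standards_signals) < 3:
        raise ValueError("need at least 3 calibration levels")
    concs = [c for c, _ in standards_signals]
    if len(set(concs)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    sigs = [s for _, s in standards_signals]
    return fit_line(concs, sigs)


# -- persistence: plain-text key = value, one per line ----------------------

_FLOAT_FIELDS = ("slope", "intercept", "r", "residual_sd")
_OPT_FLOAT_FIELDS = ("divisor_concentration", "delta_lambda", "scale")


def save_calibration(cal: MethodCalibration, path: str | Path) -> None:
    lines = [
        f"method = {cal.method}",
        f"analyte = {cal.analyte}",
        "wavelengths = " + ", ".join(f"{w:g}" for w in cal.wavelengths),
    ]
    for name in _FLOAT_FIELDS:
        lines.append(f"{name} = {getattr(cal, name)!r}")
    lines.append(f"n = {cal.n}")
    if cal.divisor_label is not None:
        lines.append(f"divisor_label = {cal.divisor_label}")
    for name in _OPT_FLOAT_FIELDS:
        val = getattr(cal, name)
        if val is not None:
            lines.append(f"{name} = {val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path: str | Path) -> MethodCalibration:
    fields: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        fields[key.strip()] = val.strip()
    try:
        kwargs = dict(
            method=fields["method"],
            analyte=fields["analyte"],
            wavelengths=tuple(
                float(w) for w in fields["wavelengths"].split(",") if w.strip()
            ),
            n=int(fields["n"]),
            **{name: float(fields[name]) for name in _FLOAT_FIELDS},
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing calibration field {exc}") from exc
    if "divisor_label" in fields:
        kwargs["divisor_label"] = fields["divisor_label"]
    for name in _OPT_FLOAT_FIELDS:
        if name in fields:
            kwargs[name] = float(fields[name])
    return MethodCalibration(**kwargs)
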