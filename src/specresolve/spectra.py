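"""Spectrum containers and the spectral algebra every resolution method builds on.

Wavelengths are in nanometres (nm), absorbances in absorbance units (AU).
All spectra live on a uniform, closed wavelength grid — the convention of a
scanning double-beam instrument — and every operation (difference, ratio,
windowed derivative, interpolation) assumes that grid.  Files whose sampling
differs are resampled by linear interpolation on read.

Ratio spectra and derivative traces carry a per-point validity mask: points
where the divisor falls below a guard threshold, or that sit within the
derivative window of a grid edge, are flagged invalid and refuse point
evaluation rather than returning amplified noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


class GridError(ValueError):
    """Wavelength off the grid, or two grids that should match do not."""


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed."""


class MaskedValueError(ValueError):
    """A value was requested at a wavelength flagged invalid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform closed wavelength grid [start, stop] with fixed step (nm)."""

    start: float
    stop: float
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise GridError(f"start ({self.start}) must be < stop ({self.stop})")
        if self.step <= 0:
            raise GridError(f"step must be positive, got {self.step}")
        span = (self.stop - self.start) / self.step
        if abs(span - round(span)) > 1e-6:
            raise GridError(
                f"grid span {self.stop - self.start} nm is not an integral "
                f"multiple of step {self.step} nm"
            )

    @property
    def n_points(self) -> int:
        return round((self.stop - self.start) / self.step) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def position(self, wavelength: float) -> float:
        """Fractional index of `wavelength` on the grid; GridError outside."""
        if wavelength < self.start - 1e-9 or wavelength > self.stop + 1e-9:
            raise GridError(
                f"{wavelength} nm outside grid [{self.start}, {self.stop}]"
            )
        return (wavelength - self.start) / self.step

    def index_of(self, wavelength: float, tol: float = 1e-6) -> int:
        """Integer index of an on-grid wavelength; GridError if off-grid."""
        pos = self.position(wavelength)
        idx = round(pos)
        if abs(pos - idx) > tol:
            raise GridError(f"{wavelength} nm is not a grid point")
        return int(idx)


#: The scan grid of the study protocol: 200-350 nm at 0.2 nm intervals.
DEFAULT_GRID = WavelengthGrid(200.0, 350.0, 0.2)


def _as_array(values: Sequence[float], n: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{what} must be a 1-D sequence of {n} values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A zero-order absorption spectrum A(lambda) on a uniform grid.

    `concentration` (ug/mL) and `solvent` are optional metadata used by
    calibration bookkeeping; they do not affect the spectral algebra.
    """

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""
    concentration: float | None = None
    solvent: str | None = None

    def __post_init__(self) -> None:
        arr = _as_array(self.values, self.grid.n_points, "absorbance")
        if not np.all(np.isfinite(arr)):
            raise ValueError("absorbance values must all be finite")
        object.__setattr__(self, "values", arr)

    # -- arithmetic (convenience; grids must match exactly) ----------------
    def _check_grid(self, other: "Spectrum") -> None:
        if self.grid != other.grid:
            raise GridError("spectra are on different wavelength grids")

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return Spectrum(self.grid, self.values + other.values, label=self.label)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return Spectrum(self.grid, self.values - other.values, label=self.label)

    def __mul__(self, k: float) -> "Spectrum":
        return Spectrum(self.grid, self.values * float(k), label=self.label)

    __rmul__ = __mul__

    def value_at(self, wavelength: float) -> float:
        return value_at(self, wavelength)


@dataclass(frozen=True)
class Trace:
    """A spectrum-shaped trace with a per-point validity mask.

    Used for derivative traces; `mask` is True where the point is valid.
    """

    grid: WavelengthGrid
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        vals = _as_array(self.values, self.grid.n_points, "values")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != vals.shape:
            raise ValueError("mask and values must have the same length")
        if not np.all(np.isfinite(vals[mask])):
            raise ValueError("valid trace points must be finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)

    def value_at(self, wavelength: float) -> float:
        return value_at(self, wavelength)


@dataclass(frozen=True)
class RatioSpectrum(Trace):
    """A sample spectrum divided pointwise by a divisor standard spectrum.

    The divisor's own component contributes a wavelength-independent
    constant to the amplitude; that constant is what the ratio-difference
    and derivative-ratio methods cancel.
    """

    divisor_label: str = ""
    divisor_concentration: float = float("nan")


SpectrumLike = Union[Spectrum, Trace]


def _values_and_mask(obj: SpectrumLike) -> tuple[WavelengthGrid, np.ndarray, np.ndarray]:
    if isinstance(obj, Trace):
        return obj.grid, obj.values, obj.mask
    if isinstance(obj, Spectrum):
        return obj.grid, obj.values, np.ones(obj.grid.n_points, dtype=bool)
    raise TypeError(f"expected Spectrum or Trace, got {type(obj).__name__}")


def value_at(obj: SpectrumLike, wavelength: float) -> float:
    """Amplitude at `wavelength`, linearly interpolated if off-grid.

    Raises GridError outside the grid and MaskedValueError if the point (or
    either interpolation neighbour) is flagged invalid.
    """
    grid, values, mask = _values_and_mask(obj)
    pos = grid.position(wavelength)
    lo = int(math.floor(pos))
    hi = min(int(math.ceil(pos)), grid.n_points - 1)
    if abs(pos - round(pos)) < 1e-6:
        idx = int(round(pos))
        if not mask[idx]:
            raise MaskedValueError(f"{wavelength} nm lies in a masked region")
        return float(values[idx])
    if not (mask[lo] and mask[hi]):
        raise MaskedValueError(f"{wavelength} nm lies in a masked region")
    frac = pos - lo
    return float(values[lo] * (1.0 - frac) + values[hi] * frac)


def subtract(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a - b (e.g. blank/baseline correction). Grids must match."""
    return a - b


def ratio_spectrum(
    numerator: Spectrum,
    divisor: Spectrum,
    guard: float = 0.01,
) -> RatioSpectrum:
    """Divide `numerator` by `divisor` pointwise, masking weak-divisor points.

    Points where the divisor absorbance falls below `guard` (AU) are flagged
    invalid: dividing by a vanishing absorbance only amplifies noise.

    Raises GridError on mismatched grids and ValueError if the divisor is
    below the guard everywhere.
    """
    if numerator.grid != divisor.grid:
        raise GridError("numerator and divisor are on different grids")
    valid = np.abs(divisor.values) >= guard
    if not np.any(valid):
        raise ValueError(
            f"divisor absorbance is below the guard ({guard} AU) everywhere"
        )
    amp = np.zeros_like(numerator.values)
    amp[valid] = numerator.values[valid] / divisor.values[valid]
    return RatioSpectrum(
        grid=numerator.grid,
        values=amp,
        mask=valid,
        divisor_label=divisor.label,
        divisor_concentration=(
            divisor.concentration if divisor.concentration is not None else float("nan")
        ),
    )


@dataclass(frozen=True)
class DerivativeConfig:
    """Window and scaling of the first-derivative operator.

    delta_lambda is the full derivative window in nm (a positive even
    multiple of the grid step); scale is the conventional instrument-software
    multiplier applied to the derivative amplitude.  `method` selects the
    operator: "central" (difference over the window) or "savgol"
    (Savitzky-Golay, quadratic, first derivative over the same window).
    """

    delta_lambda: float = 4.0
    scale: float = 10.0
    method: str = "central"

    def __post_init__(self) -> None:
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.method not in ("central", "savgol"):
            raise ValueError(f"unknown derivative method {self.method!r}")

    def half_window_points(self, grid: WavelengthGrid) -> int:
        """Half-window in grid points; errors if not representable."""
        half = self.delta_lambda / 2.0 / grid.step
        if abs(half - round(half)) > 1e-6 or round(half) < 1:
            raise GridError(
                f"delta_lambda={self.delta_lambda} nm is not a positive even "
                f"multiple of the grid step ({grid.step} nm)"
            )
        return int(round(half))


def derivative(obj: SpectrumLike, cfg: DerivativeConfig = DerivativeConfig()) -> Trace:
    """First-derivative trace of a spectrum or ratio spectrum.

    Central form: D(lambda) = scale * [A(lambda + dl/2) - A(lambda - dl/2)] / dl
    with dl = cfg.delta_lambda.  Points within dl/2 of the grid ends are
    flagged invalid, and invalid input points propagate through the window.
    """
    grid, values, mask = _values_and_mask(obj)
    k = cfg.half_window_points(grid)
    n = grid.n_points
    out = np.zeros(n)
    out_mask = np.zeros(n, dtype=bool)
    if cfg.method == "central":
        out[k:n - k] = (
            cfg.scale * (values[2 * k:] - values[: n - 2 * k]) / cfg.delta_lambda
        )
        out_mask[k:n - k] = mask[2 * k:] & mask[: n - 2 * k]
    else:  # savgol
        window = 2 * k + 1
        sg = savgol_filter(
            values, window_length=window, polyorder=2, deriv=1, delta=grid.step
        )
        out[k:n - k] = cfg.scale * sg[k:n - k]
        # a point is valid only if its whole fit window is valid
        ok = np.convolve(mask.astype(int), np.ones(window, dtype=int), "same") == window
        out_mask[k:n - k] = ok[k:n - k]
    # invalid wherever the input centre point itself is invalid
    out_mask &= mask
    out[~out_mask] = 0.0
    return Trace(grid=grid, values=out, mask=out_mask)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("wavelength_nm", "absorbance")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV (`wavelength_nm,absorbance`)."""
    df = pd.DataFrame(
        {CSV_COLUMNS[0]: spectrum.grid.wavelengths, CSV_COLUMNS[1]: spectrum.values}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def _read_two_column_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise SpectrumParseError(f"{path}: empty spectrum file") from exc
    if df.shape[1] != 2:
        raise SpectrumParseError(
            f"{path}: expected 2 columns (wavelength, absorbance), got {df.shape[1]}"
        )
    # optional single header line
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise SpectrumParseError(f"{path}: no data rows")
    try:
        x = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
        y = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectrumParseError(f"{path}: non-numeric data row") from exc
    return x, y


def _read_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: ##XYDATA=(X++(Y..Y)) blocks in AFFN form."""
    header: dict[str, str] = {}
    ys: list[float] = []
    in_xy = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                if val.replace(" ", "") != "(X++(Y..Y))":
                    raise SpectrumParseError(
                        f"{path}: unsupported XYDATA form {val!r}"
                    )
                in_xy = True
            elif key == "END":
                in_xy = False
            else:
                header[key] = val
            continue
        if in_xy:
            parts = line.replace(",", " ").split()
            try:
                nums = [float(p) for p in parts]
            except ValueError as exc:
                raise SpectrumParseError(f"{path}: bad XYDATA line {line!r}") from exc
            ys.extend(nums[1:])  # first number on each line is the X start
    if not ys:
        raise SpectrumParseError(f"{path}: no XYDATA found")
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
    except KeyError as exc:
        raise SpectrumParseError(f"{path}: missing FIRSTX/LASTX") from exc
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    npoints = int(header.get("NPOINTS", len(ys)))
    if npoints != len(ys):
        raise SpectrumParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} Y values read"
        )
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys) * yfactor
    return x, y


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    grid: WavelengthGrid | None = None,
    label: str = "",
    concentration: float | None = None,
) -> Spectrum:
    """Read a spectrum from CSV or JCAMP-DX.

    The format is inferred from the extension (.jdx/.dx/.jcamp vs anything
    else) unless given explicitly.  With `grid` supplied the data are
    resampled onto it by linear interpolation; wavelengths outside the grid
    are clipped with a warning.  Without `grid`, the file's own (uniform)
    sampling defines the grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "csv":
        x, y = _read_two_column_csv(path)
    elif format in ("jcamp-dx", "jcamp", "jdx"):
        x, y = _read_jcamp(path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        raise SpectrumParseError(f"{path}: duplicate wavelengths")

    if grid is None:
        steps = np.diff(x)
        step = float(np.median(steps))
        if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1e-6):
            raise SpectrumParseError(
                f"{path}: non-uniform wavelength spacing; pass an explicit grid"
            )
        grid = WavelengthGrid(float(x[0]), float(x[-1]), step)
        values = y
    else:
        inside = (x >= grid.start - 1e-9) & (x <= grid.stop + 1e-9)
        if not np.all(inside):
            warnings.warn(
                f"{path}: {np.count_nonzero(~inside)} points outside "
                f"[{grid.start}, {grid.stop}] nm were clipped",
                UserWarning,
                stacklevel=2,
            )
            x, y = x[inside], y[inside]
        if x.size < 2:
            raise SpectrumParseError(f"{path}: fewer than 2 points inside the grid")
        if x[0] > grid.start + 1e-9 or x[-1] < grid.stop - 1e-9:
            raise SpectrumParseError(
                f"{path}: data [{x[0]}, {x[-1]}] nm do not cover the grid "
                f"[{grid.start}, {grid.stop}] nm"
            )
        values = np.interp(grid.wavelengths, x, y)
    return Spectrum(
        grid=grid, values=values, label=label, concentration=concentration
    )
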