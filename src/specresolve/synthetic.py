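"""Synthetic UV absorption spectra for a severely overlapped binary mixture.

The generator emulates the structure the resolution methods assume: two
components whose bands overlap heavily in the 220-280 nm region, one of
which ("ROX-like") keeps absorbing past 290 nm while the other ("ASP-like")
is spectroscopically silent there.  Components are sums of Gaussian bands;
mixtures obey Beer-Lambert additivity with optional homoscedastic Gaussian
noise and an optional broad plasma-like baseline.

These spectra are structural stand-ins: no attempt is made to reproduce the
true molar absorptivities of aspirin or rivaroxaban.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

ASP_LABEL = "ASP-like"
ROX_LABEL = "ROX-like"


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: height * exp(-(l-center)^2 / (2 width^2)).

    `height` is the response per unit concentration (AU mL/ug) at the band
    centre; `width` is the Gaussian sigma in nm.
    """

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.height < 0:
            raise ValueError("band height must be non-negative")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.center) / self.width
        return self.height * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class ComponentModel:
    """A component's unit-concentration absorptivity profile (sum of bands)."""

    label: str
    bands: tuple[BandModel, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("a component needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class MixtureSpec:
    """Concentrations plus the nuisance terms of one simulated scan."""

    concentrations: Mapping[str, float]
    noise_sd: float = 0.0
    baseline: ComponentModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def basis_spectrum(model: ComponentModel, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Unit-concentration response of a component on `grid`."""
    wl = grid.wavelengths
    values = np.zeros_like(wl)
    for band in model.bands:
        if not (grid.start <= band.center <= grid.stop):
            raise ValueError(
                f"band centre {band.center} nm outside grid "
                f"[{grid.start}, {grid.stop}]"
            )
        values += band.evaluate(wl)
    return Spectrum(grid=grid, values=values, label=model.label, concentration=1.0)


def make_mixture(
    components: Mapping[str, ComponentModel],
    spec: MixtureSpec,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Spectrum:
    """Beer-Lambert mixture A = sum_i c_i basis_i + baseline + noise.

    The baseline (if any) is added at unit strength; noise is additive
    Gaussian with SD `spec.noise_sd` AU, reproducible under `spec.seed`.
    """
    values = np.zeros(grid.n_points)
    labels = []
    for label, conc in spec.concentrations.items():
        if label not in components:
            raise KeyError(f"no component model for label {label!r}")
        values += conc * basis_spectrum(components[label], grid).values
        if conc > 0:
            labels.append(label)
    if spec.baseline is not None:
        values += basis_spectrum(spec.baseline, grid).values
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values += rng.normal(0.0, spec.noise_sd, grid.n_points)
    return Spectrum(grid=grid, values=values, label="+".join(labels) or "blank")


def relative_noise_sd(
    components: Mapping[str, ComponentModel],
    concentrations: Mapping[str, float],
    fraction: float = 0.01,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> float:
    """Noise SD equal to `fraction` of a sample's peak absorbance.

    "x% relative noise" for a simulated sample is defined against the
    noise-free spectrum's maximum absorbance; the noise itself stays
    additive and homoscedastic across the scan.
    """
    clean = make_mixture(
        components, MixtureSpec(concentrations=dict(concentrations)), grid
    )
    return fraction * float(np.max(np.abs(clean.values)))


def default_models() -> dict[str, ComponentModel]:
    """The two default overlapped components.

    Band parameters were tuned once so that:

    * both components absorb strongly and simultaneously in the 230-270 nm
      overlap region,
    * the ASP-like component is dark past ~290 nm (< 0.005 AU at 293 nm even
      at its 40 ug/mL top standard) while the ROX-like one still absorbs
      there (> 0.01 AU at 293 nm at its 2 ug/mL bottom standard),
    * dual-wavelength pairs with a silent interferent exist for each analyte
      (the ROX-like main band is symmetric about 249 nm, so mirrored pairs
      about 249 nm cancel it exactly), and
    * the two shapes are far from proportional, so ratio spectra carry
      usable structure.
    """
    asp = ComponentModel(
        label=ASP_LABEL,
        bands=(
            BandModel(center=228.0, width=6.0, height=0.050),
            BandModel(center=269.0, width=8.0, height=0.009),
        ),
    )
    rox = ComponentModel(
        label=ROX_LABEL,
        bands=(
            BandModel(center=249.0, width=12.0, height=0.015),
            BandModel(center=297.0, width=10.0, height=0.050),
        ),
    )
    return {ASP_LABEL: asp, ROX_LABEL: rox}


def plasma_baseline() -> ComponentModel:
    """A broad short-wavelength blank-plasma-like baseline.

    Decays to a few mAU by ~290 nm, so red-side measurement wavelengths see
    essentially no matrix contribution; blank subtraction removes the rest.
    """
    return ComponentModel(
        label="plasma-baseline",
        bands=(BandModel(center=210.0, width=28.0, height=0.35),),
    )


def make_calibration_set(
    components: Mapping[str, ComponentModel],
    label: str,
    levels: Sequence[float],
    noise_sd: float = 0.0,
    baseline: ComponentModel | None = None,
    seed: int | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> list[tuple[float, Spectrum]]:
    """Single-component standards at the given concentration levels.

    Each level gets an independent noise realisation; the whole set is
    reproducible under `seed`.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("at least one calibration level is required")
    if any(c <= 0 for c in levels):
        raise ValueError("calibration levels must be positive")
    if len(set(levels)) != len(levels):
        raise ValueError("calibration levels must be distinct")
    if label not in components:
        raise KeyError(f"no component model for label {label!r}")
    seeds = np.random.SeedSequence(seed).generate_state(len(levels)) % (2**31)
    out = []
    for level, sub_seed in zip(levels, seeds):
        spec = MixtureSpec(
            concentrations={label: level},
            noise_sd=noise_sd,
            baseline=baseline,
            seed=int(sub_seed),
        )
        s = make_mixture(components, spec, grid)
        out.append((level, replace(s, concentration=float(level), label=label)))
    return out


# Calibration ranges of the study protocol (ug/mL).
DEFAULT_LEVELS: dict[str, tuple[float, ...]] = {
    ASP_LABEL: (4.0, 8.0, 12.0, 16.0, 24.0, 32.0, 40.0),
    ROX_LABEL: (2.0, 4.0, 8.0, 12.0, 16.0, 20.0),
}

# Divisor concentrations of the study protocol: each analyte's ratio spectra
# use the other component's standard as the divisor.
DEFAULT_DIVISOR_CONCENTRATIONS: dict[str, tuple[str, float]] = {
    ASP_LABEL: (ROX_LABEL, 20.0),
    ROX_LABEL: (ASP_LABEL, 36.0),
}


@dataclass(frozen=True)
class AnalyteProtocol:
    """Frozen measurement wavelengths for one analyte of the default models.

    These are properties of the synthetic system, selected once on
    noise-free default-model spectra — dual-wavelength pairs from the
    package's own pair search, ratio wavelengths by balancing sensitivity
    against divisor-noise amplification (the classic divisor trade-off) —
    and then fixed, the way an analyst fixes method wavelengths during
    development.
    """

    analyte: str
    dw_pair: tuple[float, float]          # (lambda_low, lambda_high)
    rd_wavelengths: tuple[float, float]   # (lambda_plus, lambda_minus)
    dd_wavelength: float
    divisor_label: str
    divisor_concentration: float


def default_protocol() -> dict[str, AnalyteProtocol]:
    """Measurement protocol for the two default components."""
    return {
        ASP_LABEL: AnalyteProtocol(
            analyte=ASP_LABEL,
            dw_pair=(228.0, 320.4),
            rd_wavelengths=(228.0, 297.0),
            dd_wavelength=232.0,
            divisor_label=ROX_LABEL,
            divisor_concentration=20.0,
        ),
        ROX_LABEL: AnalyteProtocol(
            analyte=ROX_LABEL,
            dw_pair=(305.0, 345.0),
            rd_wavelengths=(289.0, 223.0),
            dd_wavelength=288.0,
            divisor_label=ASP_LABEL,
            divisor_concentration=36.0,
        ),
    }
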