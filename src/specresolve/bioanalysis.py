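"""Plasma-protocol arithmetic and matrix-interference checks.

The bioanalytical workflow spikes drug-free plasma with a standard mixture,
deproteinates with methanol, and dilutes the filtrate; each step is a pure
volume ratio, so the final concentration is the initial one times the
product of aliquot/total ratios.  Centrifugation and filtration move no
analyte mass and are volume-neutral no-ops in this model.

Matrix interference is assessed the way an analyst does it: compute each
method's signal on the blank-plasma spectrum and on the top calibration
standard, and require the blank/top ratio to stay below a threshold at
every measurement wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .spectra import Spectrum


@dataclass(frozen=True)
class DilutionChain:
    """Ordered (aliquot mL, final volume mL) steps applied to a stock."""

    initial_concentration: float
    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError("initial concentration must be non-negative")
        steps = tuple((float(a), float(t)) for a, t in self.steps)
        for aliquot, total in steps:
            if aliquot <= 0 or total <= 0:
                raise ValueError("volumes must be positive")
            if aliquot > total:
                raise ValueError(
                    f"aliquot {aliquot} mL exceeds its step's total volume {total} mL"
                )
        object.__setattr__(self, "steps", steps)


def final_concentration(chain: DilutionChain) -> float:
    """Concentration after the whole chain: c0 * prod(aliquot/total)."""
    c = chain.initial_concentration
    for aliquot, total in chain.steps:
        c *= aliquot / total
    return c


# The study's plasma protocol: 4 mL of spiking mixture enters a tube already
# holding 0.5 mL plasma and receives 0.5 mL methanol (5 mL intermediate
# volume — the only arithmetic consistent with the protocol's final
# concentrations), then 2 mL of filtrate is made up to 10 mL.
PLASMA_PROTOCOL_STEPS: tuple[tuple[float, float], ...] = ((4.0, 5.0), (2.0, 10.0))


def plasma_chain(initial_concentration: float) -> DilutionChain:
    """The study's spike-deproteinate-dilute chain for a given stock level."""
    return DilutionChain(
        initial_concentration=initial_concentration, steps=PLASMA_PROTOCOL_STEPS
    )


@dataclass(frozen=True)
class SignalProbe:
    """One method signal to evaluate on blank and top-standard spectra."""

    name: str
    wavelength: float
    compute: Callable[[Spectrum], float]


@dataclass(frozen=True)
class InterferenceReport:
    name: str
    wavelength: float
    blank_signal: float
    top_standard_signal: float
    ratio: float
    passed: bool


def interference_check(
    blank: Spectrum,
    top_standard: Spectrum,
    probes: Sequence[SignalProbe],
    threshold: float = 0.02,
) -> tuple[list[InterferenceReport], bool]:
    """Blank-versus-top-standard signal ratios for each method probe.

    Passes overall when every |blank| / |top standard| ratio is within
    `threshold`.  A zero top-standard signal is an error: the ratio would
    be meaningless.
    """
    if blank.grid != top_standard.grid:
        raise ValueError("blank and top standard are on different grids")
    reports = []
    for probe in probes:
        b = probe.compute(blank)
        t = probe.compute(top_standard)
        if t == 0:
            raise ZeroDivisionError(
                f"top-standard signal for {probe.name!r} is zero"
            )
        ratio = abs(b) / abs(t)
        reports.append(
            InterferenceReport(
                name=probe.name,
                wavelength=probe.wavelength,
                blank_signal=b,
                top_standard_signal=t,
                ratio=ratio,
                passed=ratio <= threshold,
            )
        )
    return reports, all(r.passed for r in reports)
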