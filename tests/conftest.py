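import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specresolve import (
    DEFAULT_GRID,
    Spectrum,
    basis_spectrum,
    default_models,
    default_protocol,
)
from specresolve.ratio_methods import DivisorSpec
from specresolve.synthetic import ASP_LABEL, DEFAULT_LEVELS, ROX_LABEL, make_calibration_set

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def bases(models, grid):
    return {label: basis_spectrum(m, grid) for label, m in models.items()}


@pytest.fixture(scope="session")
def standards(models, grid):
    """Noise-free calibration sets for both components."""
    return {
        label: make_calibration_set(models, label, DEFAULT_LEVELS[label], grid=grid)
        for label in (ASP_LABEL, ROX_LABEL)
    }


@pytest.fixture(scope="session")
def divisors(bases, protocol, grid):
    """Protocol divisor standards (noise-free stored spectra)."""
    out = {}
    for label, p in protocol.items():
        base = bases[p.divisor_label]
        out[label] = DivisorSpec(
            p.divisor_label,
            p.divisor_concentration,
            Spectrum(
                grid,
                base.values * p.divisor_concentration,
                label=p.divisor_label,
                concentration=p.divisor_concentration,
            ),
        )
    return out
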