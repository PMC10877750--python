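"""End-to-end simulate -> calibrate -> predict -> validate runs.

A run is described by a plain YAML/dict configuration; every tolerance,
wavelength and seed is surfaced there so method-development choices are
user-overridable.  Outputs are CSV tables plus a run log recording the
seed, a configuration hash and the package version, so a run is exactly
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .calibration import MethodCalibration, save_calibration
from .dw import WavelengthPair, dw_calibrate, dw_predict
from .ratio_methods import (
    DDConfig,
    DivisorSpec,
    RDConfig,
    dd_calibrate,
    dd_predict,
    rd_calibrate,
    rd_predict,
)
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid
from .synthetic import (
    DEFAULT_LEVELS,
    MixtureSpec,
    basis_spectrum,
    default_models,
    default_protocol,
    make_calibration_set,
    make_mixture,
    relative_noise_sd,
)
from .validation import LinearFit, lod_loq, precision_rsd, recovery_percent

VALID_METHODS = ("dw", "rd", "dd")


def default_config() -> dict[str, Any]:
    """The demo configuration: noise-free default models, all methods."""
    proto = default_protocol()
    return {
        "seed": 0,
        "grid": {"start": 200.0, "stop": 350.0, "step": 0.2},
        "methods": list(VALID_METHODS),
        "noise_fraction": 0.0,
        "levels": {label: list(DEFAULT_LEVELS[label]) for label in DEFAULT_LEVELS},
        "samples": {
            label: [float(lv) for lv in DEFAULT_LEVELS[label][1:4]]
            for label in DEFAULT_LEVELS
        },
        "protocol": {
            label: {
                "dw_pair": list(p.dw_pair),
                "rd_wavelengths": list(p.rd_wavelengths),
                "dd_wavelength": p.dd_wavelength,
                "divisor_label": p.divisor_label,
                "divisor_concentration": p.divisor_concentration,
            }
            for label, p in proto.items()
        },
    }


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    predictions: pd.DataFrame
    validation: pd.DataFrame
    seed: int
    config_hash: str
    version: str


class PipelineError(RuntimeError):
    """Raised with a stage-tagged message when a pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> RunReport:
    """Execute simulate -> calibrate -> predict -> validate.

    With `outdir` given, writes predictions.csv, validation_report.csv,
    one calibration file per analyte/method, and run_log.txt.
    """
    cfg = default_config()
    cfg.update({k: v for k, v in config.items()})
    methods = list(cfg["methods"])
    if any(m not in VALID_METHODS for m in methods):
        raise PipelineError("config", f"methods must be among {VALID_METHODS}")
    seed = int(cfg["seed"])
    g = cfg["grid"]
    grid = WavelengthGrid(float(g["start"]), float(g["stop"]), float(g["step"]))
    noise_fraction = float(cfg["noise_fraction"])

    # -- simulate ---------------------------------------------------------
    try:
        models = default_models()
        standards = {
            label: make_calibration_set(
                models, label, cfg["levels"][label], grid=grid
            )
            for label in cfg["levels"]
        }
        divisors = {}
        for label, p in cfg["protocol"].items():
            basis = basis_spectrum(models[p["divisor_label"]], grid)
            spec = Spectrum(
                grid,
                basis.values * float(p["divisor_concentration"]),
                label=p["divisor_label"],
                concentration=float(p["divisor_concentration"]),
            )
            divisors[label] = DivisorSpec(
                p["divisor_label"], float(p["divisor_concentration"]), spec
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # -- calibrate --------------------------------------------------------
    cals: dict[tuple[str, str], MethodCalibration] = {}
    try:
        for label, p in cfg["protocol"].items():
            std = standards[label]
            if "dw" in methods:
                cals[(label, "dw")] = dw_calibrate(
                    std, WavelengthPair(*p["dw_pair"]), analyte=label
                )
            if "rd" in methods:
                cals[(label, "rd")] = rd_calibrate(
                    std, divisors[label], RDConfig(*p["rd_wavelengths"]), analyte=label
                )
            if "dd" in methods:
                cals[(label, "dd")] = dd_calibrate(
                    std, divisors[label], DDConfig(float(p["dd_wavelength"])), analyte=label
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("calibrate", str(exc)) from exc

    # -- predict ----------------------------------------------------------
    rows = []
    try:
        seeds = iter(
            np.random.SeedSequence(seed).generate_state(
                sum(len(v) for v in cfg["samples"].values()) or 1
            )
            % (2**31)
        )
        for label, levels in cfg["samples"].items():
            for level in levels:
                level = float(level)
                nsd = (
                    relative_noise_sd(models, {label: level}, noise_fraction, grid)
                    if noise_fraction > 0
                    else 0.0
                )
                mix = make_mixture(
                    models,
                    MixtureSpec(
                        {label: level}, noise_sd=nsd, seed=int(next(seeds))
                    ),
                    grid,
                )
                for method in methods:
                    cal = cals[(label, method)]
                    if method == "dw":
                        pred = dw_predict(mix, cal)
                    elif method == "rd":
                        pred = rd_predict(mix, divisors[label], cal)
                    else:
                        pred = dd_predict(mix, divisors[label], cal)
                    rows.append(
                        {
                            "analyte": label,
                            "method": method,
                            "true_ug_per_ml": level,
                            "predicted_ug_per_ml": pred,
                            "recovery_percent": recovery_percent(pred, level),
                        }
                    )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("predict", str(exc)) from exc
    predictions = pd.DataFrame(rows)

    # -- validate ---------------------------------------------------------
    vrows = []
    try:
        for (label, method), cal in sorted(cals.items()):
            lod, loq = lod_loq(
                LinearFit(
                    slope=cal.slope,
                    intercept=cal.intercept,
                    r=cal.r,
                    residual_sd=cal.residual_sd,
                    n=cal.n,
                ),
            )
            sub = predictions[
                (predictions.analyte == label) & (predictions.method == method)
            ]
            recs = sub.recovery_percent.to_numpy()
            vrows.append(
                {
                    "analyte": label,
                    "method": method,
                    "slope": cal.slope,
                    "intercept": cal.intercept,
                    "r": cal.r,
                    "residual_sd": cal.residual_sd,
                    "lod_ug_per_ml": lod,
                    "loq_ug_per_ml": loq,
                    "mean_recovery_percent": float(np.mean(recs)),
                    "recovery_rsd_percent": (
                        precision_rsd(recs) if len(recs) >= 2 else float("nan")
                    ),
                }
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validate", str(exc)) from exc
    validation = pd.DataFrame(vrows)

    chash = config_hash(cfg)
    report = RunReport(
        predictions=predictions,
        validation=validation,
        seed=seed,
        config_hash=chash,
        version=__version__,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(outdir / "predictions.csv", index=False, float_format="%.10g")
        validation.to_csv(
            outdir / "validation_report.csv", index=False, float_format="%.10g"
        )
        for (label, method), cal in sorted(cals.items()):
            save_calibration(cal, outdir / f"calibration_{label}_{method}.txt")
        (outdir / "run_log.txt").write_text(
            f"specresolve version = {__version__}\n"
            f"seed = {seed}\n"
            f"config_hash = {chash}\n"
        )
    return report
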