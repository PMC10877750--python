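"""Composite solvent sustainability score.

The GSK solvent-sustainability framework summarises a solvent by four
sub-scores — health (H), safety (S), environment (E), waste (W), each on a
0-10 scale with 10 greenest — and combines them as the geometric mean
G = (H * S * E * W)^(1/4).  Sub-scores are user-supplied external data;
this module only composes them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SolventScores:
    """H, S, E, W sub-scores; the GSK scale is 0-10 (10 greenest).

    Only positivity is enforced — the geometric mean is well defined for
    any positive inputs.
    """

    H: float
    S: float
    E: float
    W: float

    def __post_init__(self) -> None:
        for name in ("H", "S", "E", "W"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"sub-score {name} must be positive, got {v}")


def g_score(scores: SolventScores) -> float:
    """Fourth root of H*S*E*W; always between min and max of the inputs."""
    return (scores.H * scores.S * scores.E * scores.W) ** 0.25


#: Published composite G scores of the candidate solvents of the assay
#: (reference constants from the GSK solvent guide, not recomputed here).
REFERENCE_G = {"ethanol": 6.6, "DMSO": 6.4, "methanol": 5.8}
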