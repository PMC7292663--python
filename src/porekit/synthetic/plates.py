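"""Synthetic dual-channel cytotoxicity plates.

Each condition has a programmed true percent death.  The per-well
cytotoxicity/viability ratio is linear in the death fraction between a
minimum- and a maximum-death anchor, so min/max-control normalization
recovers the programmed value exactly at zero noise.  Well-to-well noise is
a multiplicative Gaussian CV applied once to the ratio (the standard reason
for running a ratiometric dual-channel assay is that common-mode channel
noise cancels; what remains is well-level variability).  Channel gains then
split the ratio into realistic cytotoxicity and viability signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PlateSimConfig", "gen_cytotox_plate"]


@dataclass
class PlateSimConfig:
    """Programmed plate layout: conditions, controls, gains and noise."""

    conditions: dict[str, float] = field(
        default_factory=lambda: {"G0": 5.0, "G1": 20.0, "G2": 25.0}
    )  # condition label -> true percent death
    wells_per_condition: int = 6
    n_min_control_wells: int = 6
    n_max_control_wells: int = 6
    ratio_at_min_death: float = 0.05
    ratio_at_max_death: float = 0.95
    viability_gain: float = 40000.0
    cytotox_gain: float = 1.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for label, death in self.conditions.items():
            if not 0.0 <= death <= 100.0:
                raise ValueError(f"true percent death for {label!r} outside [0, 100]")
        if self.n_min_control_wells < 1 or self.n_max_control_wells < 1:
            raise ValueError("need at least one min-death and one max-death control well")
        if self.ratio_at_max_death <= self.ratio_at_min_death:
            raise ValueError("max-death ratio anchor must exceed min-death anchor")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.wells_per_condition < 1:
            raise ValueError("wells_per_condition must be >= 1")


def gen_cytotox_plate(cfg: PlateSimConfig) -> pd.DataFrame:
    """Simulate one plate as a tidy well table.

    Columns: well, condition, cytotox, viability, control_role.  Min-death
    control wells sit at 0% death and max-death controls at 100% by
    construction; identical configs give identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    r_lo, r_hi = cfg.ratio_at_min_death, cfg.ratio_at_max_death

    layout: list[tuple[str, float, str]] = []
    layout += [("min_death_control", 0.0, "min_death")] * cfg.n_min_control_wells
    layout += [("max_death_control", 100.0, "max_death")] * cfg.n_max_control_wells
    for label, death in cfg.conditions.items():
        layout += [(label, death, "none")] * cfg.wells_per_condition

    rows = []
    for i, (label, death, role) in enumerate(layout):
        d = death / 100.0
        ratio = r_lo + d * (r_hi - r_lo)
        if cfg.noise_cv > 0:
            ratio = max(ratio * (1.0 + rng.normal(0.0, cfg.noise_cv)), 1e-9)
        viability = cfg.viability_gain * (1.0 - 0.8 * d)
        cytotox = cfg.cytotox_gain * ratio * viability
        rows.append(
            {
                "well": f"W{i:03d}",
                "condition": label,
                "cytotox": cytotox,
                "viability": viability,
                "control_role": role,
            }
        )
    return pd.DataFrame(rows)
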