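"""Plate-level cytotoxicity normalization and multiple-testing correction.

Percent cell death is computed from per-well cytotoxicity/viability ratios
(or raw cytotoxicity for an LDH-only assay) normalized between the plate's
minimum-death and maximum-death control wells.  Ion-replacement rescue is
the fractional reduction of percent death relative to a baseline condition.
Benjamini-Hochberg FDR adjustment is provided for downstream imaging
comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["percent_death", "rescue_effect", "bh_adjust", "PLATE_COLUMNS"]

#: expected columns of a plate table (viability optional in LDH-only mode)
PLATE_COLUMNS = ["well", "condition", "cytotox", "viability", "control_role"]


def _well_ratios(plate: pd.DataFrame, ldh_only: bool) -> pd.Series:
    if ldh_only:
        return plate["cytotox"].astype(float)
    if "viability" not in plate.columns or plate["viability"].isna().any():
        raise ValueError(
            "dual-channel mode needs a complete 'viability' column; "
            "pass ldh_only=True for a cytotoxicity-only assay"
        )
    return plate["cytotox"].astype(float) / plate["viability"].astype(float)


def percent_death(plate: pd.DataFrame, ldh_only: bool = False) -> pd.DataFrame:
    """Per-condition percent cell death from min/max-control normalization.

    Per well, R = cytotox/viability (or raw cytotox in LDH-only mode), then
    ``percent = 100 * (R - mean R_min) / (mean R_max - mean R_min)``.
    Values outside [0, 100] (possible with noisy controls) are reported and
    flagged via ``out_of_range``, never clipped.
    """
    for col in ("well", "condition", "cytotox", "control_role"):
        if col not in plate.columns:
            raise ValueError(f"plate table lacks required column {col!r}")
    roles = plate["control_role"].fillna("none")
    min_mask = roles == "min_death"
    max_mask = roles == "max_death"
    if not min_mask.any() or not max_mask.any():
        raise ValueError("plate needs at least one min_death and one max_death well")

    ratio = _well_ratios(plate, ldh_only)
    r_min = float(ratio[min_mask].mean())
    r_max = float(ratio[max_mask].mean())
    if r_max <= r_min:
        raise ValueError(
            f"degenerate controls: mean max-death ratio ({r_max:.4g}) must exceed "
            f"mean min-death ratio ({r_min:.4g})"
        )
    pct = 100.0 * (ratio - r_min) / (r_max - r_min)

    rows = []
    for cond, grp_idx in plate.groupby("condition", sort=True).groups.items():
        vals = pct.loc[grp_idx].to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "n_wells": int(vals.size),
                "percent_death": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "out_of_range": bool(np.any((vals < 0) | (vals > 100))),
            }
        )
    return pd.DataFrame(rows)


def rescue_effect(
    results: pd.DataFrame,
    baseline_condition: str,
    treated_condition: str,
) -> float:
    """Percent reduction in cell death of a treatment versus its baseline.

    ``100 * (1 - death_treated / death_baseline)``; e.g. halving death under
    partial extracellular Na+ replacement reads as a 50% rescue.
    """
    by_cond = results.set_index("condition")["percent_death"]
    for cond in (baseline_condition, treated_condition):
        if cond not in by_cond.index:
            raise ValueError(f"condition {cond!r} not in results")
    base = float(by_cond[baseline_condition])
    if base <= 0:
        raise ValueError(f"baseline percent death must be positive, got {base:.4g}")
    return 100.0 * (1.0 - float(by_cond[treated_condition]) / base)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Monotonicity-enforced, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a nonempty 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
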