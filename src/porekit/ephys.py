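"""Planar-bilayer channel biophysics.

Reversal-potential based permeability analysis for a non-selective cation
channel studied in planar lipid bilayers: ion activities (Davies equation),
Nernst potentials, the bi-ionic Goldman-Hodgkin-Katz permeability ratio,
the Lewis relation for divalent/monovalent permeability ratios in monovalent
excess, least-squares reversal-potential estimation from current-voltage
records, and pH-gating conductance fold-change.

Sign convention
---------------
Voltages are reported as *cis* relative to *trans* (the cis chamber is the
protein-addition side).  Under this convention the bi-ionic reversal
potential for monovalent cations X (cis) and Y (trans), with zero anion
permeability, satisfies

    E_rev = (RT/F) * ln( pY * a_Y,trans / (pX * a_X,cis) )

so a cis ion slightly *more* permeant than the trans ion pulls E_rev
slightly negative.  The Nernst potential uses the same orientation:
E = (RT/zF) * ln(a_trans / a_cis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhysConstants",
    "IonSpecies",
    "BathCondition",
    "IVRecording",
    "PermeabilityResult",
    "ReversalEstimate",
    "activity",
    "nernst_potential",
    "ghk_bionic_permeability",
    "lewis_delta_erev",
    "lewis_pca_ratio",
    "estimate_reversal_potential",
    "conductance_fold_change",
]

# Davies A coefficient for water at 25 C, (mol/L)^-1/2
_DAVIES_A = 0.5092


@dataclass(frozen=True)
class PhysConstants:
    """Gas constant, Faraday constant and absolute temperature.

    Default temperature is 295.15 K (22 C), typical for room-temperature
    bilayer recordings; override for other conditions.
    """

    R: float = 8.314462618  # J mol^-1 K^-1
    F: float = 96485.33212  # C mol^-1
    T: float = 295.15  # K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")

    @property
    def rt_f_mV(self) -> float:
        """RT/F in millivolts (~25.43 mV at 22 C)."""
        return self.R * self.T / self.F * 1e3


@dataclass
class IonSpecies:
    """One ionic species with per-side concentrations and activity coefficients."""

    name: str
    z: int
    cis_mM: float = 0.0
    trans_mM: float = 0.0
    cis_gamma: float = 1.0
    trans_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("ion charge must be nonzero")
        if self.cis_mM < 0 or self.trans_mM < 0:
            raise ValueError("concentrations must be >= 0")
        for g in (self.cis_gamma, self.trans_gamma):
            if not 0 < g <= 1:
                raise ValueError("activity coefficients must be in (0, 1]")

    @property
    def cis_activity(self) -> float:
        return self.cis_mM * self.cis_gamma

    @property
    def trans_activity(self) -> float:
        return self.trans_mM * self.trans_gamma


@dataclass
class BathCondition:
    """Recording-chamber composition: ions, constants and per-side pH."""

    ions: list[IonSpecies]
    constants: PhysConstants = field(default_factory=PhysConstants)
    cis_ph: float = 7.2
    trans_ph: float = 7.2

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError("a bath condition needs at least one ion")


@dataclass
class IVRecording:
    """Timestamped commanded-voltage / measured-current record.

    ``annotations`` is a list of ``(time_s, label)`` events (pH changes,
    perfusions).  Voltage is commanded cis-relative-to-trans, in mV;
    current in pA.
    """

    time_s: np.ndarray
    voltage_mV: np.ndarray
    current_pA: np.ndarray
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        n = self.time_s.size
        if self.voltage_mV.size != n or self.current_pA.size != n:
            raise ValueError("time, voltage and current must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    def window(self, t_start: float, t_end: float) -> "IVRecording":
        """Sub-record on the half-open time interval [t_start, t_end)."""
        m = (self.time_s >= t_start) & (self.time_s < t_end)
        return IVRecording(
            self.time_s[m], self.voltage_mV[m], self.current_pA[m],
            [(t, lab) for t, lab in self.annotations if t_start <= t < t_end],
        )


@dataclass
class PermeabilityResult:
    """A relative permeability with the reversal potential it came from."""

    ratio_name: str
    value: float
    erev_used_mV: float
    method: str  # "ghk_bionic" | "lewis"
    temperature_K: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("permeability ratios are nonnegative")


@dataclass
class ReversalEstimate:
    """Linear I-V fit: zero-crossing voltage, slope conductance, residuals."""

    erev_mV: float
    conductance_nS: float
    fit_window_s: tuple[float, float]
    residual_rmse_pA: float


# ---------------------------------------------------------------------------
# activities and equilibrium potentials
# ---------------------------------------------------------------------------

def activity(
    concentration_mM: float,
    z: int,
    ionic_strength_mM: float = 0.0,
    gamma: float | None = None,
) -> float:
    """Single-ion activity on the mM scale.

    Uses the Davies equation at 25 C,
    ``log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)`` with I in mol/L,
    unless an explicit ``gamma`` is supplied.  At zero ionic strength the
    ideal-solution limit gamma = 1 applies.
    """
    if concentration_mM < 0 or ionic_strength_mM < 0:
        raise ValueError("concentration and ionic strength must be >= 0")
    if gamma is not None:
        if not 0 < gamma <= 1:
            raise ValueError("explicit gamma must be in (0, 1]")
        return gamma * concentration_mM
    if ionic_strength_mM == 0:
        return concentration_mM
    i_molar = ionic_strength_mM / 1e3
    sqrt_i = math.sqrt(i_molar)
    log_g = -_DAVIES_A * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * i_molar)
    return 10.0 ** log_g * concentration_mM


def nernst_potential(ion: IonSpecies, constants: PhysConstants | None = None) -> float:
    """Equilibrium (Nernst) potential in mV, cis relative to trans.

    E = (RT/zF) ln(a_trans / a_cis).  A pure activity gradient of the single
    permeant ion zeroes the current at this voltage; for a channel ideally
    selective for that ion the measured reversal potential lies on this line.
    """
    constants = constants or PhysConstants()
    a_cis, a_trans = ion.cis_activity, ion.trans_activity
    if a_cis <= 0 or a_trans <= 0:
        raise ValueError("Nernst potential needs positive activities on both sides")
    return constants.rt_f_mV / ion.z * math.log(a_trans / a_cis)


# ---------------------------------------------------------------------------
# GHK bi-ionic and Lewis relations
# ---------------------------------------------------------------------------

def ghk_bionic_permeability(
    erev_mV: float,
    cis_ion: IonSpecies,
    trans_ion: IonSpecies,
    constants: PhysConstants | None = None,
) -> PermeabilityResult:
    """Bi-ionic GHK permeability ratio p_cis / p_trans for monovalent cations.

    Solves ``E_rev = (RT/F) ln(p_trans a_trans / (p_cis a_cis))`` for the
    cis-ion permeability relative to the trans ion (trans reference = 1.0),
    assuming zero anion permeability.  Divalent ions are rejected; use the
    Lewis relations for the divalent-over-monovalent case.
    """
    constants = constants or PhysConstants()
    for ion, side in ((cis_ion, "cis"), (trans_ion, "trans")):
        if ion.z != 1:
            raise ValueError(
                f"{side} ion {ion.name!r} has z={ion.z}; the bi-ionic GHK form "
                "applies to monovalent cations only - use lewis_pca_ratio for "
                "divalent/monovalent ratios"
            )
    a_cis = cis_ion.cis_activity
    a_trans = trans_ion.trans_activity
    if a_cis <= 0 or a_trans <= 0:
        raise ValueError("both bi-ionic activities must be positive")
    ratio = (a_trans / a_cis) * math.exp(-erev_mV / constants.rt_f_mV)
    return PermeabilityResult(
        ratio_name=f"p{cis_ion.name}/p{trans_ion.name}",
        value=ratio,
        erev_used_mV=erev_mV,
        method="ghk_bionic",
        temperature_K=constants.T,
    )


def lewis_delta_erev(
    pca_over_pk: float,
    ca_mM: float,
    k_mM: float,
    constants: PhysConstants | None = None,
) -> float:
    """Magnitude of the reversal-potential shift on adding Ca2+ in K+ excess.

    ``dE_rev = (RT/2F) ln(1 + (pCa/pK) * 4 [Ca2+]/[K+])`` in mV.  The shift is
    toward more negative cis-relative voltages when the calcium is added to
    the cis chamber; callers track direction via the addition side.
    """
    constants = constants or PhysConstants()
    if pca_over_pk < 0 or ca_mM < 0:
        raise ValueError("permeability ratio and [Ca2+] must be >= 0")
    if k_mM <= 0:
        raise ValueError("[K+] must be positive")
    return constants.rt_f_mV / 2.0 * math.log1p(pca_over_pk * 4.0 * ca_mM / k_mM)


def lewis_pca_ratio(
    delta_erev_mV: float,
    ca_mM: float,
    k_mM: float,
    constants: PhysConstants | None = None,
) -> PermeabilityResult:
    """Invert the Lewis relation: pCa/pK from a measured |dE_rev|.

    Exact algebraic inverse of :func:`lewis_delta_erev`;
    ``pCa/pK = (exp(2F dE/RT) - 1) [K+] / (4 [Ca2+])``.
    """
    constants = constants or PhysConstants()
    if delta_erev_mV < 0:
        raise ValueError("pass the magnitude of the shift (>= 0)")
    if ca_mM <= 0 or k_mM <= 0:
        raise ValueError("[Ca2+] and [K+] must be positive")
    ratio = math.expm1(2.0 * delta_erev_mV / constants.rt_f_mV) * k_mM / (4.0 * ca_mM)
    if ratio < 0:
        raise ValueError("inputs imply a negative permeability ratio")
    return PermeabilityResult(
        ratio_name="pCa/pK",
        value=ratio,
        erev_used_mV=delta_erev_mV,
        method="lewis",
        temperature_K=constants.T,
    )


# ---------------------------------------------------------------------------
# I-V record fitting
# ---------------------------------------------------------------------------

def estimate_reversal_potential(
    rec: IVRecording,
    window: tuple[float, float] | None = None,
) -> ReversalEstimate:
    """Least-squares linear I-V fit; E_rev is the zero-current voltage.

    Fits ``I = G (V - E_rev)`` over the chosen time window (whole record by
    default).  This mirrors the operational bench definition - the voltage
    required to zero the current - and needs at least two distinct commanded
    voltages in the window.
    """
    sub = rec if window is None else rec.window(*window)
    if sub.time_s.size < 2:
        raise ValueError("fit window contains fewer than 2 samples")
    v, i = sub.voltage_mV, sub.current_pA
    if np.ptp(v) == 0:
        raise ValueError("constant commanded voltage in window: E_rev unidentifiable")
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValueError("zero fitted conductance: E_rev unidentifiable")
    erev = -intercept / slope
    resid = i - (slope * v + intercept)
    t0 = float(sub.time_s[0]) if window is None else window[0]
    t1 = float(sub.time_s[-1]) if window is None else window[1]
    return ReversalEstimate(
        erev_mV=float(erev),
        conductance_nS=float(slope),  # pA/mV == nS
        fit_window_s=(t0, t1),
        residual_rmse_pA=float(np.sqrt(np.mean(resid ** 2))),
    )


def conductance_fold_change(
    rec: IVRecording,
    window_before: tuple[float, float],
    window_after: tuple[float, float],
    noise_floor_nS: float = 1e-6,
) -> float:
    """Ratio of fitted conductances (after / before) across two windows.

    Quantifies pH-gated channel opening, e.g. the several-hundred-fold
    amplification of bilayer conductance on cis neutralization.  Each window
    gets its own linear I-V fit; the before-window slope must exceed
    ``noise_floor_nS`` to give a meaningful ratio.
    """
    before = estimate_reversal_potential(rec, window_before)
    after = estimate_reversal_potential(rec, window_after)
    g_before = abs(before.conductance_nS)
    if g_before <= noise_floor_nS:
        raise ValueError(
            "conductance in the 'before' window is at or below the noise floor "
            f"({g_before:.3g} nS <= {noise_floor_nS:.3g} nS); widen the window or "
            "check that the channel had inserted"
        )
    return abs(after.conductance_nS) / g_before
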