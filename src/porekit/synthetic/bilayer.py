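"""Synthetic pH-gated bilayer current-voltage recordings.

Emulates the two-step gating phenotype of the channel: acid-driven membrane
insertion gives a minor ("closed-dominated") conductance, and neutralization
opens the channels, amplifying the conductance by a configurable fold
(default 450).  Current follows an ohmic model around a known reversal
potential, which makes the true E_rev and fold-change recoverable by the
analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ephys import IVRecording

__all__ = ["BilayerSimConfig", "gen_bilayer_recording"]

# pH at or above which the inserted channel is considered open
_NEUTRAL_PH = 6.8


@dataclass
class BilayerSimConfig:
    """Parameters of a simulated pH-gated bilayer recording.

    ``voltage_protocol`` is a list of ``(duration_s, commanded_mV)`` steps.
    ``ph_events`` is a list of ``(time_s, new_pH)``; a pH below 6.8 puts the
    (inserted) channel population in the closed-dominated state with
    ``closed_conductance_nS``, a pH at or above 6.8 opens it.  If
    ``open_conductance_nS`` is None it defaults to
    ``closed * fold_change_on_neutralization``.
    """

    true_erev_mV: float = 0.0
    closed_conductance_nS: float = 0.004
    open_conductance_nS: float | None = None
    fold_change_on_neutralization: float = 450.0
    voltage_protocol: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, v) for v in range(-80, 81, 20)]
    )
    ph_events: list[tuple[float, float]] = field(default_factory=list)
    initial_ph: float = 5.6
    noise_sd_pA: float = 2.0
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.voltage_protocol:
            raise ValueError("voltage protocol must contain at least one step")
        if any(d <= 0 for d, _ in self.voltage_protocol):
            raise ValueError("protocol step durations must be positive")
        if self.fold_change_on_neutralization < 1:
            raise ValueError("fold change on neutralization must be >= 1")
        if self.closed_conductance_nS < 0:
            raise ValueError("conductances must be >= 0")
        if self.open_conductance_nS is not None and self.open_conductance_nS < 0:
            raise ValueError("conductances must be >= 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def resolved_open_conductance_nS(self) -> float:
        if self.open_conductance_nS is not None:
            return self.open_conductance_nS
        return self.closed_conductance_nS * self.fold_change_on_neutralization


def gen_bilayer_recording(cfg: BilayerSimConfig) -> IVRecording:
    """Simulate one recording: I(t) = G(t) * (V(t) - E_rev) + noise.

    G(t) switches between the closed-dominated and open conductance at each
    pH event; the events are carried on the record as annotations.  Identical
    configs (same seed) produce bit-identical records.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sample_rate_hz

    # sample grid and commanded voltage from the step protocol
    times, volts = [], []
    t = 0.0
    for duration, v in cfg.voltage_protocol:
        n = max(1, int(round(duration * cfg.sample_rate_hz)))
        times.append(t + dt * np.arange(n))
        volts.append(np.full(n, float(v)))
        t += n * dt
    time_s = np.concatenate(times)
    voltage = np.concatenate(volts)

    # piecewise conductance from the pH history
    def state_g(ph: float) -> float:
        return (
            cfg.resolved_open_conductance_nS
            if ph >= _NEUTRAL_PH
            else cfg.closed_conductance_nS
        )

    g = np.full(time_s.size, state_g(cfg.initial_ph))
    for t_ev, ph in sorted(cfg.ph_events):
        g[time_s >= t_ev] = state_g(ph)

    current = g * (voltage - cfg.true_erev_mV)
    if cfg.noise_sd_pA > 0:
        current = current + rng.normal(0.0, cfg.noise_sd_pA, size=time_s.size)

    annotations = [(float(t_ev), f"pH {ph:g}") for t_ev, ph in sorted(cfg.ph_events)]
    return IVRecording(time_s, voltage, current, annotations)
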