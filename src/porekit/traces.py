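"""Per-cell fluorescence time-series analysis.

Computes ∆F/F₀ against a per-cell baseline (mean of the first three recorded
frames by default), detects the onset of a sustained indicator rise with a
persistence-thresholded robust-z rule, detects lysis as a persistent step in
a membrane-integrity dye channel, measures onset lags between channels
(e.g. cytoplasmic Ca²⁺ vs membrane voltage), applies rule-based quality
filtering, and summarizes cell populations per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTrack",
    "TraceFeature",
    "compute_dff",
    "detect_onset",
    "detect_lysis",
    "onset_lag",
    "qc_filter",
    "population_summary",
]

# absolute ∆F/F₀ floor used when the baseline spread is degenerate (zero MAD)
DFF_FLOOR = 0.2


@dataclass
class CellTrack:
    """One tracked cell: frame times plus per-channel mean intensities.

    Channels are keyed by canonical sensor names ("gcamp6f", "flicr",
    "draq7", ...).  ``position`` optionally carries the (row, col) centroid
    used by the spot tracker and the ROI-bounds QC rule.
    """

    cell_id: str
    field_id: str
    condition: str
    time_min: np.ndarray
    channels: dict[str, np.ndarray]
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.time_min.size > 1 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not self.channels:
            raise ValueError("a track needs at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vals in self.channels.items():
            if vals.size != self.time_min.size:
                raise ValueError(
                    f"channel {name!r} length {vals.size} != {self.time_min.size} frames"
                )

    @property
    def n_frames(self) -> int:
        return self.time_min.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format rows: cell_id, field_id, condition, time_min, channel, intensity."""
        rows = []
        for name, vals in self.channels.items():
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": self.cell_id,
                        "field_id": self.field_id,
                        "condition": self.condition,
                        "time_min": self.time_min,
                        "channel": name,
                        "intensity": vals,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class TraceFeature:
    """Derived per-cell features: baseline, ∆F/F₀ series and event times."""

    cell_id: str
    channel: str
    f0: float
    dff: np.ndarray
    onset_time: float | None = None
    peak_dff: float = field(default=np.nan)
    lysis_time: float | None = None
    depolarization_onset: float | None = None


def compute_dff(track: CellTrack, channel: str, n_baseline: int = 3) -> TraceFeature:
    """∆F/F₀ for one channel: dff_t = (F_t - F0) / F0.

    F₀ is the mean of the first ``n_baseline`` recorded frames of *this*
    cell, regardless of absolute clock time; it must be positive.
    """
    if channel not in track.channels:
        raise KeyError(f"track {track.cell_id} has no channel {channel!r}")
    f = track.channels[channel]
    if f.size < n_baseline:
        raise ValueError(
            f"track length {f.size} < n_baseline={n_baseline}; cannot form baseline"
        )
    f0 = float(np.mean(f[:n_baseline]))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0={f0}; ∆F/F0 undefined")
    dff = (f - f0) / f0
    return TraceFeature(
        cell_id=track.cell_id,
        channel=channel,
        f0=f0,
        dff=dff,
        peak_dff=float(np.max(dff)),
    )


def detect_onset(
    dff: np.ndarray,
    time_min: np.ndarray,
    threshold_k: float = 5.0,
    baseline_window: int = 12,
    min_consecutive: int = 3,
    zero_spread_floor: float = DFF_FLOOR,
) -> float | None:
    """First time of a sustained rise in a ∆F/F₀ series, or None.

    The onset is the first frame whose ∆F/F₀ exceeds
    ``median + threshold_k * MAD`` of the first ``baseline_window`` frames for
    at least ``min_consecutive`` consecutive frames.  A zero-spread baseline
    falls back to an absolute floor of ``zero_spread_floor`` (default 0.2)
    above the median, so a perfectly quiet noiseless baseline still yields a
    usable rule; lower the floor for sensors with small dynamic range (a
    membrane-voltage reporter plateaus near 0.2-0.3 ∆F/F₀).
    """
    dff = np.asarray(dff, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if dff.size < baseline_window + min_consecutive:
        raise ValueError(
            f"series of {dff.size} frames is shorter than baseline_window + "
            f"min_consecutive = {baseline_window + min_consecutive}"
        )
    base = dff[:baseline_window]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    threshold = med + (threshold_k * mad if mad > 0 else zero_spread_floor)

    above = dff > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(time_min[i - min_consecutive + 1])
    return None


def detect_lysis(
    track: CellTrack,
    draq7_channel: str = "draq7",
    step_threshold: float = 1.0,
    min_consecutive: int = 2,
    n_baseline: int = 3,
) -> float | None:
    """First time the membrane-integrity dye shows a persistent uptake step.

    Dye uptake only happens after loss of membrane integrity, so the first
    frame where the dye's ∆F/F₀ exceeds ``step_threshold`` for
    ``min_consecutive`` consecutive frames marks lysis; None if never.
    """
    if draq7_channel not in track.channels:
        raise KeyError(f"track {track.cell_id} has no channel {draq7_channel!r}")
    feat = compute_dff(track, draq7_channel, n_baseline=n_baseline)
    above = feat.dff > step_threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(track.time_min[i - min_consecutive + 1])
    return None


def onset_lag(
    track: CellTrack,
    channel_a: str,
    channel_b: str,
    n_baseline: int = 3,
    **onset_params,
) -> float | None:
    """Lag (minutes) between sustained rises in two channels: onset_b - onset_a.

    Used to ask whether the Ca²⁺ influx and membrane depolarization begin
    concurrently.  Returns None if either channel never shows an onset.
    """
    feats = {}
    for ch in (channel_a, channel_b):
        feat = compute_dff(track, ch, n_baseline=n_baseline)
        feats[ch] = detect_onset(feat.dff, track.time_min, **onset_params)
    a, b = feats[channel_a], feats[channel_b]
    if a is None or b is None:
        return None
    return b - a


def qc_filter(
    tracks: list[CellTrack],
    min_length: int = 10,
    max_gap_min: float | None = None,
    roi_bounds: tuple[float, float, float, float] | None = None,
) -> tuple[list[CellTrack], pd.Series]:
    """Rule-based track curation; returns (kept tracks, per-reason exclusion counts).

    Drops tracks shorter than ``min_length`` frames, tracks with a frame gap
    exceeding ``max_gap_min`` minutes, and tracks whose centroid lies outside
    ``roi_bounds`` = (row_min, row_max, col_min, col_max).  A rule-based
    analogue of manual curation for dead / overlapping / out-of-field cells.
    """
    kept: list[CellTrack] = []
    counts = {"short": 0, "gap": 0, "out_of_roi": 0}
    for tr in tracks:
        if tr.n_frames < min_length:
            counts["short"] += 1
            continue
        if max_gap_min is not None and tr.n_frames > 1:
            if np.max(np.diff(tr.time_min)) > max_gap_min:
                counts["gap"] += 1
                continue
        if roi_bounds is not None and tr.position is not None:
            r0, r1, c0, c1 = roi_bounds
            r, c = tr.position
            if not (r0 <= r <= r1 and c0 <= c <= c1):
                counts["out_of_roi"] += 1
                continue
        kept.append(tr)
    return kept, pd.Series(counts, name="n_excluded")


def population_summary(
    tracks: list[CellTrack],
    channel: str,
    timepoints: list[float],
    reference_condition: str,
    n_baseline: int = 3,
) -> pd.DataFrame:
    """Condition-level mean ∆F/F₀ at chosen timepoints, with fold vs reference.

    Cells whose recording does not span a requested timepoint are excluded
    from that timepoint (and counted), never interpolated.  ``fold_vs_reference``
    is the ratio of condition means of per-cell ∆F/F₀; it is NaN when the
    reference mean is not meaningfully nonzero.
    """
    rows = []
    for tr in tracks:
        feat = compute_dff(tr, channel, n_baseline=n_baseline)
        for tp in timepoints:
            if tp < tr.time_min[0] or tp > tr.time_min[-1]:
                rows.append((tr.condition, tp, np.nan, False))
                continue
            idx = int(np.argmin(np.abs(tr.time_min - tp)))
            rows.append((tr.condition, tp, feat.dff[idx], True))
    df = pd.DataFrame(rows, columns=["condition", "timepoint", "dff", "in_span"])

    out = []
    for (cond, tp), grp in df.groupby(["condition", "timepoint"], sort=True):
        vals = grp.loc[grp["in_span"], "dff"].to_numpy()
        if vals.size == 0:
            continue  # empty condition/timepoint omitted
        out.append(
            {
                "condition": cond,
                "timepoint": tp,
                "n_cells": int(vals.size),
                "n_excluded": int((~grp["in_span"]).sum()),
                "mean_dff": float(np.mean(vals)),
                "sd_dff": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(out)
    if summary.empty:
        return summary

    ref = summary[summary["condition"] == reference_condition].set_index("timepoint")[
        "mean_dff"
    ]
    folds = []
    for _, row in summary.iterrows():
        ref_mean = ref.get(row["timepoint"], np.nan)
        if np.isfinite(ref_mean) and abs(ref_mean) > 1e-12:
            folds.append(row["mean_dff"] / ref_mean)
        else:
            folds.append(np.nan)
    summary["fold_vs_reference"] = folds
    return summary
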