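"""∆F/F₀, onset/lysis detection, lags, QC and population summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from porekit.synthetic import CohortCondition, CohortSimConfig, gen_trace_cohort
from porekit.traces import (
    CellTrack,
    compute_dff,
    detect_lysis,
    detect_onset,
    onset_lag,
    population_summary,
    qc_filter,
)


def make_track(values, channel="gcamp6f", dt=5.0, **kwargs):
    values = np.asarray(values, dtype=float)
    return CellTrack(
        cell_id=kwargs.pop("cell_id", "c0"),
        field_id="f0",
        condition=kwargs.pop("condition", "G0"),
        time_min=dt * np.arange(values.size),
        channels={channel: values},
        **kwargs,
    )


ZERO_NOISE = {"gcamp6f": 0.0, "flicr": 0.0, "draq7": 0.0}


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        feat = compute_dff(make_track([7.0] * 10), "gcamp6f")
        assert feat.f0 == 7.0
        assert np.allclose(feat.dff, 0.0)

    def test_hand_arithmetic(self):
        feat = compute_dff(make_track([10, 10, 10, 30]), "gcamp6f")
        assert feat.f0 == 10.0
        assert np.allclose(feat.dff, [0.0, 0.0, 0.0, 2.0])

    @given(
        st.floats(0.1, 1000),
        st.lists(st.floats(1.0, 1e4), min_size=4, max_size=40),
    )
    def test_gain_invariance(self, gain, values):
        """∆F/F₀ is unchanged by any multiplicative gain on the raw trace."""
        a = compute_dff(make_track(values), "gcamp6f").dff
        b = compute_dff(make_track(gain * np.asarray(values)), "gcamp6f").dff
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_baseline_shift_equivariance(self):
        """Adding an offset changes dff exactly as the formula dictates."""
        values = np.array([10.0, 10.0, 10.0, 30.0, 20.0])
        shift = 5.0
        shifted = compute_dff(make_track(values + shift), "gcamp6f")
        expected = (values + shift - 15.0) / 15.0
        assert np.allclose(shifted.dff, expected)

    def test_short_track_and_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="n_baseline"):
            compute_dff(make_track([1.0, 2.0]), "gcamp6f")
        with pytest.raises(ValueError, match="F0"):
            compute_dff(make_track([0.0, 0.0, 0.0, 5.0]), "gcamp6f")

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            compute_dff(make_track([1, 2, 3, 4]), "flicr")


class TestDetectOnset:
    def test_pure_noise_yields_none(self, rng):
        dff = rng.normal(0, 0.03, size=60)
        assert detect_onset(dff, 5.0 * np.arange(60)) is None

    def test_noiseless_ramp_recovered_exactly(self):
        cfg = CohortSimConfig(
            conditions=[CohortCondition("x", 3, onset=("fixed", 100.0))],
            noise_sd=ZERO_NOISE, seed=0,
        )
        coh = gen_trace_cohort(cfg)
        for tr, onset_true in zip(coh.tracks, coh.truth["onset_time"]):
            feat = compute_dff(tr, "gcamp6f")
            assert detect_onset(feat.dff, tr.time_min) == onset_true == 100.0

    def test_single_frame_spike_ignored(self):
        dff = np.zeros(40)
        dff[20] = 5.0
        assert detect_onset(dff, np.arange(40.0), min_consecutive=3) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(np.zeros(5), np.arange(5.0), baseline_window=12)


class TestDetectLysis:
    def test_flat_dye_channel_yields_none(self):
        tr = make_track([20.0] * 30, channel="draq7")
        assert detect_lysis(tr) is None

    def test_generator_lysis_recovered_at_zero_noise(self):
        cfg = CohortSimConfig(
            conditions=[
                CohortCondition(
                    "x", 5, onset=("fixed", 100.0), lysis_delay=("fixed", 120.0)
                )
            ],
            noise_sd=ZERO_NOISE, seed=0,
        )
        coh = gen_trace_cohort(cfg)
        for tr, t_lys in zip(coh.tracks, coh.truth["lysis_time"]):
            assert detect_lysis(tr) == t_lys == 220.0

    def test_lysis_never_precedes_onset_on_ordered_cohorts(self):
        cfg = CohortSimConfig(
            conditions=[
                CohortCondition(
                    "x", 40, onset=("uniform", 50.0, 200.0),
                    lysis_delay=("uniform", 60.0, 200.0),
                )
            ],
            n_frames=120, seed=3,
        )
        coh = gen_trace_cohort(cfg)
        for tr in coh.tracks:
            feat = compute_dff(tr, "gcamp6f")
            onset = detect_onset(feat.dff, tr.time_min)
            lysis = detect_lysis(tr)
            if onset is not None and lysis is not None:
                assert lysis >= onset

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            detect_lysis(make_track([1.0] * 30, channel="gcamp6f"))


class TestOnsetLag:
    def test_identical_channels_zero_lag(self):
        values = np.concatenate([np.full(20, 10.0), np.full(20, 40.0)])
        tr = make_track(values)
        tr.channels["flicr"] = values.copy()
        assert onset_lag(tr, "gcamp6f", "flicr") == 0.0

    def test_programmed_coupling_lag_exact_at_zero_noise(self):
        cfg = CohortSimConfig(
            conditions=[
                CohortCondition(
                    "x", 5, onset=("fixed", 100.0), voltage_coupling_lag_frames=2
                )
            ],
            noise_sd=ZERO_NOISE, seed=0,
        )
        coh = gen_trace_cohort(cfg)
        for tr in coh.tracks:
            # floor below the voltage sensor's per-frame rise increment
            lag = onset_lag(tr, "gcamp6f", "flicr", zero_spread_floor=0.02)
            assert lag == 2 * cfg.frame_interval_min

    def test_quiet_cohort_yields_none(self):
        cfg = CohortSimConfig(
            conditions=[CohortCondition("ref", 4, onset=("never",))], seed=1
        )
        coh = gen_trace_cohort(cfg)
        for tr in coh.tracks:
            assert onset_lag(tr, "gcamp6f", "flicr") is None


class TestQcFilter:
    def test_compliant_tracks_identity(self):
        tracks = [make_track(np.full(20, 10.0), cell_id=f"c{i}") for i in range(5)]
        kept, counts = qc_filter(tracks, min_length=10)
        assert len(kept) == 5
        assert counts.sum() == 0

    def test_short_track_removed_and_counted(self):
        tracks = [make_track(np.full(3, 10.0)), make_track(np.full(20, 10.0))]
        kept, counts = qc_filter(tracks, min_length=10)
        assert len(kept) == 1
        assert counts["short"] == 1

    def test_roi_and_gap_rules_and_bookkeeping(self):
        good = make_track(np.full(20, 10.0), position=(50.0, 50.0))
        outside = make_track(np.full(20, 10.0), position=(500.0, 50.0))
        gappy = CellTrack(
            "g", "f0", "G0",
            np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)]),
            {"gcamp6f": np.full(20, 10.0)},
        )
        kept, counts = qc_filter(
            [good, outside, gappy], min_length=10, max_gap_min=10.0,
            roi_bounds=(0, 100, 0, 100),
        )
        assert len(kept) == 1
        assert counts.sum() == 3 - len(kept)


class TestPopulationSummary:
    def test_programmed_plateau_fold_zero_noise(self):
        cfg = CohortSimConfig(
            conditions=[
                CohortCondition("ref", 10, onset=("fixed", 50.0), dff_plateau=1.0),
                CohortCondition("rrv", 10, onset=("fixed", 50.0), dff_plateau=2.0),
            ],
            noise_sd=ZERO_NOISE, n_frames=60, seed=0,
        )
        coh = gen_trace_cohort(cfg)
        s = population_summary(coh.tracks, "gcamp6f", [290.0], "ref")
        fold = s.set_index("condition")["fold_vs_reference"]
        assert fold["rrv"] == pytest.approx(2.0)
        assert fold["ref"] == pytest.approx(1.0)

    def test_mean_matches_per_cell_features_exactly(self):
        cfg = CohortSimConfig(
            conditions=[CohortCondition("x", 20, onset=("uniform", 50.0, 150.0))],
            seed=2,
        )
        coh = gen_trace_cohort(cfg)
        tp = float(coh.tracks[0].time_min[-1])
        s = population_summary(coh.tracks, "gcamp6f", [tp], "x")
        per_cell = [compute_dff(t, "gcamp6f").dff[-1] for t in coh.tracks]
        assert s["mean_dff"].iloc[0] == pytest.approx(np.mean(per_cell), abs=1e-12)

    def test_out_of_span_cells_excluded_and_counted(self):
        long = make_track(np.full(20, 10.0), cell_id="long")
        short = CellTrack("short", "f0", "G0", 5.0 * np.arange(10),
                          {"gcamp6f": np.full(10, 10.0)})
        s = population_summary([long, short], "gcamp6f", [80.0], "G0")
        row = s.iloc[0]
        assert row["n_cells"] == 1 and row["n_excluded"] == 1
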