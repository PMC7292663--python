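"""Channel-biophysics math: activities, Nernst, GHK, Lewis, I-V fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from porekit.ephys import (
    IonSpecies,
    IVRecording,
    PhysConstants,
    activity,
    conductance_fold_change,
    estimate_reversal_potential,
    ghk_bionic_permeability,
    lewis_delta_erev,
    lewis_pca_ratio,
    nernst_potential,
)
from porekit.synthetic import BilayerSimConfig, gen_bilayer_recording

C22 = PhysConstants()  # 295.15 K
C25 = PhysConstants(T=298.15)


class TestActivity:
    def test_ideal_solution_limit(self):
        assert activity(10.0, 2, ionic_strength_mM=0.0) == 10.0

    def test_davies_hand_evaluation(self):
        # 10 mM CaCl2 -> I = 30 mM; independent hand evaluation of the
        # Davies formula: log10(g) = -0.5092*4*(sqrt(.03)/(1+sqrt(.03)) - .3*.03)
        i = 0.030
        gamma = 10 ** (-0.5092 * 4 * (math.sqrt(i) / (1 + math.sqrt(i)) - 0.3 * i))
        assert activity(10.0, 2, ionic_strength_mM=30.0) == pytest.approx(10 * gamma)
        assert activity(10.0, 2, ionic_strength_mM=30.0) == pytest.approx(5.2195, abs=1e-3)

    def test_explicit_gamma_override(self):
        assert activity(10.0, 2, ionic_strength_mM=30.0, gamma=0.5) == 5.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            activity(-1.0, 1)
        with pytest.raises(ValueError):
            activity(1.0, 1, ionic_strength_mM=-5.0)


class TestNernst:
    def test_symmetric_activities_zero(self):
        ion = IonSpecies("K", 1, cis_mM=150, trans_mM=150)
        assert nernst_potential(ion, C22) == pytest.approx(0.0)

    def test_tenfold_potassium_gradient_25C(self):
        # (RT/F) ln 10 = 59.16 mV at 25 C, independently evaluated
        ion = IonSpecies("K", 1, cis_mM=15, trans_mM=150)
        assert abs(nernst_potential(ion, C25)) == pytest.approx(59.16, abs=0.01)

    def test_calcium_gradient_22C(self):
        # (RT/2F) ln 1.95 = 8.49 mV; the cis-rich gradient pulls E negative
        ion = IonSpecies("Ca", 2, cis_mM=19.5, trans_mM=10.0)
        e = nernst_potential(ion, C22)
        assert e == pytest.approx(-8.49, abs=0.01)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError):
            nernst_potential(IonSpecies("K", 1, cis_mM=0, trans_mM=150), C22)


class TestGhkBionic:
    def test_sodium_over_potassium_printed_value(self):
        na = IonSpecies("Na", 1, cis_mM=150)
        k = IonSpecies("K", 1, trans_mM=150)
        # -2 mV bi-ionic reversal with equimolar baths: ratio rounds to 1.1
        # at every temperature in the 20-25 C range
        for t_c in (20.0, 22.0, 25.0):
            res = ghk_bionic_permeability(-2.0, na, k, PhysConstants(T=273.15 + t_c))
            assert round(res.value, 1) == 1.1

    def test_choline_over_potassium_printed_value(self):
        ch = IonSpecies("choline", 1, cis_mM=150)
        k = IonSpecies("K", 1, trans_mM=150)
        res = ghk_bionic_permeability(60.0, ch, k, C25)
        # +60 mV: about a tenth of the potassium permeability (0.1 at 1 s.f.
        # at 25 C; fractionally lower, ~0.093-0.095, toward 20 C)
        assert res.value == pytest.approx(0.0968, abs=2e-4)
        assert float(f"{res.value:.1g}") == 0.1

    def test_equimolar_zero_reversal_symmetry(self):
        na = IonSpecies("Na", 1, cis_mM=150)
        k = IonSpecies("K", 1, trans_mM=150)
        assert ghk_bionic_permeability(0.0, na, k, C22).value == pytest.approx(1.0)

    def test_divalent_rejected_with_guidance(self):
        ca = IonSpecies("Ca", 2, cis_mM=10)
        k = IonSpecies("K", 1, trans_mM=150)
        with pytest.raises(ValueError, match="lewis"):
            ghk_bionic_permeability(0.0, ca, k, C22)

    @given(st.floats(-80, 80), st.floats(10, 500), st.floats(10, 500))
    def test_inversion_consistency(self, erev, cis, trans):
        """Re-substituting the solved ratio reproduces E_rev to <=1e-9 mV."""
        na = IonSpecies("Na", 1, cis_mM=cis)
        k = IonSpecies("K", 1, trans_mM=trans)
        r = ghk_bionic_permeability(erev, na, k, C22).value
        back = C22.rt_f_mV * math.log(trans / (r * cis))
        assert back == pytest.approx(erev, abs=1e-9)

    def test_identical_species_degenerates_to_nernst(self):
        ion = IonSpecies("K", 1, cis_mM=50, trans_mM=150)
        e_nernst = nernst_potential(ion, C22)
        res = ghk_bionic_permeability(
            e_nernst,
            IonSpecies("K", 1, cis_mM=50),
            IonSpecies("K", 1, trans_mM=150),
            C22,
        )
        assert res.value == pytest.approx(1.0, abs=1e-12)


class TestLewis:
    def test_zero_ratio_zero_shift(self):
        assert lewis_delta_erev(0.0, 2.0, 150.0, C22) == 0.0

    def test_forward_hand_evaluation(self):
        # (RT/2F) ln(1 + 0.6*4*2/150) = 0.4006 mV at 22 C
        assert lewis_delta_erev(0.6, 2.0, 150.0, C22) == pytest.approx(0.40, abs=0.005)

    def test_inverse_of_forward_example(self):
        d = lewis_delta_erev(0.6, 2.0, 150.0, C22)
        assert lewis_pca_ratio(d, 2.0, 150.0, C22).value == pytest.approx(0.6, rel=1e-12)

    @pytest.mark.parametrize("ratio", [0.1, 0.6, 2.0])
    def test_round_trip(self, ratio):
        d = lewis_delta_erev(ratio, 2.0, 150.0, C22)
        assert lewis_pca_ratio(d, 2.0, 150.0, C22).value == pytest.approx(ratio, rel=1e-9)

    def test_monotone_in_permeability_ratio(self):
        shifts = [lewis_delta_erev(r, 2.0, 150.0, C22) for r in (0.1, 0.3, 0.6, 1.2)]
        assert np.all(np.diff(shifts) > 0)

    def test_zero_potassium_rejected(self):
        with pytest.raises(ValueError):
            lewis_delta_erev(0.6, 2.0, 0.0, C22)


class TestReversalEstimation:
    def test_noiseless_record_exact(self):
        cfg = BilayerSimConfig(true_erev_mV=-6.0, noise_sd_pA=0.0, initial_ph=7.2, seed=0)
        est = estimate_reversal_potential(gen_bilayer_recording(cfg))
        assert est.erev_mV == pytest.approx(-6.0, abs=1e-9)
        assert est.residual_rmse_pA == pytest.approx(0.0, abs=1e-9)

    def test_two_points_linear_interpolation(self):
        rec = IVRecording([0.0, 1.0], [-10.0, 10.0], [-6.0, 14.0])
        est = estimate_reversal_potential(rec)
        assert est.erev_mV == pytest.approx(-4.0)
        assert est.conductance_nS == pytest.approx(1.0)

    def test_error_shrinks_with_more_sweeps(self, rng):
        def err(n_steps, seed):
            proto = [(0.2, v) for v in np.linspace(-40, 40, n_steps)]
            cfg = BilayerSimConfig(
                true_erev_mV=5.0, voltage_protocol=proto, noise_sd_pA=20.0,
                initial_ph=7.2, seed=seed,
            )
            return abs(estimate_reversal_potential(gen_bilayer_recording(cfg)).erev_mV - 5.0)

        small = np.mean([err(5, s) for s in range(20)])
        large = np.mean([err(80, s) for s in range(20)])
        assert large < small

    def test_constant_voltage_rejected(self):
        rec = IVRecording([0.0, 1.0, 2.0], [10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_reversal_potential(rec)

    def test_scale_invariance_pA_vs_nA(self):
        cfg = BilayerSimConfig(true_erev_mV=12.0, noise_sd_pA=0.0, initial_ph=7.2, seed=0)
        rec = gen_bilayer_recording(cfg)
        scaled = IVRecording(rec.time_s, rec.voltage_mV, rec.current_pA / 1e3)
        assert estimate_reversal_potential(scaled).erev_mV == pytest.approx(
            estimate_reversal_potential(rec).erev_mV
        )


class TestFoldChange:
    def test_programmed_450_fold_noiseless(self):
        cfg = BilayerSimConfig(
            true_erev_mV=0.0, noise_sd_pA=0.0,
            voltage_protocol=[(0.5, v) for v in (-40, -20, 20, 40)] * 2,
            ph_events=[(2.0, 7.1)], seed=0,
        )
        rec = gen_bilayer_recording(cfg)
        fold = conductance_fold_change(rec, (0.0, 2.0), (2.0, 4.0))
        assert fold == pytest.approx(450.0, rel=1e-9)

    def test_identical_windows_unity(self):
        cfg = BilayerSimConfig(true_erev_mV=0.0, initial_ph=7.2, seed=1)
        rec = gen_bilayer_recording(cfg)
        assert conductance_fold_change(rec, (0.0, 4.0), (0.0, 4.0)) == pytest.approx(1.0)

    def test_tenfold_with_noise_within_ten_percent(self):
        cfg = BilayerSimConfig(
            true_erev_mV=0.0, closed_conductance_nS=0.2,
            fold_change_on_neutralization=10.0,
            voltage_protocol=[(0.5, v) for v in (-40, -20, 20, 40)] * 2,
            ph_events=[(2.0, 7.1)], seed=2,
        )
        rec = gen_bilayer_recording(cfg)
        fold = conductance_fold_change(rec, (0.0, 2.0), (2.0, 4.0))
        assert fold == pytest.approx(10.0, rel=0.10)

    def test_noise_floor_guard(self):
        # no inserted channel before neutralization: the before-window slope
        # is pure noise and must be refused rather than divided by
        cfg = BilayerSimConfig(
            true_erev_mV=0.0, closed_conductance_nS=0.0, noise_sd_pA=2.0,
            ph_events=[(4.0, 7.1)], open_conductance_nS=1.0, seed=0,
        )
        rec = gen_bilayer_recording(cfg)
        with pytest.raises(ValueError, match="noise floor"):
            conductance_fold_change(rec, (0.0, 4.0), (4.0, 8.0), noise_floor_nS=0.05)
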