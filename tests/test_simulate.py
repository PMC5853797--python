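"""Forward models: movement kinetics, quenching dynamics, observation model."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import chloroquench as cq
from chloroquench.errors import ChloroquenchError
from chloroquench.regimes import LightRegime, LightStep
from chloroquench.simulate import SimulationTruth


def step_regime(intensity=500.0, dark_min=60.0, light_min=600.0):
    """One dark step then one light step."""
    return LightRegime(
        [LightStep(0, dark_min, 0.0, "dark"),
         LightStep(dark_min, light_min, intensity, "ambient")],
        photoperiod_length=light_min)


class TestMovement:
    def test_null_profile_gives_flat_trace(self, single_day, wt):
        null = dataclasses.replace(wt, acc_amplitude=0.0, avoid_amplitude=0.0)
        trace, truth = cq.simulate_movement(single_day, null, noise_sd=0.0)
        assert np.all(truth.frame["x"] == 0.0)
        assert np.all(trace.relative == 0.0)

    def test_exponential_approach_matches_closed_form(self, wt):
        # after exactly one time constant the response covers (1 - 1/e)
        # of the distance to the target
        regime = step_regime(500.0)
        _, truth = cq.simulate_movement(regime, wt, noise_sd=0.0)
        d = 500.0 - wt.I_switch
        target = wt.avoid_amplitude * d / (d + wt.K_move)
        x_tau = truth.at(60.0 + wt.tau_avoid)["x"]
        assert x_tau == pytest.approx((1 - math.e ** -1) * target, rel=1e-9)

    def test_accumulation_target_sign_and_value(self, wt):
        regime = step_regime(10.0, light_min=600.0)
        _, truth = cq.simulate_movement(regime, wt, noise_sd=0.0)
        target = -wt.acc_amplitude * 10.0 / (10.0 + wt.K_move)
        assert truth.at(660.0)["x"] == pytest.approx(target, rel=1e-6)
        assert truth.at(660.0)["x"] < 0

    def test_same_seed_bitwise_identical(self, single_day, wt):
        t1, _ = cq.simulate_movement(single_day, wt, noise_sd=0.01, seed=7)
        t2, _ = cq.simulate_movement(single_day, wt, noise_sd=0.01, seed=7)
        assert np.array_equal(t1.R, t2.R)

    def test_seed_changes_noise_not_truth(self, single_day, wt):
        t1, tr1 = cq.simulate_movement(single_day, wt, noise_sd=0.01, seed=1)
        t2, tr2 = cq.simulate_movement(single_day, wt, noise_sd=0.01, seed=2)
        assert np.array_equal(tr1.frame["x"], tr2.frame["x"])
        assert not np.array_equal(t1.R, t2.R)

    def test_negative_noise_rejected(self, single_day, wt):
        with pytest.raises(ChloroquenchError):
            cq.simulate_movement(single_day, wt, noise_sd=-0.1)

    def test_starts_at_zero(self, single_day, wt):
        _, truth = cq.simulate_movement(single_day, wt)
        assert truth.frame["x"].iloc[0] == 0.0


class TestQuenching:
    def test_dark_limit(self, wt):
        regime = LightRegime([LightStep(0, 120, 0.0, "dark")],
                             photoperiod_length=0)
        truth = cq.simulate_quenching(regime, wt)
        assert np.all(truth.frame["qE"] == 0.0)
        assert np.all(truth.frame["qI"] == 0.0)
        assert np.all(truth.frame["phi_ii"] == wt.phi_max)

    def test_no_damage_below_threshold(self, wt):
        regime = step_regime(intensity=wt.I_crit - 50.0)
        truth = cq.simulate_quenching(regime, wt)
        assert np.all(truth.frame["qI"] == 0.0)
        lit = truth.frame[truth.frame["intensity"] > 0]
        assert lit["qE"].nunique() == 1

    def test_qi_fixed_point_above_threshold(self, wt):
        # dqI/dt = k_dmg (I - I_crit) - k_rep qI has fixed point
        # k_dmg (I - I_crit) / k_rep
        I = 500.0
        regime = step_regime(I, dark_min=60.0, light_min=4000.0)
        truth = cq.simulate_quenching(regime, wt)
        expected = wt.k_dmg * (I - wt.I_crit) / wt.k_rep
        assert truth.frame["qI"].iloc[-1] == pytest.approx(expected, rel=1e-6)

    def test_npq_is_sum_of_components_exactly(self, single_day, wt):
        truth = cq.simulate_quenching(single_day, wt)
        assert np.all(truth.frame["npq"] == truth.frame["qE"] + truth.frame["qI"])


class TestObservationModel:
    def test_no_movement_means_no_modulation(self, single_day, wt):
        null = dataclasses.replace(wt, acc_amplitude=0.0, avoid_amplitude=0.0)
        trace, truth = cq.simulate_experiment(single_day, null)
        pulses = cq.render_observed_pulses(truth, trace, m=1.0, cv_noise=0.0)
        for e in pulses.events:
            row = truth.at(e.time)
            assert e.F_m_prime == pytest.approx(
                1000.0 / (1 + row["qE"] + row["qI"]), abs=1e-12)
            assert e.F_m_dprime == pytest.approx(
                1000.0 / (1 + row["qI"]), abs=1e-12)

    def test_yield_model_worked_example(self):
        # qE = 1, qI = 0.25, F_M = 1000 → F_M′ = 444.4̄, F_M″ = 800
        frame = pd.DataFrame({
            "time_min": [0.0, 10.0], "intensity": [0.0, 500.0],
            "x": [0.0, 0.0], "qE": [0.0, 1.0], "qI": [0.0, 0.25],
            "npq": [0.0, 1.25], "phi_ii": [0.8, 0.4],
        })
        truth = SimulationTruth(frame)
        trace = cq.ReflectanceTrace.from_relative([0.0, 10.0, 30.0], [0.0] * 3)
        pulses = cq.render_observed_pulses(
            truth, trace, m=1.0, F_M_dark=1000.0, cv_noise=0.0,
            pulse_times=np.array([10.0]))
        e = pulses.events[0]
        assert e.F_m_prime == pytest.approx(4000.0 / 9, abs=1e-9)
        assert e.F_m_dprime == pytest.approx(800.0, abs=1e-9)
        assert e.F_s == pytest.approx((4000.0 / 9) * 0.6, abs=1e-9)

    def test_forward_model_inverts_through_correction(self, large_noiseless):
        trace, truth, pulses = large_noiseless
        corrected = cq.correct_series(pulses, trace, m=1.0)
        for k, e in enumerate(pulses.events):
            row = truth.at(e.time)
            assert corrected.frame["npq"].iloc[k] == pytest.approx(
                row["npq"], abs=1e-9)
            assert corrected.frame["qe_sv"].iloc[k] == pytest.approx(
                row["qE"], abs=1e-9)
            assert corrected.frame["qi"].iloc[k] == pytest.approx(
                row["qI"], abs=1e-9)

    def test_dark_pair_unscaled(self, wt_noiseless, wt):
        _, _, pulses = wt_noiseless
        assert pulses.F_m == 1000.0
        assert pulses.F_0 == pytest.approx(1000.0 * (1 - wt.phi_max))

    def test_nonpositive_fm_dark_rejected(self, wt_noiseless):
        trace, truth, _ = wt_noiseless
        with pytest.raises(ChloroquenchError):
            cq.render_observed_pulses(truth, trace, F_M_dark=0.0)


class TestImageRenderer:
    def test_noiseless_burst_reproduces_trace_value(self):
        trace = cq.ReflectanceTrace(np.array([0.0, 10.0]),
                                    np.array([1.0, 1.3]), R_0=1.0)
        bursts, mask = cq.render_image_frames(trace, image_size=32,
                                              plant_radius=8,
                                              pixel_noise_sd=0.0)
        assert bursts.shape == (2, 30, 32, 32)
        # every frame in a burst identical, masked mean equals R(t)
        assert np.all(bursts[0] == bursts[0][0])
        assert bursts[1][0][mask].mean() == pytest.approx(1.3)
        assert bursts[1][0][~mask].mean() == pytest.approx(0.1)

    def test_burst_averaging_shrinks_noise(self):
        # sd of the 30-frame averaged masked mean ≈ per-frame sd / sqrt(30)
        trace = cq.ReflectanceTrace(np.array([0.0]), np.array([1.0]), R_0=1.0)
        sds, sds1 = [], []
        for seed in range(40):
            bursts, mask = cq.render_image_frames(
                trace, image_size=32, plant_radius=8, pixel_noise_sd=0.05,
                seed=seed)
            frame_means = bursts[0][:, mask].mean(axis=1)
            sds.append(frame_means.mean())
            sds1.append(frame_means[0])
        ratio = np.std(sds1) / np.std(sds)
        assert ratio == pytest.approx(np.sqrt(30), rel=0.35)

    def test_disk_must_fit(self):
        trace = cq.ReflectanceTrace(np.array([0.0]), np.array([1.0]), R_0=1.0)
        with pytest.raises(ChloroquenchError):
            cq.render_image_frames(trace, image_size=16, plant_radius=8)
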