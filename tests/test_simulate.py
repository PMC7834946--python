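import dataclasses

import numpy as np
import pytest

from pupilload.features import latency_to_peak, mpdc, peak_dilation
from pupilload.preprocess import estimate_baseline, merge_eyes
from pupilload.simulate import (
    EXP1_CONDITIONS,
    KernelSpec,
    SimConfig,
    luminance_response,
    simulate_cohort,
    simulate_experiment2_cohort,
    simulate_gamer_telemetry,
    simulate_participant,
    simulate_trial_trace,
    synth_game_frame,
)
from pupilload.scramble import grid_scramble, uniform_baseline, whole_scramble


NOISELESS = SimConfig(
    noise_sd_px=0.0, channel_noise_sd_px=0.0, interval_jitter_sd_px=0.0,
    blink_rate_hz=0.0, spike_rate_hz=0.0,
)


def test_participant_determinism_and_moments():
    cfg = SimConfig()
    a = simulate_participant(42, cfg)
    b = simulate_participant(42, cfg)
    assert a == b
    draws = [simulate_participant(s, cfg).d0 for s in range(1000)]
    se = cfg.d0_sd_px / np.sqrt(len(draws))
    assert abs(np.mean(draws) - cfg.d0_mean_px) < 3 * se


def test_zero_variance_profiles_identical():
    cfg = SimConfig(d0_sd_px=0.0, light_gain_sd=0.0, tepr_gain_sigma=0.0)
    profiles = {
        dataclasses.replace(simulate_participant(s, cfg), skill=0.0)
        for s in range(5)
    }
    assert len(profiles) == 1


def test_kernel_shape_properties():
    k = KernelSpec()
    t = np.linspace(0, 8000, 4000)
    h = k(t)
    assert np.all(h >= 0)
    assert h.max() == pytest.approx(1.0, abs=1e-4)
    peak = t[np.argmax(h)]
    assert abs(peak - k.peak_time_ms) < 5
    assert 600 < k.peak_time_ms < 1500
    # unimodal: rises then falls
    i = int(np.argmax(h))
    assert np.all(np.diff(h[:i + 1]) >= -1e-12)
    assert np.all(np.diff(h[i:]) <= 1e-12)
    # subsides quickly: below 5% of peak 4 s after onset
    assert k(np.array([k.onset_ms + 3700.0]))[0] < 0.05


def test_luminance_response_signs():
    cfg = SimConfig()
    frame = synth_game_frame(cfg.frame_width, cfg.frame_height, cfg.frame_seed)
    p = simulate_participant(1, cfg)
    assert luminance_response(p, frame, frame, cfg) == 0.0
    white = uniform_baseline(cfg.frame_width, cfg.frame_height, "white")
    black = uniform_baseline(cfg.frame_width, cfg.frame_height, "black")
    s_white = luminance_response(p, white, frame, cfg)
    s_black = luminance_response(p, black, frame, cfg)
    assert s_white < 0 < s_black  # bright constricts, dark dilates
    s_scr = luminance_response(p, whole_scramble(frame, 2), frame, cfg)
    s_grid = luminance_response(p, grid_scramble(frame, 8, 6, 2), frame, cfg)
    assert abs(s_grid) < abs(s_scr) < abs(s_white)


def test_null_trace_is_constant():
    cfg = NOISELESS
    frame = synth_game_frame(cfg.frame_width, cfg.frame_height, cfg.frame_seed)
    p = simulate_participant(3, cfg)
    tt = simulate_trial_trace(p, frame, None, 8000.0, 5, cfg, frame)
    merged = merge_eyes(tt.measurement)
    np.testing.assert_allclose(merged.d, p.d0, atol=1e-12)
    b = estimate_baseline(merge_eyes(tt.baseline), 2000.0)
    assert mpdc(merged, b) == pytest.approx(0.0, abs=1e-9)
    assert peak_dilation(merged, b) == pytest.approx(0.0, abs=1e-9)


def test_noiseless_features_match_closed_form():
    """With noise off, pipeline MPDC/PD must equal the kernel-sum closed form."""
    cfg = NOISELESS
    frame = synth_game_frame(cfg.frame_width, cfg.frame_height, cfg.frame_seed)
    p = simulate_participant(7, cfg)
    tt = simulate_trial_trace(p, frame, "B", 30000.0, 8, cfg, frame)
    merged = merge_eyes(tt.measurement)
    b = estimate_baseline(merge_eyes(tt.baseline), 2000.0)
    truth = tt.truth
    t = tt.measurement.t
    assert truth.event_times_ms.size > 0
    det = np.full(t.size, truth.tonic_measurement)
    for tk, a in zip(truth.event_times_ms, truth.amplitudes):
        det += a * truth.kernel(t - tk)
    assert b.mean_d == pytest.approx(truth.tonic_baseline, abs=1e-9)
    assert mpdc(merged, b) == pytest.approx(
        det.mean() - truth.tonic_baseline, abs=1e-9)
    assert peak_dilation(merged, b) == pytest.approx(
        det.max() - truth.tonic_baseline, abs=1e-9)
    assert latency_to_peak(merged) == pytest.approx(
        t[np.argmax(det)] / 1000.0, abs=1e-9)


def test_monotone_difficulty_effect_without_noise():
    cfg = NOISELESS
    frame = synth_game_frame(cfg.frame_width, cfg.frame_height, cfg.frame_seed)
    for seed in range(5):
        p = simulate_participant(seed, cfg)
        feats = {}
        for world in ("A", "B"):
            tt = simulate_trial_trace(p, frame, world, 50000.0, seed + 100,
                                      cfg, frame)
            merged = merge_eyes(tt.measurement)
            b = estimate_baseline(merge_eyes(tt.baseline), 2000.0)
            feats[world] = mpdc(merged, b)
        assert feats["B"] > feats["A"]


def test_telemetry_distributions():
    cfg = SimConfig()
    expert = dataclasses.replace(simulate_participant(0, cfg), skill=0.95)
    te_easy = [simulate_gamer_telemetry(expert, "A", s, cfg).count("error")
               for s in range(300)]
    assert np.median(te_easy) == 0

    avg = dataclasses.replace(simulate_participant(0, cfg), skill=0.5)
    tc_hard = [next(t for t, k in
                    simulate_gamer_telemetry(avg, "B", s, cfg).events
                    if k == "level_complete")
               for s in range(1000)]
    assert np.median(tc_hard) == pytest.approx(cfg.tc_median_ms["B"], rel=0.10)
    log = simulate_gamer_telemetry(avg, "A", 3, cfg, "L1a")
    assert log.complete and log.level_id == "L1a"
    assert log.count("attempt_start") >= 1


def test_cp_and_attempts_carry_no_difficulty_signal():
    cfg = SimConfig()
    p = dataclasses.replace(simulate_participant(1, cfg), skill=0.5)
    cp = {w: np.mean([simulate_gamer_telemetry(p, w, s, cfg).count("move")
                      for s in range(500)]) for w in ("A", "B")}
    assert abs(cp["A"] - cp["B"]) < 0.2


def test_cohort_determinism_and_structure():
    cfg = SimConfig(n_participants=3, n_participants_exp1=2, seed=99)
    c1 = simulate_cohort(cfg)
    c2 = simulate_cohort(cfg)
    assert len(c1.experiment2) == 3
    assert len(c1.experiment1) == 2 * len(EXP1_CONDITIONS)
    t1 = c1.experiment2[1].trials[2]
    t2 = c2.experiment2[1].trials[2]
    np.testing.assert_array_equal(t1.measurement.d_left, t2.measurement.d_left)
    assert t1.log.events == t2.log.events


def test_adding_participants_preserves_earlier_data():
    small = simulate_experiment2_cohort(SimConfig(n_participants=2, seed=5))
    large = simulate_experiment2_cohort(SimConfig(n_participants=4, seed=5))
    a = small.experiment2[1].trials[0]
    b = large.experiment2[1].trials[0]
    np.testing.assert_array_equal(a.measurement.d_left, b.measurement.d_left)
    assert a.log.events == b.log.events


def test_increasing_amplitude_gap_widens_mpdc_gap():
    """Ground-truth round trip: a larger hard-world amplitude raises the
    median across seeds of MPDC(hard) - MPDC(easy)."""
    gaps = []
    for amp_b in (6.0, 15.0, 30.0):
        cfg = dataclasses.replace(
            NOISELESS, phasic_amp_px={"A": 4.0, "B": amp_b})
        frame = synth_game_frame(cfg.frame_width, cfg.frame_height,
                                 cfg.frame_seed)
        deltas = []
        for seed in range(6):
            p = simulate_participant(seed, cfg)
            vals = {}
            for world in ("A", "B"):
                tt = simulate_trial_trace(p, frame, world, 60000.0,
                                          seed + 50, cfg, frame)
                merged = merge_eyes(tt.measurement)
                b = estimate_baseline(merge_eyes(tt.baseline), 2000.0)
                vals[world] = mpdc(merged, b)
            deltas.append(vals["B"] - vals["A"])
        gaps.append(np.median(deltas))
    assert gaps[0] < gaps[1] < gaps[2]
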