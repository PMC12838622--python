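import numpy as np
import pytest
from dataclasses import replace

from fatiguekit.emg import bandpass_emg, emg_envelope, emg_ft_slope
from fatiguekit.force import contraction_auc, fatigue_slope, fwhm_median, segment_contractions
from fatiguekit.synth import (
    EmgGenConfig,
    ForceGenConfig,
    MapGenConfig,
    ObjectHitConfig,
    PaddlePolicy,
    gen_emg_session,
    gen_force_session,
    gen_mvc_profile,
    gen_spatial_maps,
    simulate_object_hit,
)

SMALL_OH = ObjectHitConfig(
    objects_per_bin=8, duration=64.0, rate=100.0
)  # 16 bins x 8 = 128 = 2/s x 64 s


class TestForceGenerator:
    def test_protocol_shape(self):
        cfg = ForceGenConfig(n_cycles=270)
        trace, sched = gen_force_session(cfg, seed=0)
        assert sched.n_cycles == 270
        assert trace.duration == pytest.approx(540.0, abs=0.05)
        assert trace.rate == 47.75

    def test_noiseless_auc_identity(self):
        """Noiseless per-contraction AUCs equal the injected linear drift, so the
        fitted slope recovers drift_beta to numerical precision."""
        cfg = ForceGenConfig(n_cycles=60, drift_beta=-0.02, noise_sd=0.0)
        trace, sched = gen_force_session(cfg, seed=0)
        aucs = [contraction_auc(s) for s in segment_contractions(trace, sched)]
        a0 = cfg.target_force * cfg.pulse_area_per_unit
        np.testing.assert_allclose(aucs, a0 - 0.02 * np.arange(60), atol=1e-9)
        est = fatigue_slope(aucs, discard_first=10)
        assert est.beta == pytest.approx(-0.02, abs=1e-9)

    def test_deterministic_per_seed(self):
        cfg = ForceGenConfig(n_cycles=20, noise_sd=0.5)
        a, _ = gen_force_session(cfg, seed=5)
        b, _ = gen_force_session(cfg, seed=5)
        c, _ = gen_force_session(cfg, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_infeasible_rise_fall(self):
        with pytest.raises(ValueError):
            ForceGenConfig(rise_s=0.6, fall_s=0.6, on_s=1.0)

    def test_noisy_recovery_across_seeds(self):
        """Mean recovered slope over seeds sits within 2 Monte-Carlo SEs of the target."""
        beta = -0.02
        betas = []
        for seed in range(25):
            cfg = ForceGenConfig(n_cycles=270, drift_beta=beta, noise_sd=0.5)
            trace, sched = gen_force_session(cfg, seed=seed)
            aucs = [contraction_auc(s) for s in segment_contractions(trace, sched)]
            betas.append(fatigue_slope(aucs).beta)
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean() - beta) < 2 * se + 1e-12

    def test_mvc_profile_summary_near_amplitude(self):
        prof = gen_mvc_profile(50.0)
        m = fwhm_median(prof).median_force
        assert 25.0 <= m <= 50.0 + 1e-9


class TestEmgGenerator:
    CFG = EmgGenConfig(n_cycles=20)

    def test_gate_off_gives_near_silence(self):
        trace, _ = gen_emg_session(self.CFG, seed=0, gate_on=False)
        on_level = 1.0  # unit-RMS carrier at amplitude 1
        assert np.sqrt(np.mean(trace.values**2)) < 0.01 * on_level

    def test_deterministic(self):
        a, _ = gen_emg_session(self.CFG, seed=3)
        b, _ = gen_emg_session(self.CFG, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_zero_drift_slope_near_zero(self):
        betas = []
        for seed in range(8):
            trace, sched = gen_emg_session(self.CFG, seed=seed)
            env = emg_envelope(bandpass_emg(trace))
            betas.append(emg_ft_slope(env, sched, discard_first=5).beta)
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean()) < 3 * se + 1e-4

    def test_negative_drift_recovered(self):
        cfg = replace(self.CFG, n_cycles=40, drift_per_contraction=-0.005)
        neg = 0
        for seed in range(10):
            trace, sched = gen_emg_session(cfg, seed=seed)
            env = emg_envelope(bandpass_emg(trace))
            if emg_ft_slope(env, sched, discard_first=5).beta < 0:
                neg += 1
        assert neg >= 9


class TestObjectHitSimulator:
    def test_infeasible_schedule_rejected(self):
        with pytest.raises(ValueError):
            ObjectHitConfig(objects_per_bin=31)

    def test_quota_and_conservation(self):
        log = simulate_object_hit(SMALL_OH, seed=1)
        assert len(log.releases) == 128
        per_bin = np.bincount([r.bin for r in log.releases], minlength=16)
        assert np.all(per_bin == 8)
        assert len(log.hits) <= len(log.releases)
        assert all(0 <= h.bin < 16 for h in log.hits)
        assert all(h.time <= SMALL_OH.duration for h in log.hits)

    def test_deterministic(self):
        a = simulate_object_hit(SMALL_OH, seed=9)
        b = simulate_object_hit(SMALL_OH, seed=9)
        assert [(h.time, h.hand, h.bin) for h in a.hits] == [
            (h.time, h.hand, h.bin) for h in b.hits
        ]
        np.testing.assert_array_equal(
            a.trajectories["left"][0].values, b.trajectories["left"][0].values
        )

    def test_parked_paddles_hit_nothing(self):
        parked = PaddlePolicy(max_speed=0.0, park=(1.0, 1.0))
        cfg = replace(SMALL_OH, left=parked, right=replace(parked, park=(75.0, 1.0)))
        log = simulate_object_hit(cfg, seed=2)
        assert len(log.hits) == 0

    def test_paddles_do_hit_by_default(self):
        log = simulate_object_hit(SMALL_OH, seed=3)
        counts = {h: sum(1 for x in log.hits if x.hand == h) for h in ("left", "right")}
        assert counts["left"] > 0 and counts["right"] > 0

    def test_slower_hand_hits_less(self):
        """Halving one hand's speed cap reduces that hand's hit total."""
        fast = replace(SMALL_OH, right=PaddlePolicy(max_speed=40.0))
        slow = replace(SMALL_OH, right=PaddlePolicy(max_speed=15.0))
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            hf = sum(1 for h in simulate_object_hit(fast, seed=seed).hits if h.hand == "right")
            hs = sum(1 for h in simulate_object_hit(slow, seed=seed).hits if h.hand == "right")
            wins += hf > hs
        assert wins >= round(0.9 * n_seeds)

    def test_trajectories_within_workspace(self):
        log = simulate_object_hit(SMALL_OH, seed=4)
        for hand in ("left", "right"):
            x, y = log.trajectories[hand]
            assert np.all((x.values >= 0) & (x.values <= 76))
            assert np.all((y.values >= 0) & (y.values <= 44))


class TestMapGenerator:
    def test_deterministic(self):
        cfg = MapGenConfig(effect_rows=(2, 6), effect_cols=(2, 6), effect_size=1.0)
        a = gen_spatial_maps(cfg, seed=5)
        b = gen_spatial_maps(cfg, seed=5)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_effect_in_group_two_only(self):
        cfg = MapGenConfig(n_per_group=200, effect_rows=(5, 11), effect_cols=(5, 11),
                           effect_size=2.0)
        mset = gen_spatial_maps(cfg, seed=6)
        block = (slice(5, 11), slice(5, 11))
        g1 = mset.maps[:200][(slice(None),) + block].mean()
        g2 = mset.maps[200:][(slice(None),) + block].mean()
        assert abs(g1) < 0.2
        assert g2 == pytest.approx(2.0, abs=0.2)

    def test_region_validated(self):
        with pytest.raises(ValueError):
            MapGenConfig(height=10, effect_rows=(5, 12))
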