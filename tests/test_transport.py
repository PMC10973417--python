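"""Run segmentation, motility classification and cohort summaries."""

import numpy as np
import pytest

from dendrotrace import AnalysisConfig
from dendrotrace import synthdata as sd
from dendrotrace.transport import classify_track, segment_runs, summarize_transport
from dendrotrace.types import Run

from tests.conftest import straight_track


def run_of(direction, t0=0.0, t1=10.0, s0=0.0, s1=5.0):
    return Run(track_id=0, t_start=t0, t_end=t1, s_start=s0, s_end=s1,
               direction=direction)


class TestSegmentRuns:
    def test_monotone_track_single_run(self):
        t = np.arange(61.0)
        tr = straight_track(0, t, 0.5 * t)
        runs = segment_runs(tr)
        assert len(runs) == 1
        r = runs[0]
        assert r.direction == "anterograde"
        assert r.velocity == pytest.approx(0.5)

    def test_out_and_back_two_runs(self):
        t = np.arange(41.0)
        arc = np.concatenate([0.5 * np.arange(21), 10 - 0.5 * np.arange(1, 21)])
        runs = segment_runs(straight_track(0, t, arc))
        dirs = [r.direction for r in runs]
        assert dirs == ["anterograde", "retrograde"]

    def test_noiseless_generator_runs_recovered(self):
        """Segmentation matches the generator's own run boundaries."""
        p = sd.MotionModelParams(p_mobile=1.0, loc_noise_sd=0.0,
                                 speed_cv=0.0, p_reverse=0.5)
        tracks, truth = sd.simulate_granules(p, 15, 300.0, 400.0, seed=8)
        n_checked = 0
        for tr, true_runs in zip(tracks, truth.runs):
            got = [r for r in segment_runs(tr) if r.mobile]
            # well-resolved true runs: long enough to be sampled and
            # flanked by pauses longer than one frame
            for i, w in enumerate(true_runs):
                if (w.direction == "paused"
                        or abs(w.s_end - w.s_start) < 2.0
                        or (w.t_end - w.t_start) < 4.0):
                    continue
                match = [g for g in got
                         if g.direction == w.direction
                         and min(g.t_end, w.t_end) - max(g.t_start, w.t_start)
                         >= 0.8 * (w.t_end - w.t_start)]
                assert match, f"true run {w} not recovered"
                n_checked += 1
        assert n_checked >= 20

    def test_jitter_is_not_a_run(self):
        rng = np.random.default_rng(0)
        t = np.arange(120.0)
        tr = straight_track(0, t, 5.0 + rng.normal(0, 0.05, len(t)))
        runs = segment_runs(tr)
        assert all(not r.mobile for r in runs)


class TestClassifyTrack:
    @pytest.mark.parametrize("runs,expected", [
        ([run_of("anterograde")], "anterograde"),
        ([run_of("retrograde", s0=5.0, s1=0.0)], "retrograde"),
        ([run_of("anterograde"), run_of("paused", 10, 30, 5, 5),
          run_of("anterograde", 30, 40, 5, 10)], "interrupted"),
        ([run_of("anterograde"), run_of("retrograde", 10, 20, 5, 0)],
         "multidirectional"),
        ([run_of("paused", s1=0.0)], "stationary"),
        ([run_of("anterograde", s1=0.5), run_of("paused", 10, 20, 0.5, 0.5)],
         "stationary"),   # sub-threshold total displacement
    ])
    def test_five_way_rules(self, runs, expected):
        assert classify_track(runs, mobility_min_disp=2.0) == expected

    def test_exhaustive_single_label(self, control_cohort):
        """Every track gets exactly one of the five labels; freq sums to 100."""
        _, tracks, _, _ = control_cohort
        s = summarize_transport(tracks)
        assert set(s.class_freq) == {"stationary", "anterograde", "retrograde",
                                     "multidirectional", "interrupted"}
        assert sum(s.class_freq.values()) == pytest.approx(100.0)


class TestSummarize:
    def test_percent_mobile_simple(self):
        tracks = []
        t = np.arange(31.0)
        for i in range(6):       # mobile
            tracks.append(straight_track(i, t, 0.5 * t))
        for i in range(6, 10):   # stationary
            tracks.append(straight_track(i, t, np.full(len(t), 3.0)))
        s = summarize_transport(tracks)
        assert s.percent_mobile == pytest.approx(60.0)

    def test_no_retrograde_runs_reported_none(self):
        t = np.arange(31.0)
        s = summarize_transport([straight_track(0, t, 0.5 * t)])
        assert s.mean_v_retro is None
        assert s.mean_v_antero == pytest.approx(0.5, rel=1e-6)

    def test_velocity_recovery_control_regime(self, control_cohort):
        """Cohort velocity means recover the generator speeds within 2 SEM."""
        _, tracks, _, _ = control_cohort
        s = summarize_transport(tracks)
        assert abs(s.mean_v_antero - 0.56) <= 2 * s.sem_v_antero
        assert abs(s.mean_v_retro - 0.49) <= 2 * s.sem_v_retro

    def test_velocity_unbiased_within_3pct(self):
        """Pooled over seeds, recovery bias is below 3% at 0.05 µm noise."""
        errs_a, errs_r = [], []
        for seed in (1, 2, 3, 4):
            p = sd.MotionModelParams(loc_noise_sd=0.05)
            tracks, _ = sd.simulate_granules(p, 200, 300.0, 100.0, seed=seed)
            s = summarize_transport(tracks)
            errs_a.append(s.mean_v_antero - 0.56)
            errs_r.append(s.mean_v_retro - 0.49)
        assert abs(np.mean(errs_a)) / 0.56 < 0.03
        assert abs(np.mean(errs_r)) / 0.49 < 0.03

    def test_speed_scaling_monotonicity(self):
        """Scaling generator speeds by c scales recovered means by c (±5%)."""
        base = sd.MotionModelParams(p_mobile=1.0, loc_noise_sd=0.0)
        c = 1.5
        fast = sd.MotionModelParams(p_mobile=1.0, loc_noise_sd=0.0,
                                    v_antero=base.v_antero * c,
                                    v_retro=base.v_retro * c)
        t1, _ = sd.simulate_granules(base, 100, 300.0, 200.0, seed=13)
        t2, _ = sd.simulate_granules(fast, 100, 300.0, 200.0, seed=13)
        s1, s2 = summarize_transport(t1), summarize_transport(t2)
        assert s2.mean_v_antero / s1.mean_v_antero == pytest.approx(c, rel=0.05)
        assert s2.mean_v_retro / s1.mean_v_retro == pytest.approx(c, rel=0.05)

    def test_knockdown_regime_strictly_degraded(self):
        """Reduced p_mobile/speeds/run lengths lower every transport metric."""
        ctrl = sd.MotionModelParams()
        kd = sd.MotionModelParams(p_mobile=0.119, v_antero=0.3, v_retro=0.25,
                                  run_len_mean=4.0)
        tc, _ = sd.simulate_granules(ctrl, 250, 300.0, 100.0, seed=21)
        tk, _ = sd.simulate_granules(kd, 250, 300.0, 100.0, seed=22)
        sc, sk = summarize_transport(tc), summarize_transport(tk)
        assert sk.percent_mobile < sc.percent_mobile
        assert sk.mean_v_antero < sc.mean_v_antero
        assert sk.mean_v_retro < sc.mean_v_retro

    def test_group_sem_across_neurons(self):
        t = np.arange(31.0)
        tracks = [straight_track(i, t, (0.4 + 0.1 * (i % 2)) * t)
                  for i in range(8)]
        s_track = summarize_transport(tracks)
        s_neuron = summarize_transport(tracks, group_ids=[i % 2 for i in range(8)])
        assert s_neuron.mean_v_antero == pytest.approx(s_track.mean_v_antero)
        assert s_neuron.sem_v_antero != s_track.sem_v_antero
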