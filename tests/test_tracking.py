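"""Spot detection, linking, path projection and kymographs."""

import numpy as np
import pytest

from dendrotrace import synthdata as sd
from dendrotrace.tracking import (Detection, build_kymograph, detect_spots,
                                  link_tracks, project_to_path)
from dendrotrace.types import DendritePath, FrameStack

from tests.conftest import straight_track


def render_single_spot(x, y, **kw):
    tr = straight_track(0, [0.0], [x], y=y)
    tr.x = np.array([x])
    rp = sd.RenderParams(**kw)
    return sd.render_stack([tr], rp, seed=0)


class TestDetect:
    def test_noiseless_spot_centroid(self):
        """One clean Gaussian spot -> one detection within 0.05 µm."""
        stack = render_single_spot(5.0, 4.0, background=0.0,
                                   read_noise_sd=0.0, poisson_noise=False,
                                   photon_scale=1000.0)
        dets = detect_spots(stack, 0.25, snr_min=5.0)
        assert len(dets) == 1
        assert dets[0].x == pytest.approx(5.0, abs=0.05)
        assert dets[0].y == pytest.approx(4.0, abs=0.05)

    def test_noisy_spot_centroid_within_point1_um(self):
        stack = render_single_spot(5.0, 4.0, background=10.0,
                                   photon_scale=500.0)
        dets = detect_spots(stack, 0.25, snr_min=5.0)
        assert len(dets) >= 1
        best = min(dets, key=lambda d: (d.x - 5.0) ** 2 + (d.y - 4.0) ** 2)
        assert np.hypot(best.x - 5.0, best.y - 4.0) < 0.1

    def test_resolved_pair(self):
        """Two spots 4 sigma apart are detected separately."""
        sep = 4 * 0.25
        t1 = straight_track(0, [0.0], [3.0], y=3.0)
        t2 = straight_track(1, [0.0], [3.0 + sep], y=3.0)
        rp = sd.RenderParams(background=0.0, read_noise_sd=0.0,
                             poisson_noise=False, photon_scale=1000.0)
        stack = sd.render_stack([t1, t2], rp, seed=0)
        dets = detect_spots(stack, 0.25, snr_min=3.0)
        assert len(dets) == 2

    def test_false_positive_rate_on_pure_noise(self):
        """SNR gate keeps false positives below 0.1 per frame."""
        rng = np.random.default_rng(1)
        data = rng.poisson(10.0, (100, 48, 48)).astype(float) \
            + rng.normal(0, 1.0, (100, 48, 48))
        stack = FrameStack(data=data, pixel_size=0.16, frame_interval=1.0)
        dets = detect_spots(stack, 0.25, snr_min=5.0)
        assert len(dets) / 100 < 0.1

    def test_translation_equivariance(self):
        """Shifting the image by whole pixels shifts centroids identically."""
        stack = render_single_spot(5.0, 4.0, background=0.0,
                                   read_noise_sd=0.0, poisson_noise=False,
                                   photon_scale=1000.0)
        shifted = FrameStack(data=np.roll(stack.data, (3, 5), axis=(1, 2)),
                             pixel_size=stack.pixel_size,
                             frame_interval=1.0, origin=stack.origin)
        d0 = detect_spots(stack, 0.25, 5.0)[0]
        d1 = detect_spots(shifted, 0.25, 5.0)[0]
        assert d1.x - d0.x == pytest.approx(5 * 0.16, abs=1e-6)
        assert d1.y - d0.y == pytest.approx(3 * 0.16, abs=1e-6)

    def test_empty_stack(self):
        stack = FrameStack(data=np.zeros((0, 8, 8)), pixel_size=0.16,
                           frame_interval=1.0)
        assert detect_spots(stack, 0.25, 5.0) == []


class TestLink:
    def test_single_granule_single_track(self):
        dets = [Detection(f, 1.0 + 0.3 * f, 2.0, 100.0, 10.0)
                for f in range(20)]
        tracks = link_tracks(dets, 1.2, 2)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_crossing_granules_minimal_total_displacement(self):
        """At a crossing, the optimal (not greedy) assignment is chosen."""
        dets = []
        for f in range(11):
            xa = 0.5 * f          # rightward granule
            xb = 5.0 - 0.5 * f    # leftward granule
            dets.append(Detection(f, xa, 0.0, 100.0, 10.0))
            dets.append(Detection(f, xb, 1.0, 100.0, 10.0))
        tracks = link_tracks(dets, 1.2, 0)
        assert len(tracks) == 2
        # brute force: per frame pair the two possible assignments cost
        # (straight) 2*0.5 vs (swap) ~sqrt(0.5^2+1)+...; straight wins,
        # so each track keeps a constant y
        for tr in tracks:
            assert np.ptp(tr.y) == pytest.approx(0.0, abs=1e-9)

    def test_gap_closing(self):
        dets = [Detection(f, 0.1 * f, 0.0, 100.0, 10.0)
                for f in range(20) if f != 10]
        tracks = link_tracks(dets, 1.2, max_gap=2)
        assert len(tracks) == 1
        assert 10 not in tracks[0].frames

    def test_no_two_detections_same_frame_one_track(self):
        rng = np.random.default_rng(2)
        dets = [Detection(f, float(rng.uniform(0, 10)), 0.0, 100.0, 10.0)
                for f in range(30) for _ in range(3)]
        for tr in link_tracks(dets, 1.2, 2):
            assert len(np.unique(tr.frames)) == len(tr.frames)

    def test_link_accuracy_on_simulated_cohort(self):
        """>= 95% of frame-to-frame links match ground-truth identities."""
        p = sd.MotionModelParams(p_mobile=0.5)
        tracks, _ = sd.simulate_granules(p, 12, 60.0, 60.0, seed=17)
        # ground-truth positions with identities; link from detections
        dets = []
        for tr in tracks:
            for k in range(len(tr)):
                dets.append(Detection(int(tr.frames[k]), float(tr.x[k]),
                                      float(tr.id), 100.0, 10.0))
        # y encodes identity but linking must not use it: strip to a copy
        truth_xy = {(d.frame, round(d.x, 6)): int(d.y) for d in dets}
        stripped = [Detection(d.frame, d.x, 0.0, d.intensity, d.snr)
                    for d in dets]
        linked = link_tracks(stripped, 1.2, 2)
        good = bad = 0
        for tr in linked:
            ids = [truth_xy.get((int(f), round(x, 6)))
                   for f, x in zip(tr.frames, tr.x)]
            for a, b in zip(ids, ids[1:]):
                if a is None or b is None:
                    continue
                good += a == b
                bad += a != b
        assert good / (good + bad) >= 0.95


class TestProjectionAndKymograph:
    def test_orthogonal_projection_on_straight_path(self):
        path = DendritePath(np.array([[0.0, 0.0], [20.0, 0.0]]))
        tr = straight_track(0, [0.0, 1.0], [7.0, 7.5], y=0.2)
        tr.arc = None
        out = project_to_path([tr], path, corridor_halfwidth=1.5)
        assert out[0].arc[0] == pytest.approx(7.0)

    def test_off_corridor_detection_excluded(self):
        path = DendritePath(np.array([[0.0, 0.0], [20.0, 0.0]]))
        from dendrotrace.types import Track
        tr = Track(id=0, frames=np.arange(3), t=np.arange(3.0),
                   x=np.array([5.0, 6.0, 7.0]),
                   y=np.array([0.1, 5.0, 0.1]))
        out = project_to_path([tr], path)
        assert len(out[0]) == 2

    def test_kymograph_ridge_slope_matches_velocity(self):
        """A constant-velocity granule traces a ridge of slope v."""
        v = 0.5
        t = np.arange(20.0)
        tr = straight_track(0, t, 2.0 + v * t, y=3.0)
        rp = sd.RenderParams(background=0.0, read_noise_sd=0.0,
                             poisson_noise=False, photon_scale=1000.0)
        stack = sd.render_stack([tr], rp, seed=0)
        path = DendritePath(np.array([[stack.origin[0], 3.0],
                                      [stack.origin[0] + 16.0, 3.0]]))
        kymo = build_kymograph(stack, path, bin_size=0.5)
        ridge = kymo.data.argmax(axis=0) * kymo.bin_size
        slope = np.polyfit(t, ridge, 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_stationary_granule_constant_ridge(self):
        t = np.arange(10.0)
        tr = straight_track(0, t, np.full(10, 5.0), y=3.0)
        rp = sd.RenderParams(background=0.0, read_noise_sd=0.0,
                             poisson_noise=False, photon_scale=1000.0)
        stack = sd.render_stack([tr], rp, seed=0)
        path = DendritePath(np.array([[stack.origin[0], 3.0],
                                      [stack.origin[0] + 10.0, 3.0]]))
        kymo = build_kymograph(stack, path, bin_size=0.5)
        ridge = kymo.data.argmax(axis=0)
        assert len(set(ridge.tolist())) == 1
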