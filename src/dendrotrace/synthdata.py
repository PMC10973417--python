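"""Synthetic imaging data with known ground truth.

Every analysis stage in this package is validated by parameter recovery:
the generators here produce granule trajectories, rendered timelapse
stacks, spine-volume transients, donor photon decays, dendritic skeletons
and protected-fragment coverage profiles whose generating parameters are
recorded, so the corresponding estimator can be checked against truth.

Granule motion is a continuous-time semi-Markov switching model over
{paused, anterograde, retrograde}: run speeds are log-normal around the
direction mean, run lengths exponential, pauses exponential in duration
and entered at a constant hazard during runs.  A mobile granule crossing
a spine that is already occupied by another granule reverses with a
configurable probability, emulating occupancy-dependent turnaround at
spines.  Trajectories are sampled at the frame interval and corrupted
with Gaussian localization noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import (ANTEROGRADE, PAUSED, RETROGRADE, CoverageProfile,
                    FrameStack, PhotonHistogram, Run, Skeleton, Track,
                    VolumeTrace)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MotionModelParams:
    """Kinetic parameters of the granule state-switching model.

    Defaults describe the control regime: ~36 % of granules mobile over a
    5-min recording, anterograde runs averaging 0.56 µm/s and retrograde
    0.49 µm/s.
    """

    p_mobile: float = 0.357        # probability a granule is ever mobile
    v_antero: float = 0.56         # µm/s mean anterograde run speed
    v_retro: float = 0.49          # µm/s mean retrograde run speed
    speed_cv: float = 0.3          # coefficient of variation of run speeds
    run_len_mean: float = 8.0      # µm mean run length
    pause_rate: float = 0.05       # 1/s hazard of pausing mid-run
    pause_dur_mean: float = 10.0   # s mean pause duration
    p_reverse: float = 0.3         # baseline reversal probability at run end
    p_reverse_at_spine: float = 0.5  # reversal probability at an occupied spine
    frame_interval: float = 1.0    # s
    loc_noise_sd: float = 0.05     # µm localization noise

    def validate(self) -> None:
        probs = (self.p_mobile, self.p_reverse, self.p_reverse_at_spine)
        if not all(np.isfinite(p) and 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be finite and in [0, 1]")
        pos = (self.v_antero, self.v_retro, self.run_len_mean,
               self.frame_interval)
        if not all(np.isfinite(v) and v > 0 for v in pos):
            raise ValueError("speeds, run length and frame interval must be > 0")
        nonneg = (self.speed_cv, self.pause_rate, self.pause_dur_mean,
                  self.loc_noise_sd)
        if not all(np.isfinite(v) and v >= 0 for v in nonneg):
            raise ValueError("rates, CV and noise must be finite and >= 0")


@dataclass
class RenderParams:
    """Parameters mapping arc-space tracks onto a rendered image stack."""

    pixel_size: float = 0.16       # µm
    psf_sigma: float = 0.25        # µm
    photon_scale: float = 500.0    # expected photons per granule
    background: float = 10.0       # expected background photons per pixel
    read_noise_sd: float = 1.0     # counts
    shape: tuple | None = None     # (H, W) pixels; derived from tracks if None
    origin: tuple = (0.0, 0.0)     # µm position of pixel (0, 0); used with shape
    poisson_noise: bool = True

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")
        if self.pixel_size >= 2 * self.psf_sigma:
            warnings.warn("pixel size >= 2*psf_sigma: PSF is undersampled",
                          stacklevel=3)


@dataclass
class TrueRun:
    """One generator-side run or pause (exact, un-sampled)."""

    t_start: float
    t_end: float
    s_start: float
    s_end: float
    direction: str
    speed: float                   # drawn speed, 0 for pauses


@dataclass
class GroundTruth:
    """Generator-side record of what was simulated."""

    labels: list = field(default_factory=list)       # per-granule TrackClass label
    runs: list = field(default_factory=list)         # per-granule list of TrueRun
    mobile: list = field(default_factory=list)       # per-granule bool (>=1 mobile run)
    spine_occupancy: dict = field(default_factory=dict)   # spine idx -> [(t0, t1)]
    reversal_events: list = field(default_factory=list)   # (granule, spine, t, occupied)

    @property
    def mobile_fraction(self) -> float:
        return float(np.mean(self.mobile)) if self.mobile else 0.0


# ---------------------------------------------------------------------------
# granule trajectories
# ---------------------------------------------------------------------------

def _draw_speed(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal speed with the given mean and coefficient of variation."""
    if cv == 0:
        return mean
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _classify_true_runs(runs: list[TrueRun], mobility_min_disp: float = 2.0) -> str:
    mobile = [r for r in runs if r.direction != PAUSED]
    if not mobile or sum(abs(r.s_end - r.s_start) for r in mobile) < mobility_min_disp:
        return "stationary"
    dirs = {r.direction for r in mobile}
    if len(dirs) == 2:
        return "multidirectional"
    # single direction: look for a pause strictly between mobile runs
    idx = [i for i, r in enumerate(runs) if r.direction != PAUSED]
    interior = runs[idx[0] + 1: idx[-1]]
    if any(r.direction == PAUSED for r in interior):
        return "interrupted"
    return ANTEROGRADE if dirs == {ANTEROGRADE} else RETROGRADE


def simulate_granules(params: MotionModelParams, n_granules: int,
                      duration: float, dendrite_length: float,
                      spine_positions=(), seed: int = 0,
                      docking_radius: float = 2.5,
                      mobility_min_disp: float = 2.0):
    """Simulate granule trajectories on the arc-length axis.

    Returns ``(tracks, truth)``.  Tracks are sampled at
    ``params.frame_interval`` with Gaussian localization noise and clipped
    to ``[0, dendrite_length]``; the x/y coordinates place the dendrite on
    a straight horizontal line so tracks can be rendered directly.

    Stationary granules dock near a spine half of the time (when spines
    are given), so spine occupancy is present at baseline.  A mobile
    granule reaching a spine occupied at that moment by another granule
    reverses with ``p_reverse_at_spine``.
    """
    params.validate()
    if duration / params.frame_interval < 2:
        raise ValueError("recording must cover at least 2 frames")
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be > 0")
    rng = np.random.default_rng(seed)
    spine_positions = np.asarray(spine_positions, dtype=float)

    times = np.arange(0.0, duration + 0.5 * params.frame_interval,
                      params.frame_interval)
    times = times[times <= duration]
    frames = np.arange(len(times))

    truth = GroundTruth()
    # granule -> list of (t, s) breakpoints of the exact piecewise-linear path
    paths: list[list[tuple[float, float, float]]] = []  # (t0, s0, v) segments
    mobile_flags = rng.random(n_granules) < params.p_mobile

    # --- pass 1: stationary granules (they define baseline spine occupancy)
    start_pos = np.empty(n_granules)
    for g in range(n_granules):
        if mobile_flags[g]:
            start_pos[g] = rng.uniform(0.0, dendrite_length)
        elif len(spine_positions) and rng.random() < 0.5:
            sp = spine_positions[rng.integers(len(spine_positions))]
            start_pos[g] = float(np.clip(sp + rng.uniform(-1.0, 1.0),
                                         0.0, dendrite_length))
        else:
            start_pos[g] = rng.uniform(0.0, dendrite_length)

    occupied_all = np.zeros(len(spine_positions), dtype=bool)
    for g in range(n_granules):
        if not mobile_flags[g] and len(spine_positions):
            occupied_all |= np.abs(spine_positions - start_pos[g]) <= docking_radius

    # --- pass 2: trajectories
    for g in range(n_granules):
        s0 = start_pos[g]
        runs: list[TrueRun] = []
        segs: list[tuple[float, float, float]] = []
        if not mobile_flags[g]:
            segs.append((0.0, s0, 0.0))
            paths.append(segs)
            truth.runs.append(runs)
            truth.mobile.append(False)
            truth.labels.append("stationary")
            continue

        t, s = 0.0, s0
        direction = 1 if rng.random() < 0.5 else -1
        terminal = False
        while t < duration and not terminal:
            v_mean = params.v_antero if direction > 0 else params.v_retro
            speed = _draw_speed(rng, v_mean, params.speed_cv)
            run_len = rng.exponential(params.run_len_mean)
            t_pause = (rng.exponential(1.0 / params.pause_rate)
                       if params.pause_rate > 0 else np.inf)
            dt_run = run_len / speed
            # first spine (occupied at baseline) ahead within this run
            dt_spine, spine_hit = np.inf, -1
            if len(spine_positions):
                ahead = ((spine_positions - s) * direction > 1e-9) & occupied_all
                if ahead.any():
                    dists = (spine_positions[ahead] - s) * direction
                    k = int(np.argmin(dists))
                    cand_dt = dists[k] / speed
                    if cand_dt < min(dt_run, t_pause):
                        if rng.random() < params.p_reverse_at_spine:
                            dt_spine = cand_dt
                            spine_hit = int(np.flatnonzero(ahead)[k])
            # boundary
            s_lim = dendrite_length if direction > 0 else 0.0
            dt_edge = (s_lim - s) / (speed * direction)
            dt = min(dt_run, t_pause, dt_spine, dt_edge, duration - t)
            s_new = s + direction * speed * dt
            segs.append((t, s, direction * speed))
            runs.append(TrueRun(t, t + dt, s, s_new,
                                ANTEROGRADE if direction > 0 else RETROGRADE,
                                speed))
            t, s = t + dt, s_new
            if t >= duration:
                break
            if dt == dt_edge:
                # ran off the imaged region: hold at the boundary
                segs.append((t, s, 0.0))
                if t < duration:
                    runs.append(TrueRun(t, duration, s, s, PAUSED, 0.0))
                terminal = True
            elif dt == dt_spine:
                occupied = bool(occupied_all[spine_hit])
                truth.reversal_events.append((g, spine_hit, t, occupied))
                direction = -direction
            elif dt == t_pause or dt == dt_run:
                paused_for = rng.exponential(params.pause_dur_mean)
                pause_end = min(t + paused_for, duration)
                segs.append((t, s, 0.0))
                runs.append(TrueRun(t, pause_end, s, s, PAUSED, 0.0))
                t = pause_end
                if dt == dt_run and rng.random() < params.p_reverse:
                    direction = -direction
        paths.append(segs)
        truth.runs.append(runs)
        truth.mobile.append(any(r.direction != PAUSED for r in runs))
        truth.labels.append(_classify_true_runs(runs, mobility_min_disp))

    # --- sample at frame times and add localization noise
    tracks = []
    true_arcs = np.empty((n_granules, len(times)))
    for g, segs in enumerate(paths):
        seg_t = np.array([seg[0] for seg in segs])
        idx = np.clip(np.searchsorted(seg_t, times, side="right") - 1,
                      0, len(segs) - 1)
        arc = np.array([segs[i][1] + segs[i][2] * (tt - segs[i][0])
                        for i, tt in zip(idx, times)])
        true_arcs[g] = np.clip(arc, 0.0, dendrite_length)
        noisy = true_arcs[g] + rng.normal(0.0, params.loc_noise_sd, len(times))
        noisy = np.clip(noisy, 0.0, dendrite_length)
        tracks.append(Track(id=g, frames=frames.copy(), t=times.copy(),
                            x=noisy.copy(), y=np.zeros_like(noisy),
                            arc=noisy))

    # --- exact spine occupancy intervals from the true (noiseless) paths
    for k, sp in enumerate(spine_positions):
        inside = np.abs(true_arcs - sp) <= docking_radius   # (granule, frame)
        any_in = inside.any(axis=0)
        truth.spine_occupancy[k] = _bool_to_intervals(any_in, times)

    return tracks, truth


def _bool_to_intervals(mask: np.ndarray, times: np.ndarray) -> list:
    """Merge a boolean per-frame mask into (t_start, t_end) intervals."""
    out, start = [], None
    for m, tt in zip(mask, times):
        if m and start is None:
            start = tt
        elif not m and start is not None:
            out.append((start, tt))
            start = None
    if start is not None:
        out.append((start, float(times[-1])))
    return out


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def render_stack(tracks, rp: RenderParams, seed: int = 0,
                 frame_interval: float = 1.0) -> FrameStack:
    """Render tracks as Gaussian spots with Poisson + read noise.

    Each granule contributes ``photon_scale`` expected photons spread as a
    2-D Gaussian of sd ``psf_sigma`` centred at its subpixel position.
    """
    rp.validate()
    rng = np.random.default_rng(seed)
    n_frames = max((int(t.frames[-1]) + 1 for t in tracks), default=1)
    margin = 6 * rp.psf_sigma
    if rp.shape is None:
        xmin = min((float(t.x.min()) for t in tracks), default=0.0)
        ymin = min((float(t.y.min()) for t in tracks), default=0.0)
        xmax = max((float(t.x.max()) for t in tracks), default=0.0)
        ymax = max((float(t.y.max()) for t in tracks), default=0.0)
        origin = (xmin - margin, ymin - margin)
        H = int(np.ceil((ymax - ymin + 2 * margin) / rp.pixel_size)) + 1
        W = int(np.ceil((xmax - xmin + 2 * margin) / rp.pixel_size)) + 1
    else:
        H, W = rp.shape
        origin = rp.origin
    sig_px = rp.psf_sigma / rp.pixel_size
    norm = rp.photon_scale / (2 * np.pi * sig_px ** 2)
    half = int(np.ceil(4 * sig_px))

    signal = np.zeros((n_frames, H, W))
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.x, tr.y):
            cx = (x - origin[0]) / rp.pixel_size
            cy = (y - origin[1]) / rp.pixel_size
            r0, r1 = int(cy) - half, int(cy) + half + 1
            c0, c1 = int(cx) - half, int(cx) + half + 1
            r0, r1 = max(r0, 0), min(r1, H)
            c0, c1 = max(c0, 0), min(c1, W)
            if r0 >= r1 or c0 >= c1:
                continue
            rows = np.arange(r0, r1)
            cols = np.arange(c0, c1)
            g = np.exp(-((rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2)
                       / (2 * sig_px ** 2))
            signal[int(f), r0:r1, c0:c1] += norm * g

    expected = signal + rp.background
    if rp.poisson_noise:
        data = rng.poisson(expected).astype(float)
    else:
        data = expected
    if rp.read_noise_sd > 0:
        data = data + rng.normal(0.0, rp.read_noise_sd, data.shape)
    return FrameStack(data=data, pixel_size=rp.pixel_size,
                      frame_interval=frame_interval, origin=tuple(origin))


# ---------------------------------------------------------------------------
# structural plasticity traces
# ---------------------------------------------------------------------------

def simulate_volume_trace(amp_transient: float, amp_sustained: float,
                          tau_decay: float = 120.0, t_stim: float = 60.0,
                          duration: float = 2100.0,
                          frame_interval: float = 1.5,
                          noise_sd: float = 0.0, seed: int = 0,
                          rise_time: float = 90.0) -> VolumeTrace:
    """Spine-volume transient: baseline, linear rise, exponential relaxation.

    The trace is 100 % before the first uncaging pulse, rises linearly to
    ``100 + amp_transient`` % at ``rise_time`` seconds after the pulse
    (the +1.5 min transient read-out), then relaxes exponentially with
    time constant ``tau_decay`` toward the ``100 + amp_sustained`` %
    plateau.  Amplitudes are percent of baseline volume.
    """
    if t_stim >= duration:
        raise ValueError("t_stim must precede the end of the recording")
    if amp_transient < -100 or amp_sustained < -100:
        raise ValueError("amplitudes below -100% are unphysical")
    rng = np.random.default_rng(seed)
    t_abs = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    t_abs = t_abs[t_abs <= duration]
    t = t_abs - t_stim
    v = np.full_like(t, 100.0)
    rising = (t > 0) & (t <= rise_time)
    v[rising] = 100.0 + amp_transient * t[rising] / rise_time
    after = t > rise_time
    v[after] = (100.0 + amp_sustained
                + (amp_transient - amp_sustained)
                * np.exp(-(t[after] - rise_time) / tau_decay))
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return VolumeTrace(t=t, v=v, baseline_window=(-t_stim, 0.0),
                       rate_hz=1.0 / frame_interval)


# ---------------------------------------------------------------------------
# FLIM photon decays
# ---------------------------------------------------------------------------

def simulate_photon_histogram(tau_free: float, tau_bound: float,
                              bound_fraction: float, n_photons: int,
                              bin_width: float = 0.05, n_bins: int = 500,
                              seed: int = 0, epoch: str = "pre") -> PhotonHistogram:
    """Photon arrival histogram from a two-state donor-lifetime mixture.

    Arrival times are exponential with lifetime ``tau_bound`` for the
    FRET-engaged fraction and ``tau_free`` otherwise; photons past the
    histogram range are discarded.
    """
    if not 0 <= bound_fraction <= 1:
        raise ValueError("bound_fraction must be in [0, 1]")
    if tau_free <= 0 or tau_bound <= 0:
        raise ValueError("lifetimes must be > 0")
    t_range = n_bins * bin_width
    if t_range < 3 * max(tau_free, tau_bound):
        warnings.warn("histogram range < 3 lifetimes: decay is truncated",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n_bound = rng.binomial(n_photons, bound_fraction)
    arrivals = np.concatenate([
        rng.exponential(tau_bound, n_bound),
        rng.exponential(tau_free, n_photons - n_bound),
    ])
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(arrivals, bins=edges)
    return PhotonHistogram(bin_edges=edges, counts=counts.astype(float),
                           epoch=epoch)


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

def simulate_skeleton(n_primary: int, branch_prob_per_10um: float,
                      max_radius: float, seed: int = 0,
                      step: float = 1.0, jitter_sd: float = 0.08) -> Skeleton:
    """Planar rooted dendritic tree grown outward from the soma.

    Each of ``n_primary`` primary dendrites grows radially in ``step`` µm
    increments with small angular jitter (radial distance is enforced to
    increase, so every circle below a tip's extent is crossed exactly
    once per tip), branching with probability ``branch_prob_per_10um``
    per 10 µm of growth, and stops at ``max_radius``.
    """
    if n_primary < 1:
        raise ValueError("need at least one primary dendrite")
    rng = np.random.default_rng(seed)
    ids = [1]
    xyz = [(0.0, 0.0, 0.0)]
    radius = [5.0]
    parent = [-1]
    ntype = [1]
    next_id = 2
    p_branch_step = branch_prob_per_10um * step / 10.0

    # active tips: (node_id, position 2-vector, unit direction)
    tips = []
    base_angles = np.linspace(0.0, 2 * np.pi, n_primary, endpoint=False)
    base_angles = base_angles + rng.uniform(0, 2 * np.pi)
    for ang in base_angles:
        tips.append((1, np.zeros(2), np.array([np.cos(ang), np.sin(ang)])))

    while tips:
        new_tips = []
        for node, pos, dirv in tips:
            r_now = np.hypot(*pos)
            if r_now >= max_radius:
                continue
            ang = np.arctan2(dirv[1], dirv[0]) + rng.normal(0.0, jitter_sd)
            d = np.array([np.cos(ang), np.sin(ang)])
            cand = pos + step * d
            if np.hypot(*cand) <= r_now:      # keep growth strictly outward
                radial = pos / r_now if r_now > 0 else d
                cand = pos + step * radial
                d = radial
            if np.hypot(*cand) > max_radius:  # stop exactly at the extent
                radial = cand / np.hypot(*cand)
                cand = radial * max_radius
            ids.append(next_id)
            xyz.append((float(cand[0]), float(cand[1]), 0.0))
            radius.append(0.5)
            parent.append(node)
            ntype.append(3)
            child = next_id
            next_id += 1
            if np.hypot(*cand) >= max_radius:
                continue
            if rng.random() < p_branch_step:
                for sign in (+1, -1):
                    a2 = np.arctan2(d[1], d[0]) + sign * rng.uniform(0.3, 0.6)
                    new_tips.append((child, cand.copy(),
                                     np.array([np.cos(a2), np.sin(a2)])))
            else:
                new_tips.append((child, cand.copy(), d))
        tips = new_tips

    return Skeleton(ids=np.array(ids), xyz=np.array(xyz),
                    radius=np.array(radius), parent=np.array(parent),
                    node_type=np.array(ntype))


# ---------------------------------------------------------------------------
# protected-fragment coverage
# ---------------------------------------------------------------------------

def simulate_coverage(transcript_length: int, protected_intervals,
                      peak_height=100.0, floor: float = 2.0,
                      noise_sd: float = 0.0, seed: int = 0) -> CoverageProfile:
    """Box-shaped coverage peaks over protected intervals (1-based inclusive).

    ``peak_height`` may be a scalar or one value per interval (minor
    fragments typically attract far fewer reads than the major one).
    """
    rng = np.random.default_rng(seed)
    intervals = [(int(a), int(b)) for a, b in protected_intervals]
    heights = (list(np.broadcast_to(peak_height, len(intervals)))
               if intervals else [])
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    intervals = [intervals[i] for i in order]
    heights = [float(heights[i]) for i in order]
    for a, b in intervals:
        if a < 1 or b > transcript_length or a > b:
            raise ValueError(f"interval ({a}, {b}) outside [1, {transcript_length}]")
    merged: list[list] = []
    for (a, b), h in zip(intervals, heights):
        if merged and a <= merged[-1][1]:
            warnings.warn(f"overlapping protected intervals merged at {a}",
                          stacklevel=2)
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2] = max(merged[-1][2], h)
        else:
            merged.append([a, b, h])
    depth = np.full(transcript_length, float(floor))
    for a, b, h in merged:
        depth[a - 1:b] += h
    if noise_sd > 0:
        depth = depth + rng.normal(0.0, noise_sd, depth.shape)
    return CoverageProfile(depth=np.clip(depth, 0.0, None))
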