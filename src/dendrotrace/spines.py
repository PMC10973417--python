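"""Granule behavior relative to PSD95-marked spines.

The docking taxonomy uses a fixed proximity radius (default 2.5 µm)
around each PSD95 punctum on the arc axis:

* ``docked`` — the granule stays within the radius for the entire
  recording;
* ``docking`` — the granule moves to the spine and then resides within
  the radius, either continuously for at least ``residence_min`` seconds
  or through the end of the recording;
* ``undocking`` — a granule that begins inside the radius and is
  stationary there for at least ``residence_min`` seconds then exits and
  travels away;
* ``direction_change`` — a mobile granule reverses its run direction
  while inside the radius.

Recruitment to a stimulated spine is scored two ways: the change in
granule count within a ±5 µm window from just before stimulation to 5
minutes after, and the number of granules in a ±25 µm region whose net
motion in the 5 minutes after stimulation is toward the spine.
"""

from __future__ import annotations

import logging

import numpy as np

from .transport import segment_runs
from .types import PAUSED, DockEvent, SpineSite, Track

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# docking taxonomy
# ---------------------------------------------------------------------------

def _arc(track: Track) -> np.ndarray:
    return track.arc if track.arc is not None else track.x


def classify_dock(track: Track, spine: SpineSite, radius: float = 2.5,
                  residence_min: float = 10.0,
                  run_min_disp: float = 1.0,
                  pause_max_speed: float = 0.1) -> list[DockEvent]:
    """Classify one track's behavior at one spine (possibly several events)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    s = _arc(track)
    t = track.t
    inside = np.abs(s - spine.arc) <= radius
    events: list[DockEvent] = []

    if inside.all():
        return [DockEvent(track.id, spine.id, "docked", float(t[0]))]

    runs = segment_runs(track, run_min_disp, pause_max_speed)

    # --- docking: enters the radius and resides (stationary) there.
    # Residence must be a paused spell, not a slow transit: either the
    # track stays inside through the end of the recording, or a pause of
    # at least residence_min lies fully inside the radius after entry.
    if not inside[0]:
        entries = np.flatnonzero(~inside[:-1] & inside[1:]) + 1
        for e in entries:
            exits_after = np.flatnonzero(~inside[e:])
            if len(exits_after) == 0:
                events.append(DockEvent(track.id, spine.id, "docking",
                                        float(t[e])))
                break
            stay_end = e + exits_after[0] - 1
            resident_pause = any(
                r.direction == PAUSED
                and r.t_start >= t[e] - 1e-9 and r.t_end <= t[stay_end] + 1e-9
                and (r.t_end - r.t_start) >= residence_min
                for r in runs)
            if resident_pause:
                events.append(DockEvent(track.id, spine.id, "docking",
                                        float(t[e])))
                break

    # --- undocking: begins inside, stationary >= residence_min, then leaves
    if inside[0]:
        exit_idx = np.flatnonzero(~inside)
        if len(exit_idx):
            e = exit_idx[0]
            stationary_spell = t[e - 1] - t[0] if e > 0 else 0.0
            initial_paused = any(
                r.direction == PAUSED and r.t_start <= t[0] + 1e-9
                and (r.t_end - r.t_start) >= residence_min
                for r in runs)
            if stationary_spell >= residence_min and initial_paused:
                events.append(DockEvent(track.id, spine.id, "undocking",
                                        float(t[e])))

    # --- direction change inside the radius
    mobile = [r for r in runs if r.mobile]
    for r1, r2 in zip(mobile, mobile[1:]):
        if r1.direction != r2.direction:
            t_rev = r2.t_start
            k = int(np.argmin(np.abs(t - t_rev)))
            if inside[k]:
                events.append(DockEvent(track.id, spine.id,
                                        "direction_change", float(t_rev)))
    return events


def dock_events(tracks: list[Track], spines: list[SpineSite],
                radius: float = 2.5, residence_min: float = 10.0,
                **kw) -> list[DockEvent]:
    out = []
    for tr in tracks:
        for sp in spines:
            out.extend(classify_dock(tr, sp, radius, residence_min, **kw))
    return out


# ---------------------------------------------------------------------------
# occupancy and reversal at occupied spines
# ---------------------------------------------------------------------------

def occupancy_intervals(tracks: list[Track], spine: SpineSite,
                        radius: float = 2.5,
                        exclude_track: int | None = None) -> list[tuple]:
    """(t0, t1) intervals during which >= 1 granule is within the radius."""
    masks, times = [], None
    for tr in tracks:
        if exclude_track is not None and tr.id == exclude_track:
            continue
        if times is None:
            times = tr.t
        masks.append(np.abs(_arc(tr) - spine.arc) <= radius)
    if not masks or times is None:
        return []
    n = min(len(m) for m in masks)
    any_in = np.any([m[:n] for m in masks], axis=0)
    out, start = [], None
    for m, tt in zip(any_in, times[:n]):
        if m and start is None:
            start = float(tt)
        elif not m and start is not None:
            out.append((start, float(tt)))
            start = None
    if start is not None:
        out.append((start, float(times[n - 1])))
    return out


def occupied_reversal_fraction(tracks: list[Track], spines: list[SpineSite],
                               radius: float = 2.5, **kw) -> float | None:
    """Percent of at-spine direction changes where the spine was occupied.

    A spine counts as occupied at a reversal if a *different* granule is
    within the radius at the event time.  Returns ``None`` (logged) when
    no direction-change events exist.
    """
    n_total = n_occ = 0
    for tr in tracks:
        for sp in spines:
            evts = [e for e in classify_dock(tr, sp, radius, **kw)
                    if e.kind == "direction_change"]
            for e in evts:
                n_total += 1
                for other in tracks:
                    if other.id == tr.id:
                        continue
                    k = int(np.argmin(np.abs(other.t - e.t_event)))
                    if abs(_arc(other)[k] - sp.arc) <= radius:
                        n_occ += 1
                        break
    if n_total == 0:
        log.info("no direction-change events at spines: fraction undefined")
        return None
    return 100.0 * n_occ / n_total


# ---------------------------------------------------------------------------
# recruitment to stimulated spines
# ---------------------------------------------------------------------------

def recruitment(tracks: list[Track], spine: SpineSite,
                near_halfwidth: float = 5.0, region_halfwidth: float = 25.0,
                post_window: float = 300.0, run_min_disp: float = 1.0):
    """Granule recruitment around a stimulated spine.

    Returns a dict with ``delta_count_near`` (change in the number of
    granules within ±``near_halfwidth`` µm from just before stimulation
    to ``post_window`` s after) and ``n_toward`` (granules within the
    ±``region_halfwidth`` µm region whose net displacement over the post
    window reduces the distance to the spine by at least
    ``run_min_disp``).
    """
    if spine.t_stim is None:
        raise ValueError("spine has no stimulation time")
    t0 = spine.t_stim
    t1 = t0 + post_window
    n_pre = n_post = n_toward = 0
    for tr in tracks:
        s = _arc(tr)
        k0 = int(np.argmin(np.abs(tr.t - t0)))
        k1 = int(np.argmin(np.abs(tr.t - t1)))
        if abs(s[k0] - spine.arc) <= near_halfwidth:
            n_pre += 1
        if abs(s[k1] - spine.arc) <= near_halfwidth:
            n_post += 1
        in_region = (np.abs(s - spine.arc) <= region_halfwidth)
        window = (tr.t > t0) & (tr.t <= t1)
        if (in_region & window).any():
            d0 = abs(s[k0] - spine.arc)
            d1 = abs(s[k1] - spine.arc)
            if d0 - d1 >= run_min_disp:
                n_toward += 1
    return {"delta_count_near": n_post - n_pre, "n_toward": n_toward,
            "responsive_context": spine.stimulated}
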