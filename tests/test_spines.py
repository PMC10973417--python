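"""Docking taxonomy, occupied-spine reversals, and recruitment."""

import numpy as np
import pytest

from dendrotrace import synthdata as sd
from dendrotrace.spines import (classify_dock, occupancy_intervals,
                                occupied_reversal_fraction, recruitment)
from dendrotrace.types import SpineSite

from tests.conftest import straight_track

T = np.arange(300.0)


def spine(arc=50.0, **kw):
    return SpineSite(id=0, arc=arc, **kw)


class TestDockTaxonomy:
    def test_resident_granule_docked(self):
        tr = straight_track(0, T, np.full_like(T, 50.0))
        events = classify_dock(tr, spine(), radius=2.5)
        assert [e.kind for e in events] == ["docked"]

    def test_arriving_granule_docking(self):
        """Moves to the spine at t=100 s and resides thereafter."""
        arc = np.where(T < 100, 10.0 + 0.4 * T, 50.0)
        events = classify_dock(straight_track(0, T, arc), spine(), 2.5)
        kinds = {e.kind for e in events}
        assert "docking" in kinds and "docked" not in kinds

    def test_departing_granule_undocking(self):
        """Stationary at the spine for 60 s, then travels 10 µm away."""
        arc = np.where(T < 60, 50.0, np.minimum(50.0 + 0.5 * (T - 60), 60.0))
        events = classify_dock(straight_track(0, T, arc), spine(), 2.5)
        assert "undocking" in {e.kind for e in events}

    def test_transit_is_no_event(self):
        """A granule passing straight through the radius scores nothing."""
        arc = 0.5 * T
        events = classify_dock(straight_track(0, T, arc), spine(), 2.5,
                               residence_min=10.0)
        assert events == []

    def test_reversal_inside_radius_is_direction_change(self):
        arc = np.concatenate([0.5 * np.arange(100),   # up to 49.5
                              49.5 - 0.5 * np.arange(1, 201)])
        arc = np.clip(arc, 0.0, None)
        events = classify_dock(straight_track(0, T, arc), spine(), 2.5)
        assert "direction_change" in {e.kind for e in events}

    def test_docked_never_coexists_with_undocking(self, control_cohort):
        _, tracks, _, spines_arc = control_cohort
        for tr in tracks[:50]:
            for arc in spines_arc:
                kinds = [e.kind for e in
                         classify_dock(tr, spine(arc=float(arc)), 2.5)]
                assert not ({"docked", "undocking"} <= set(kinds))

    def test_radius_monotonicity(self, control_cohort):
        """Enlarging the radius never decreases the docked count."""
        _, tracks, _, spines_arc = control_cohort
        sites = [SpineSite(id=i, arc=float(a))
                 for i, a in enumerate(spines_arc)]
        counts = []
        for radius in (1.5, 2.5, 4.0):
            n = sum(1 for tr in tracks[:80] for sp in sites
                    for e in classify_dock(tr, sp, radius)
                    if e.kind == "docked")
            counts.append(n)
        assert counts == sorted(counts)


class TestOccupancy:
    def test_occupancy_matches_ground_truth_noiseless(self):
        p = sd.MotionModelParams(loc_noise_sd=0.0)
        spines_arc = np.arange(10.0, 90.0, 10.0)
        tracks, truth = sd.simulate_granules(p, 40, 120.0, 100.0,
                                             spine_positions=spines_arc,
                                             seed=31)
        for k, arc in enumerate(spines_arc):
            got = occupancy_intervals(tracks, SpineSite(id=k, arc=float(arc)),
                                      radius=2.5)
            want = truth.spine_occupancy[k]
            assert len(got) == len(want)
            for (g0, g1), (w0, w1) in zip(got, want):
                assert g0 == pytest.approx(w0, abs=1.0)
                assert g1 == pytest.approx(w1, abs=1.0)

    def test_single_granule_zero_percent(self):
        arc = np.concatenate([0.5 * np.arange(100),
                              49.5 - 0.5 * np.arange(1, 201)])
        tr = straight_track(0, T, np.clip(arc, 0, None))
        frac = occupied_reversal_fraction([tr], [spine()], 2.5)
        assert frac == 0.0

    def test_hand_enumerated_two_of_three(self):
        """3 reversals, 2 at spines occupied by a resident -> 66.7%."""
        resident = straight_track(9, T, np.full_like(T, 20.0))
        tracks = [resident]
        # two reversals at the occupied spine (arc 20)
        for i, t_rev in enumerate((50, 120)):
            arc = np.concatenate([
                20.0 - 0.5 * (t_rev - np.arange(t_rev)),
                20.0 - 0.5 * np.arange(1, len(T) - t_rev + 1)])
            tracks.append(straight_track(i, T, np.clip(arc, 0, None)))
        # one reversal at an empty spine (arc 60)
        arc = np.concatenate([
            60.0 - 0.5 * (80 - np.arange(80)),
            60.0 - 0.5 * np.arange(1, len(T) - 80 + 1)])
        tracks.append(straight_track(5, T, np.clip(arc, 0, None)))
        sites = [SpineSite(id=0, arc=20.0), SpineSite(id=1, arc=60.0)]
        frac = occupied_reversal_fraction(tracks, sites, 2.5)
        assert frac == pytest.approx(100.0 * 2 / 3, abs=0.1)

    def test_no_events_undefined(self):
        tr = straight_track(0, T, np.full_like(T, 5.0))
        assert occupied_reversal_fraction([tr], [spine()], 2.5) is None

    def test_spine_biased_reversal_exceeds_half(self):
        """With reversal forced at occupied spines, the fraction is > 50%."""
        p = sd.MotionModelParams(p_mobile=0.6, p_reverse=0.05,
                                 p_reverse_at_spine=0.9)
        spines_arc = np.arange(10.0, 90.0, 10.0)
        tracks, _ = sd.simulate_granules(p, 120, 300.0, 100.0,
                                         spine_positions=spines_arc, seed=33)
        sites = [SpineSite(id=i, arc=float(a))
                 for i, a in enumerate(spines_arc)]
        frac = occupied_reversal_fraction(tracks, sites, 2.5)
        assert frac is not None and frac > 50.0


class TestRecruitment:
    def test_static_scene_zero(self):
        tracks = [straight_track(i, T, np.full_like(T, 20.0 + 10 * i))
                  for i in range(4)]
        res = recruitment(tracks, spine(arc=50.0, stimulated=True,
                                        t_stim=60.0))
        assert res["delta_count_near"] == 0
        assert res["n_toward"] == 0

    def test_three_granules_converge(self):
        """3 granules entering the ±5 µm window post-stim -> Δcount 3."""
        tracks = []
        for i, start in enumerate((30.0, 70.0, 35.0)):
            direction = 1.0 if start < 50 else -1.0
            arc = np.where(T < 60, start,
                           start + direction * np.minimum(
                               0.1 * (T - 60), abs(50.0 - start) - 1.0))
            tracks.append(straight_track(i, T, arc))
        res = recruitment(tracks, spine(arc=50.0, stimulated=True,
                                        t_stim=60.0), post_window=239.0)
        assert res["delta_count_near"] == 3
        assert res["n_toward"] == 3

    def test_departing_granule_not_toward(self):
        arc = np.where(T < 60, 40.0, 40.0 - np.minimum(0.1 * (T - 60), 20.0))
        res = recruitment([straight_track(0, T, arc)],
                          spine(arc=50.0, stimulated=True, t_stim=60.0),
                          post_window=200.0)
        assert res["n_toward"] == 0

    def test_unstimulated_spine_rejected(self):
        with pytest.raises(ValueError):
            recruitment([], spine())
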