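import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afdm
from afdm.rotational import cluster_sites, ring_rotation_span


def _staircase_oracle(vals):
    """Exhaustive check over all 5 circular rotations x 2 directions."""
    n = len(vals)
    for start in range(n):
        for direction in (1, -1):
            seq = [vals[(start + direction * k) % n] for k in range(n)]
            if all(seq[i] < seq[i + 1] for i in range(n - 1)):
                return True, direction
    return False, 0


class TestRingRotationSpan:
    def test_simulated_rotor_spans_80_percent_staircase(self, geometry):
        f = afdm.simulate_activation_field(geometry, "rotational", 170, n_beats=1)
        res = ring_rotation_span(f.lat_table, geometry, 1, (0, 170), 170.0)
        span, chir, stair = res
        assert span == pytest.approx(0.8)
        assert stair and chir == 1

    def test_simultaneous_activation_is_not_a_staircase(self, geometry):
        tab = {e: np.array([50.0]) for e in range(1, 21)}
        span, chir, stair = ring_rotation_span(tab, geometry, 2, (0, 170), 170.0)
        assert span == 0.0 and not stair

    def test_missing_electrode_makes_span_undefined(self, geometry):
        tab = {e: np.array([50.0]) for e in range(1, 21)}
        tab[5] = np.array([])  # ring-1 electrode without LAT
        assert ring_rotation_span(tab, geometry, 1, (0, 170), 170.0) is None

    @given(st.permutations(list(range(5))))
    @settings(max_examples=120, deadline=None)
    def test_staircase_matches_exhaustive_oracle(self, geometry, perm):
        vals = [10.0 + 30.0 * p for p in perm]
        tab = {e: np.array([]) for e in range(1, 21)}
        for e, v in zip(afdm.make_catheter_geometry().ring_electrodes(1), vals):
            tab[int(e)] = np.array([v])
        res = ring_rotation_span(tab, geometry, 1, (0, 170), 170.0)
        expect_stair, expect_dir = _staircase_oracle(vals)
        assert res[2] == expect_stair
        if expect_stair:
            assert res[1] == expect_dir


class TestDetectRac:
    def test_planar_wave_yields_no_events(self, planar_acquisition):
        lats = afdm.detect_lats(planar_acquisition)
        dcl = afdm.dominant_cycle_length(lats)
        assert afdm.detect_rac(planar_acquisition, lats, dcl) == []

    def test_three_rotation_rotor_gives_one_event_with_exact_count(self, geometry):
        acq = afdm.simulate_acquisition("rotational", seed=7, n_beats=3,
                                        noise_sd_mv=0.0, duration_s=0.8)
        lats = afdm.detect_lats(acq)
        events = afdm.detect_rac(acq, lats, 170.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.n_rotations == 3
        assert ev.chirality == 1
        # duration = 2 cycles + within-rotation ring span, by the boundary
        # convention (first LAT of first rotation to last of last)
        assert 340.0 <= ev.duration_ms <= 510.0
        assert ev.rings_satisfying == (1, 2, 3, 4)

    def test_single_rotation_below_minimum_is_no_event(self, geometry):
        acq = afdm.simulate_acquisition("rotational", seed=8, n_beats=1,
                                        noise_sd_mv=0.0, duration_s=0.4)
        lats = afdm.detect_lats(acq)
        assert afdm.detect_rac(acq, lats, 170.0) == []

    def test_event_count_non_increasing_in_strictness(self, rotor_acquisition):
        lats = afdm.detect_lats(rotor_acquisition)
        dcl = afdm.dominant_cycle_length(lats)

        def n_events(**kw):
            return len(afdm.detect_rac(rotor_acquisition, lats, dcl, **kw))

        assert n_events(span_threshold=0.5) >= n_events(span_threshold=0.75) >= n_events(span_threshold=0.95)
        assert n_events(min_rotations=2) >= n_events(min_rotations=4) >= n_events(min_rotations=10)
        assert n_events(rings_required=2) >= n_events(rings_required=4)

    def test_chirality_detected_for_both_handednesses(self):
        for chir in (+1, -1):
            acq = afdm.simulate_acquisition("rotational", seed=11, n_beats=4,
                                            chirality=chir, noise_sd_mv=0.0, duration_s=1.0)
            lats = afdm.detect_lats(acq)
            events = afdm.detect_rac(acq, lats, 170.0)
            assert len(events) == 1 and events[0].chirality == chir


class TestConfirmRac:
    def test_two_rotation_event_never_confirmed(self, rotor_acquisition):
        ev = afdm.RAcEvent(0.0, 340.0, 2, 1, (1, 2, 3, 4), [0.8, 0.8])
        assert afdm.confirm_rac(ev, rotor_acquisition) is False
        assert "n_rotations" in ev.confirm_reason

    def test_core_activity_contrast_confirms(self):
        acq = afdm.simulate_acquisition("rotational", seed=3, n_beats=6,
                                        duration_s=3.0, noise_sd_mv=0.05)
        lats = afdm.detect_lats(acq)
        dcl = afdm.dominant_cycle_length(lats)
        ev = afdm.detect_rac(acq, lats, dcl)[0]
        inner = [e for e in range(1, 21) if acq.geometry.ring_index[e - 1] >= 3]
        with_core = afdm.add_continuous_activity(
            acq, inner, ev.start_ms, ev.end_ms, amplitude_mv=0.3, seed=9
        )
        assert afdm.confirm_rac(ev, with_core) is True

    def test_uniform_burden_not_confirmed(self):
        acq = afdm.simulate_acquisition("rotational", seed=3, n_beats=6,
                                        duration_s=3.0, noise_sd_mv=0.05)
        lats = afdm.detect_lats(acq)
        ev = afdm.detect_rac(acq, lats, 170.0)[0]
        assert afdm.confirm_rac(ev, acq) is False


class TestSummaries:
    def test_zero_events_summary(self):
        s = afdm.summarize_rac([])
        assert s["has_rac"] is False and s["n_sites"] == 0 and s["n_events"] == 0

    def test_repeated_position_is_one_site(self):
        evs = [
            afdm.RAcEvent(0, 400, 2, 1, (1, 2, 3, 4), [0.8], map_position=np.zeros(3),
                          acquisition_id="a")
            for _ in range(3)
        ]
        s = afdm.summarize_rac(evs, n_acquisitions=2)
        assert s["n_sites"] == 1 and s["n_events"] == 3
        assert s["events_per_acquisition"] == pytest.approx(1.5)

    def test_distant_positions_cluster_like_single_linkage_oracle(self):
        pos = np.array([[0, 0, 0], [25, 0, 0]], dtype=float)
        assert len(set(cluster_sites(pos, 10.0))) == 2
        chain = np.array([[0, 0, 0], [8, 0, 0], [16, 0, 0]], dtype=float)
        assert len(set(cluster_sites(chain, 10.0))) == 1  # chained single linkage
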