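"""Rotational-activity (RAc) detection from ring-ordered activation times.

A rotor pivoting under the catheter activates each concentric electrode
ring sequentially ("staircase" sequence), so within one beat the ring's
LATs span most of the dominant cycle length. A rotation qualifies when
enough rings show a monotone circular activation order of one handedness
whose span exceeds half the DCL; two or more consecutive qualifying
rotations with constant chirality form an RAc event.

The clinical workflow adds an expert review of the bipolar traces before an
event is accepted; :func:`confirm_rac` is the automated surrogate of that
review (more than 2 rotations plus a rise of electrical burden on an
inner-ring bipole during the event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .catheter import CatheterGeometry, N_RINGS
from .lat import DominantCycleLength, LatSeries
from .simulate import Acquisition


@dataclass
class RAcEvent:
    """One detected rotational-activity episode."""

    start_ms: float
    end_ms: float
    n_rotations: int
    chirality: int
    rings_satisfying: tuple
    span_fraction_per_rotation: list
    acquisition_id: str = ""
    map_position: np.ndarray | None = None
    confirmed: bool | None = None
    confirm_reason: str = ""

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("event end must exceed start")
        if self.n_rotations < 2:
            raise ValueError("an RAc event needs >= 2 rotations")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def ring_rotation_span(
    lats: LatSeries | dict,
    geometry: CatheterGeometry,
    ring: int,
    beat_window: tuple,
    dcl_ms: float,
):
    """Span, chirality and staircase flag of one ring in one beat window.

    Orders the ring's five electrodes circularly (splines are equally
    spaced in azimuth), takes each electrode's first LAT inside
    ``beat_window``, and declares a staircase iff the LAT sequence is
    monotone in circular order with exactly one wrap. Returns
    ``(span_fraction, chirality, is_staircase)`` or ``None`` when any ring
    electrode has no LAT in the window.
    """
    table = lats.lat_table if isinstance(lats, LatSeries) else lats
    lo, hi = beat_window
    electrodes = geometry.ring_electrodes(ring)  # spline order == circular order
    vals = []
    for e in electrodes:
        t = np.asarray(table[int(e)])
        inside = t[(t >= lo) & (t < hi)]
        if len(inside) == 0:
            return None
        vals.append(float(inside[0]))
    vals = np.array(vals)
    span_fraction = float((vals.max() - vals.min()) / dcl_ms)

    # cyclic descents: a monotone-increasing circular staircase has exactly
    # one position where the successor is smaller (the wrap)
    nxt = np.roll(vals, -1)
    descents = int(np.sum(nxt < vals))
    ascents = int(np.sum(nxt > vals))
    if descents == 1 and ascents == len(vals) - 1:
        return span_fraction, +1, True
    if ascents == 1 and descents == len(vals) - 1:
        return span_fraction, -1, True
    return span_fraction, 0, False


def _beat_windows(lats: LatSeries, geometry: CatheterGeometry, dcl_ms: float):
    """Beat windows anchored on external-ring (ring-1) activations.

    Pooled ring-1 LATs are greedily segmented: each window anchors at the
    first unassigned LAT and spans [anchor - 0.1 DCL, anchor + 0.9 DCL].
    A full rotation occupies at most 4/5 of the cycle, so every phase keeps
    a 0.1-DCL jitter margin to the window edges while the neighbouring
    beats' activations stay 0.2 DCL outside.
    """
    anchors = np.sort(
        np.concatenate([lats.lats(int(e)) for e in geometry.ring_electrodes(1)])
    )
    windows = []
    i = 0
    while i < len(anchors):
        t0 = anchors[i]
        windows.append((t0 - 0.10 * dcl_ms, t0 + 0.90 * dcl_ms))
        i = int(np.searchsorted(anchors, t0 + 0.90 * dcl_ms))
    return windows


def detect_rac(
    acquisition: Acquisition,
    lats: LatSeries,
    dcl: DominantCycleLength | float,
    min_rotations: int = 2,
    span_threshold: float = 0.5,
    rings_required: int = 4,
    pooled: bool = False,
) -> list:
    """Detect RAc events in one acquisition.

    A rotation (beat window) qualifies when at least ``rings_required`` of
    the four rings show a staircase of identical chirality with
    ``span_fraction > span_threshold``; maximal runs of at least
    ``min_rotations`` consecutive qualifying rotations of constant
    chirality become events. Event boundaries run from the first LAT of the
    first qualifying rotation to the last LAT of the last.

    ``pooled=True`` switches to the pooled-LAT reading of the span rule
    (span of all four rings' LATs together, staircase required on >= 1
    ring), kept as a sensitivity-analysis alternative.
    """
    dcl_ms = dcl.value_ms if isinstance(dcl, DominantCycleLength) else float(dcl)
    windows = _beat_windows(lats, acquisition.geometry, dcl_ms)

    rotations = []  # (window, chirality, rings, spans, t_first, t_last)
    for w in windows:
        per_ring = {}
        for r in range(1, N_RINGS + 1):
            res = ring_rotation_span(lats, acquisition.geometry, r, w, dcl_ms)
            if res is not None:
                per_ring[r] = res
        qual = None
        for chir in (+1, -1):
            rings = [
                r
                for r, (sf, c, stair) in per_ring.items()
                if stair and c == chir and sf > span_threshold
            ]
            if pooled:
                all_lats = _window_lats(lats, acquisition.geometry, w)
                pooled_span = (
                    (all_lats.max() - all_lats.min()) / dcl_ms if len(all_lats) else 0.0
                )
                if len(rings) >= 1 and pooled_span > span_threshold:
                    qual = (chir, tuple(rings), [per_ring[r][0] for r in rings])
                    break
            elif len(rings) >= rings_required:
                qual = (chir, tuple(rings), [per_ring[r][0] for r in rings])
                break
        t_all = _window_lats(lats, acquisition.geometry, w)
        rotations.append((w, qual, t_all))

    events = []
    run = []
    for w, qual, t_all in rotations + [((np.inf, np.inf), None, np.array([]))]:
        if qual is not None and (not run or run[-1][1][0] == qual[0]):
            run.append((w, qual, t_all))
            continue
        _flush_run(run, min_rotations, events, acquisition)
        run = [(w, qual, t_all)] if qual is not None else []
    return events


def _window_lats(lats: LatSeries, geometry: CatheterGeometry, window) -> np.ndarray:
    lo, hi = window
    out = []
    for e, t in lats.lat_table.items():
        t = np.asarray(t)
        out.append(t[(t >= lo) & (t < hi)])
    return np.concatenate(out) if out else np.array([])


def _flush_run(run, min_rotations, events, acquisition):
    if len(run) < min_rotations:
        return
    chir = run[0][1][0]
    rings = tuple(sorted(set.intersection(*(set(q[1]) for _, q, _ in run))))
    spans = [float(np.mean(q[2])) for _, q, _ in run]
    t_first = float(min(t.min() for _, _, t in run if len(t)))
    t_last = float(max(t.max() for _, _, t in run if len(t)))
    events.append(
        RAcEvent(
            start_ms=t_first,
            end_ms=t_last,
            n_rotations=len(run),
            chirality=chir,
            rings_satisfying=rings,
            span_fraction_per_rotation=spans,
            acquisition_id=acquisition.acquisition_id,
            map_position=acquisition.map_position,
        )
    )


def confirm_rac(
    event: RAcEvent,
    acquisition: Acquisition,
    burden_fn=None,
    margin: float = 0.15,
) -> bool:
    """Automated surrogate of the expert confirmation of an RAc event.

    Confirmed iff the event has more than 2 rotations AND, on at least one
    inner-ring bipole, the electrical-burden score inside the event exceeds
    the score outside it by ``margin`` (the "appearance of continuous
    activity" the reviewers looked for). If the burden cannot be computed
    the event passes through unconfirmed with a reason, never discarded.
    """
    event.confirmed = False
    if event.n_rotations <= 2:
        event.confirm_reason = "n_rotations <= 2"
        return False
    if burden_fn is None:
        from .burden import score_channel

        def burden_fn(seg, fs):
            return score_channel(seg, fs).score

    fs = acquisition.sampling_rate_hz
    i0 = int(event.start_ms * fs / 1000.0)
    i1 = int(event.end_ms * fs / 1000.0)
    inner = [
        j
        for j, (a, b) in enumerate(acquisition.geometry.bipole_pairs)
        if acquisition.geometry.ring_index[a - 1] >= 3
    ]
    best_contrast = -np.inf
    for j in inner:
        ch = acquisition.bipolar[:, j]
        outside = np.concatenate([ch[:i0], ch[i1:]])
        try:
            inside_score = burden_fn(ch[i0:i1], fs)
            outside_score = burden_fn(outside, fs)
        except Exception:
            continue
        best_contrast = max(best_contrast, inside_score - outside_score)
    if not np.isfinite(best_contrast):
        event.confirm_reason = "burden unavailable"
        return False
    if best_contrast >= margin:
        event.confirmed = True
        event.confirm_reason = f"burden contrast {best_contrast:.2f}"
        return True
    event.confirm_reason = f"burden contrast {best_contrast:.2f} < {margin}"
    return False


def cluster_sites(positions: np.ndarray, radius_mm: float = 10.0) -> np.ndarray:
    """Single-linkage clustering of event positions into driver sites.

    Positions within ``radius_mm`` of a chain of neighbours belong to one
    site. Returns 0-based cluster labels.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pos) == 1:
        return np.zeros(1, dtype=int)
    z = linkage(pdist(pos), method="single")
    return fcluster(z, t=radius_mm, criterion="distance") - 1


def summarize_rac(
    events: list,
    n_acquisitions: int = 1,
    dcl_by_acquisition: dict | None = None,
    site_radius_mm: float = 10.0,
) -> dict:
    """Patient-level RAc summary (driver-mapping table fields).

    Sites are spatial clusters of event map positions within
    ``site_radius_mm``. ``dcl_by_acquisition`` maps acquisition id to DCL in
    ms for the acquisitions hosting RAc.
    """
    if not events:
        return {
            "has_rac": False,
            "n_sites": 0,
            "n_events": 0,
            "events_per_acquisition": 0.0,
            "mean_event_duration_ms": None,
            "total_event_duration_per_acquisition_ms": None,
            "dominant_cycle_length_for_rac_acquisitions_ms": None,
        }
    positions = np.array(
        [e.map_position if e.map_position is not None else (0.0, 0.0, 0.0) for e in events]
    )
    labels = cluster_sites(positions, site_radius_mm)
    durations = np.array([e.duration_ms for e in events])
    acq_ids = {e.acquisition_id for e in events}
    dcl = None
    if dcl_by_acquisition:
        vals = [dcl_by_acquisition[a] for a in acq_ids if a in dcl_by_acquisition]
        dcl = float(np.mean(vals)) if vals else None
    return {
        "has_rac": True,
        "n_sites": int(labels.max() + 1),
        "n_events": len(events),
        "events_per_acquisition": len(events) / n_acquisitions,
        "mean_event_duration_ms": float(durations.mean()),
        "total_event_duration_per_acquisition_ms": float(durations.sum() / max(len(acq_ids), 1)),
        "dominant_cycle_length_for_rac_acquisitions_ms": dcl,
    }
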