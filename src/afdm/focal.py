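"""Focal-activity (FAc) detection from unipolar QS morphology.

A focal source fires centrifugally: the electrode over the origin sees a
monophasic negative (QS) unipolar deflection — no approaching wavefront,
only departing — while surrounding electrodes keep an RS shape. A QS
activation is an origin candidate when no other QS activation within a
10-mm radius precedes it inside a 50-ms window; repetitive firing for two
or more consecutive beats makes an FAc event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lat import DominantCycleLength, LatSeries
from .rotational import cluster_sites
from .simulate import Acquisition


@dataclass
class FAcEvent:
    """One repetitive focal-activity episode."""

    origin_electrode: int
    beat_times_ms: np.ndarray
    acquisition_id: str = ""
    map_position: np.ndarray | None = None
    origin_position: np.ndarray | None = None

    def __post_init__(self):
        self.beat_times_ms = np.sort(np.asarray(self.beat_times_ms, dtype=float))
        if len(self.beat_times_ms) < 2:
            raise ValueError("an FAc event needs >= 2 beats")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times_ms)


def _channel_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from the median absolute deviation."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def classify_qs(
    unipolar_channel: np.ndarray,
    sampling_rate_hz: float,
    lat_ms: float,
    morphology_window_ms: float = 40.0,
    rs_ratio_threshold: float = 0.15,
    noise_floor_mv: float | None = None,
) -> bool:
    """True iff the deflection around ``lat_ms`` has a QS morphology.

    Within the window centered on the LAT, QS holds when the ratio of the
    maximum positive to the maximum negative excursion is strictly below
    ``rs_ratio_threshold`` and the negative excursion rises above the
    channel noise floor (default 5x the MAD-estimated noise SD). A window
    truncated by the recording edge is classified as-is with a warning.
    """
    x = np.asarray(unipolar_channel, dtype=float)
    if not 0 <= lat_ms <= (len(x) - 1) * 1000.0 / sampling_rate_hz:
        raise ValueError("lat_ms outside the recording")
    half = int(round(morphology_window_ms / 2.0 * sampling_rate_hz / 1000.0))
    c = int(round(lat_ms * sampling_rate_hz / 1000.0))
    lo, hi = c - half, c + half + 1
    if lo < 0 or hi > len(x):
        warnings.warn("morphology window truncated by recording edge", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, len(x))
    seg = x[lo:hi]
    pos = max(float(seg.max()), 0.0)
    neg = max(float(-seg.min()), 0.0)
    floor = 5.0 * _channel_noise_sd(x) if noise_floor_mv is None else noise_floor_mv
    if neg <= floor or neg == 0.0:
        return False
    return pos / neg < rs_ratio_threshold


def detect_fac(
    acquisition: Acquisition,
    lats: LatSeries,
    dcl: DominantCycleLength | float,
    radius_mm: float = 10.0,
    precede_window_ms: float = 50.0,
    min_beats: int = 2,
    morphology_window_ms: float = 40.0,
    rs_ratio_threshold: float = 0.15,
) -> list:
    """Detect repetitive focal activity in one acquisition.

    Every LAT is QS-classified on its unipolar channel. A QS activation is
    an origin candidate when no other QS activation lies within
    ``radius_mm`` with a LAT in the preceding ``precede_window_ms``.
    Candidates are placed on a beat grid of pitch DCL; runs of at least
    ``min_beats`` consecutive beats whose origins drift by at most
    ``radius_mm`` per beat form events (a missed intermediate beat breaks
    the run). The event origin is the run's modal origin electrode (ties
    broken by first appearance), which is robust to single-beat timing
    swaps among near-simultaneous neighbours.
    """
    dcl_ms = dcl.value_ms if isinstance(dcl, DominantCycleLength) else float(dcl)
    geom = acquisition.geometry
    fs = acquisition.sampling_rate_hz

    qs_acts = []  # (lat_ms, electrode)
    for e, times in lats.lat_table.items():
        ch = acquisition.unipolar[:, e - 1]
        for t in np.asarray(times):
            if classify_qs(
                ch, fs, t,
                morphology_window_ms=morphology_window_ms,
                rs_ratio_threshold=rs_ratio_threshold,
            ):
                qs_acts.append((float(t), int(e)))
    if not qs_acts:
        return []
    qs_acts.sort()
    t_arr = np.array([t for t, _ in qs_acts])
    e_arr = np.array([e for _, e in qs_acts])
    pos = geom.electrode_positions

    def is_origin(i: int) -> bool:
        for j in range(len(qs_acts)):
            if j == i:
                continue
            dt = t_arr[i] - t_arr[j]
            if 0 < dt <= precede_window_ms:
                d = np.linalg.norm(pos[e_arr[i] - 1] - pos[e_arr[j] - 1])
                if d <= radius_mm:
                    return False
        return True

    origins = [(t_arr[i], e_arr[i]) for i in range(len(qs_acts)) if is_origin(i)]
    if not origins:
        return []

    # beat grid derived from the DCL, anchored on the first origin
    t0 = origins[0][0]
    runs = []  # list of dict(last_beat, last_e, beats=[(t,e)...])
    open_runs = []
    by_beat = {}
    for t, e in origins:
        b = int(round((t - t0) / dcl_ms))
        by_beat.setdefault(b, []).append((t, e))
    closed = []
    for b in range(min(by_beat), max(by_beat) + 1):
        cands = by_beat.get(b, [])
        still_open = []
        used = [False] * len(cands)
        for run in open_runs:
            matched = False
            for k, (t, e) in enumerate(cands):
                if used[k]:
                    continue
                drift = np.linalg.norm(pos[e - 1] - pos[run["last_e"] - 1])
                if run["last_beat"] == b - 1 and drift <= radius_mm:
                    run["beats"].append((t, e))
                    run["last_beat"], run["last_e"] = b, e
                    used[k] = matched = True
                    break
            (still_open if matched else closed).append(run)
        for k, (t, e) in enumerate(cands):
            if not used[k]:
                still_open.append({"last_beat": b, "last_e": e, "beats": [(t, e)]})
        open_runs = still_open
    closed.extend(open_runs)

    events = []
    for run in closed:
        if len(run["beats"]) >= min_beats:
            es = [e for _, e in run["beats"]]
            counts = {e: es.count(e) for e in dict.fromkeys(es)}
            origin_e = max(counts, key=counts.get)
            events.append(
                FAcEvent(
                    origin_electrode=origin_e,
                    beat_times_ms=np.array([t for t, _ in run["beats"]]),
                    acquisition_id=acquisition.acquisition_id,
                    map_position=acquisition.map_position,
                    origin_position=pos[origin_e - 1].copy(),
                )
            )
    return events


def summarize_fac(
    events: list,
    n_acquisitions: int = 1,
    site_radius_mm: float = 10.0,
) -> dict:
    """Patient-level FAc summary, mirroring the RAc summary fields."""
    if not events:
        return {
            "has_fac": False,
            "n_sites": 0,
            "n_events": 0,
            "events_per_acquisition": 0.0,
            "mean_event_duration_ms": None,
            "total_event_duration_per_acquisition_ms": None,
        }
    positions = np.array(
        [e.map_position if e.map_position is not None else (0.0, 0.0, 0.0) for e in events]
    )
    labels = cluster_sites(positions, site_radius_mm)
    durations = np.array([e.beat_times_ms[-1] - e.beat_times_ms[0] for e in events])
    acq_ids = {e.acquisition_id for e in events}
    return {
        "has_fac": True,
        "n_sites": int(labels.max() + 1),
        "n_events": len(events),
        "events_per_acquisition": len(events) / n_acquisitions,
        "mean_event_duration_ms": float(durations.mean()),
        "total_event_duration_per_acquisition_ms": float(durations.sum() / max(len(acq_ids), 1)),
    }
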