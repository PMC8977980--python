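"""Local activation time (LAT) detection and dominant cycle length (DCL).

The LAT of a unipolar electrogram is the instant of maximum negative slope
of the deflection: intrinsic deflection of the wavefront passing under the
electrode. Candidate LATs are local minima of the (optionally smoothed)
first derivative below a negative slope floor, accepted greedily from the
steepest down subject to a refractory spacing.

The dominant cycle length is the prevailing activation period of the
acquisition, estimated as the median over electrodes of each electrode's
median inter-activation interval. The median-of-medians estimator is robust
on short windows where a spectral dominant-frequency estimate is noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedDclError
from .simulate import Acquisition


@dataclass
class LatSeries:
    """Per-electrode sorted activation times with their slopes."""

    lat_table: dict  # 1-based electrode -> sorted ndarray, ms
    slope_at_lat: dict  # electrode -> ndarray, mV/ms
    refractory_ms: float
    slope_floor_mv_per_ms: dict  # electrode -> floor actually used

    def lats(self, electrode: int) -> np.ndarray:
        return self.lat_table[electrode]

    @property
    def electrodes(self):
        return sorted(self.lat_table)

    def n_total(self) -> int:
        return int(sum(len(v) for v in self.lat_table.values()))


@dataclass(frozen=True)
class DominantCycleLength:
    value_ms: float
    method: str
    per_electrode_median_ms: dict
    physiological_band_ms: tuple = (100.0, 300.0)

    @property
    def in_band(self) -> bool:
        lo, hi = self.physiological_band_ms
        return lo <= self.value_ms <= hi


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _adaptive_slope_floor(deriv: np.ndarray, fs: float, k: float = 4.5) -> float:
    """Slope floor = k x a robust estimate of the derivative noise SD.

    The channel derivative is cut into 50-ms frames and the median frame
    RMS estimates the noise level: intrinsic deflections occupy a minority
    of frames, so the median is insensitive to them, and unlike the mean of
    the quietest frames it carries no downward selection bias. The
    multiplier covers the extreme-value growth of Gaussian noise over tens
    of thousands of samples; deflection slopes sit more than an order of
    magnitude above the floor, so the margin costs no sensitivity.
    """
    frame = max(int(0.05 * fs), 4)
    n_frames = len(deriv) // frame
    if n_frames < 2:
        return k * float(np.std(deriv))
    frames = deriv[: n_frames * frame].reshape(n_frames, frame)
    rms = np.sqrt((frames**2).mean(axis=1))
    return k * float(np.median(rms))


def _detect_channel(
    x: np.ndarray,
    fs: float,
    refractory_ms: float,
    slope_floor: float | None,
    smooth_samples: int,
):
    dt_ms = 1000.0 / fs
    xs = _moving_average(x, smooth_samples)
    deriv = np.gradient(xs) / dt_ms  # central differences, mV/ms
    floor = _adaptive_slope_floor(deriv, fs) if slope_floor is None else slope_floor

    # local minima of the derivative below -floor
    d = deriv
    interior = np.arange(1, len(d) - 1)
    is_min = (d[interior] <= d[interior - 1]) & (d[interior] < d[interior + 1])
    cand = interior[is_min & (d[interior] < -floor)]
    if len(cand) == 0:
        return np.array([]), np.array([]), floor

    # greedy acceptance: steepest first, ties broken by earlier time
    order = np.lexsort((cand, d[cand]))  # ascending derivative = steepest first
    accepted = []
    refr = refractory_ms
    for idx in cand[order]:
        t = idx * dt_ms
        if all(abs(t - a) >= refr for a in accepted):
            accepted.append(t)
    accepted = np.array(sorted(accepted))

    # smoothing flattens the derivative minimum into a plateau; pin each LAT
    # to the steepest raw-derivative sample inside the smoothing window
    slope_source = d
    if smooth_samples > 1 and len(accepted):
        raw = np.gradient(x) / dt_ms
        half = smooth_samples // 2
        refined = []
        for t in accepted:
            c = int(round(t / dt_ms))
            lo, hi = max(0, c - half), min(len(raw), c + half + 1)
            refined.append((lo + int(np.argmin(raw[lo:hi]))) * dt_ms)
        accepted = np.array(sorted(refined))
        slope_source = raw
    slopes = slope_source[np.round(accepted / dt_ms).astype(int)]
    return accepted, slopes, floor


def detect_lats(
    acquisition: Acquisition,
    refractory_ms: float = 60.0,
    slope_floor_mv_per_ms: float | None = None,
    smooth_samples: int = 15,
) -> LatSeries:
    """Detect LATs on every unipolar channel of an acquisition.

    Parameters
    ----------
    refractory_ms : float
        Minimum spacing between accepted LATs on one electrode. The default
        60 ms sits below physiological atrial refractoriness.
    slope_floor_mv_per_ms : float or None
        Reject derivative minima shallower than this. ``None`` (default)
        estimates an adaptive floor of 3x the derivative noise SD from the
        quietest decile of the channel.
    smooth_samples : int
        Moving-average width applied before differentiation (15 samples at
        the 1-kHz default rate). Use 1 to disable.

    A channel with no qualifying minima yields an empty series; this is not
    an error (flat or noise-only electrode).
    """
    fs = acquisition.sampling_rate_hz
    lat_table, slope_tab, floors = {}, {}, {}
    for e in range(1, acquisition.unipolar.shape[1] + 1):
        t, s, fl = _detect_channel(
            acquisition.unipolar[:, e - 1], fs, refractory_ms,
            slope_floor_mv_per_ms, smooth_samples,
        )
        lat_table[e] = t
        slope_tab[e] = s
        floors[e] = fl
    return LatSeries(
        lat_table=lat_table,
        slope_at_lat=slope_tab,
        refractory_ms=float(refractory_ms),
        slope_floor_mv_per_ms=floors,
    )


def dominant_cycle_length(
    lats: LatSeries,
    min_activations: int = 3,
    min_electrodes: int = 3,
) -> DominantCycleLength:
    """Median-of-medians DCL over electrodes with enough activations.

    Electrodes with fewer than ``min_activations`` LATs are excluded; at
    least ``min_electrodes`` must remain or the DCL is undefined.
    """
    per_electrode = {}
    for e, t in lats.lat_table.items():
        if len(t) >= min_activations:
            per_electrode[e] = float(np.median(np.diff(t)))
    if len(per_electrode) < min_electrodes:
        raise UndefinedDclError(
            f"DCL needs >= {min_activations} activations on >= {min_electrodes} "
            f"electrodes; only {len(per_electrode)} qualify"
        )
    value = float(np.median(list(per_electrode.values())))
    return DominantCycleLength(
        value_ms=value, method="median-of-medians",
        per_electrode_median_ms=per_electrode,
    )
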