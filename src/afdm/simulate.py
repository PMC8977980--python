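"""Synthetic activation fields and electrogram synthesis.

The generator produces the three canonical intra-atrial activation regimes
seen by a multi-electrode mapping catheter during AF:

* ``planar``     - a travelling plane wave; activation time grows linearly
                   along the propagation direction.
* ``rotational`` - a spiral wave pivoting about a core; activation time is
                   proportional to the electrode azimuth about the core, so
                   one cycle is spread across each concentric ring
                   ("staircase" sequence).
* ``focal``      - centrifugal spread from a point source; activation time
                   grows with distance from the source, and electrodes over
                   the source record a monophasic negative (QS) unipolar
                   deflection.

Times are ms, distances mm, amplitudes mV. All randomness is drawn from a
``numpy`` Generator seeded explicitly, so every output is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .catheter import CatheterGeometry, N_ELECTRODES, make_catheter_geometry

PATTERNS = ("planar", "rotational", "focal")


class MissingSourceError(ValueError):
    """Focal/rotational fields need a source position."""


@dataclass(frozen=True)
class ActivationField:
    """Ground-truth local activation times for one acquisition window."""

    pattern: str
    cycle_length_ms: float
    n_beats: int
    lat_table: dict  # 1-based electrode -> sorted ndarray of LATs (ms)
    source_position: np.ndarray | None = None
    chirality: int = 0
    jitter_sd_ms: float = 0.0

    def lats(self, electrode: int) -> np.ndarray:
        return self.lat_table[electrode]

    @property
    def t_max(self) -> float:
        return max((float(v[-1]) for v in self.lat_table.values() if len(v)), default=0.0)


@dataclass
class Acquisition:
    """One multichannel recording window anchored at a map position.

    ``unipolar`` is (n_samples, 20); ``bipolar`` is (n_samples, 10) with
    columns following ``geometry.bipole_pairs``.
    """

    unipolar: np.ndarray
    bipolar: np.ndarray
    sampling_rate_hz: float
    geometry: CatheterGeometry
    map_position: np.ndarray
    ground_truth: ActivationField | None = None
    acquisition_id: str = "acq-0"

    def __post_init__(self):
        if self.unipolar.shape[1] != N_ELECTRODES:
            raise ValueError("unipolar must have 20 channels")
        if self.bipolar.shape != (self.unipolar.shape[0], len(self.geometry.bipole_pairs)):
            raise ValueError("bipolar shape must match unipolar length and bipole count")

    @property
    def n_samples(self) -> int:
        return self.unipolar.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz


def _enforce_monotone(times: np.ndarray, floor_ms: float) -> np.ndarray:
    """Sort and push activations apart so successive gaps are >= floor."""
    t = np.sort(times)
    for i in range(1, len(t)):
        if t[i] - t[i - 1] < floor_ms:
            t[i] = t[i - 1] + floor_ms
    return t


def simulate_activation_field(
    geometry: CatheterGeometry,
    pattern: str,
    cycle_length_ms: float = 170.0,
    n_beats: int = 10,
    source_position=None,
    chirality: int = 1,
    jitter_sd_ms: float = 0.0,
    conduction_velocity_mm_per_ms: float = 1.0,
    direction=(1.0, 0.0, 0.0),
    t0_ms: float = 20.0,
    refractory_floor_ms: float = 50.0,
    seed: int | None = None,
) -> ActivationField:
    """Generate ground-truth LATs for one of the three activation regimes.

    planar:      LAT_i = t0 + k*CL + (x_i . d_hat) / v
    focal:       LAT_i = t0 + k*CL + ||x_i - s|| / v
    rotational:  LAT_i = t0 + k*CL + ((chirality * theta_i) mod 2pi)/(2pi) * CL

    with i.i.d. Gaussian per-beat jitter added to every activation, then
    per-electrode monotonicity and the refractory floor enforced.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    if cycle_length_ms <= 0:
        raise ValueError("cycle_length_ms must be positive")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if conduction_velocity_mm_per_ms <= 0:
        raise ValueError("conduction velocity must be positive")
    if pattern in ("focal", "rotational") and source_position is None:
        if pattern == "rotational":
            source_position = geometry.center
        else:
            raise MissingSourceError(f"{pattern} pattern requires source_position")
    src = None if source_position is None else np.asarray(source_position, dtype=float)

    rng = np.random.default_rng(seed)
    pos = geometry.electrode_positions
    if pattern == "planar":
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        offsets = pos @ d / conduction_velocity_mm_per_ms
        offsets -= offsets.min()
    elif pattern == "focal":
        offsets = np.linalg.norm(pos - src, axis=1) / conduction_velocity_mm_per_ms
    else:  # rotational
        theta = geometry.electrode_azimuth(about=src)
        phase = np.mod(chirality * theta, 2.0 * np.pi)
        offsets = phase / (2.0 * np.pi) * cycle_length_ms

    lat_table = {}
    beats = np.arange(n_beats) * cycle_length_ms
    for e in range(N_ELECTRODES):
        t = t0_ms + beats + offsets[e]
        if jitter_sd_ms > 0:
            t = t + rng.normal(0.0, jitter_sd_ms, size=n_beats)
        lat_table[e + 1] = _enforce_monotone(t, refractory_floor_ms)

    return ActivationField(
        pattern=pattern,
        cycle_length_ms=float(cycle_length_ms),
        n_beats=int(n_beats),
        lat_table=lat_table,
        source_position=src,
        chirality=int(chirality) if pattern == "rotational" else 0,
        jitter_sd_ms=float(jitter_sd_ms),
    )


# ---------------------------------------------------------------------------
# waveform synthesis


def _biphasic(t_ms: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """RS deflection: positive then negative, steepest descent at t=0."""
    return -amplitude * (t_ms / sigma) * np.exp(0.5 - t_ms**2 / (2.0 * sigma**2))


def _qs(t_ms: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """Monophasic negative deflection, shifted so steepest descent is at t=0."""
    return -amplitude * np.exp(-((t_ms - sigma) ** 2) / (2.0 * sigma**2))


def synthesize_unipolar(
    field: ActivationField,
    geometry: CatheterGeometry,
    sampling_rate_hz: float = 1000.0,
    template: str = "biphasic",
    amplitude_mv: float = 1.0,
    noise_sd_mv: float = 0.05,
    template_width_ms: float = 10.0,
    qs_source_radius_mm: float = 5.0,
    duration_s: float | None = None,
    map_position=(0.0, 0.0, 0.0),
    acquisition_id: str = "acq-0",
    seed: int | None = None,
) -> Acquisition:
    """Render an :class:`ActivationField` into sampled unipolar + bipolar EGMs.

    Each activation inserts a deflection whose maximum negative slope falls on
    the LAT. With ``template='biphasic'`` every electrode gets an RS wave;
    with ``template='qs'`` electrodes within ``qs_source_radius_mm`` of the
    field's focal source get the monophasic QS wave instead (the far-field
    electrodes keep the RS shape). White Gaussian noise of ``noise_sd_mv`` is
    added, and bipolar channels are the difference of each bipole pair.
    """
    if template not in ("biphasic", "qs"):
        raise ValueError("template must be 'biphasic' or 'qs'")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sampling_rate_hz
    sigma = template_width_ms / 6.0

    if duration_s is None:
        duration_s = (field.t_max + 5 * template_width_ms) / 1000.0
    n = int(round(duration_s * sampling_rate_hz))
    uni = np.zeros((n, N_ELECTRODES))

    qs_electrodes = set()
    if template == "qs" and field.source_position is not None:
        d = np.linalg.norm(
            geometry.electrode_positions - field.source_position, axis=1
        )
        qs_electrodes = set(np.where(d <= qs_source_radius_mm)[0] + 1)

    half = int(np.ceil(5 * sigma / dt_ms)) + 1
    support_ms = 2 * half * dt_ms
    for e in range(1, N_ELECTRODES + 1):
        lats = field.lats(e)
        if len(lats) > 1 and np.any(np.diff(lats) < support_ms / 2):
            warnings.warn(
                f"electrode {e}: activations closer than template support; "
                "waveforms summed",
                stacklevel=2,
            )
        shape = _qs if e in qs_electrodes else _biphasic
        for lat in lats:
            c = int(round(lat / dt_ms))
            lo, hi = max(0, c - half), min(n, c + half + 1)
            if lo >= hi:
                continue
            t_rel = (np.arange(lo, hi) - lat / dt_ms) * dt_ms
            uni[lo:hi, e - 1] += shape(t_rel, amplitude_mv, sigma)

    if noise_sd_mv > 0:
        uni += rng.normal(0.0, noise_sd_mv, size=uni.shape)

    bip = np.column_stack(
        [uni[:, a - 1] - uni[:, b - 1] for a, b in geometry.bipole_pairs]
    )
    return Acquisition(
        unipolar=uni,
        bipolar=bip,
        sampling_rate_hz=float(sampling_rate_hz),
        geometry=geometry,
        map_position=np.asarray(map_position, dtype=float),
        ground_truth=field,
        acquisition_id=acquisition_id,
    )


def add_continuous_activity(
    acquisition: Acquisition,
    electrodes,
    start_ms: float,
    end_ms: float,
    amplitude_mv: float = 0.25,
    mean_interval_ms: float = 25.0,
    template_width_ms: float = 10.0,
    seed: int | None = None,
) -> Acquisition:
    """Overlay continuous low-amplitude fractionated activity on electrodes.

    Emulates the high-frequency, low-amplitude core signal recorded near a
    rotor pivot; used to build acquisitions in which the electrical burden
    rises inside the rotational interval. Returns a new Acquisition with
    bipolar channels recomputed.
    """
    rng = np.random.default_rng(seed)
    uni = acquisition.unipolar.copy()
    dt_ms = 1000.0 / acquisition.sampling_rate_hz
    sigma = template_width_ms / 6.0
    half = int(np.ceil(5 * sigma / dt_ms)) + 1
    n = uni.shape[0]
    for e in electrodes:
        t = start_ms
        while t < end_ms:
            t += rng.exponential(mean_interval_ms)
            c = int(round(t / dt_ms))
            lo, hi = max(0, c - half), min(n, c + half + 1)
            if lo >= hi:
                continue
            t_rel = (np.arange(lo, hi) - t / dt_ms) * dt_ms
            uni[lo:hi, e - 1] += _biphasic(t_rel, amplitude_mv, sigma)
    bip = np.column_stack(
        [uni[:, a - 1] - uni[:, b - 1] for a, b in acquisition.geometry.bipole_pairs]
    )
    return replace(acquisition, unipolar=uni, bipolar=bip)


def synthesize_bursty_channel(
    duration_s: float = 10.0,
    duty_cycle: float = 0.3,
    activity_interval_ms: float = 30.0,
    burst_len_ms: float = 1000.0,
    amplitude_mv: float = 1.0,
    noise_sd_mv: float = 0.05,
    sampling_rate_hz: float = 1000.0,
    seed: int | None = None,
):
    """One bipolar-like channel alternating activity bursts and silence.

    Activity bursts of ``burst_len_ms`` are laid out periodically so the
    active fraction of the window is ``duty_cycle``; inside a burst,
    deflections arrive every ~``activity_interval_ms`` so the activity is
    effectively continuous at the 50-ms burden frame scale (fractionated
    driver-core signal). Returns ``(signal, mask)`` where ``mask`` is the
    per-sample ground-truth activity indicator (the oracle for burden
    scoring). ``duty_cycle`` 0 gives pure noise, 1 continuous activity.
    """
    if not 0.0 <= duty_cycle <= 1.0:
        raise ValueError("duty_cycle must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sampling_rate_hz
    n = int(round(duration_s * sampling_rate_hz))
    sig = rng.normal(0.0, noise_sd_mv, size=n)
    mask = np.zeros(n, dtype=bool)
    if duty_cycle > 0:
        period_ms = burst_len_ms / duty_cycle
        sigma = 10.0 / 6.0
        half = int(np.ceil(5 * sigma / dt_ms)) + 1
        t_burst = 0.0
        total_ms = duration_s * 1000.0
        while t_burst < total_ms:
            b_end = min(t_burst + burst_len_ms, total_ms)
            mask[int(t_burst / dt_ms) : int(b_end / dt_ms)] = True
            t = t_burst
            while t < b_end:
                c = int(round(t / dt_ms))
                lo, hi = max(0, c - half), min(n, c + half + 1)
                if lo < hi:
                    t_rel = (np.arange(lo, hi) - t / dt_ms) * dt_ms
                    sig[lo:hi] += _biphasic(t_rel, amplitude_mv, sigma)
                t += activity_interval_ms * (1 + 0.2 * abs(rng.standard_normal()))
            t_burst += period_ms
    return sig, mask


def simulate_acquisition(
    pattern: str,
    seed: int,
    cycle_length_ms: float = 170.0,
    n_beats: int = 12,
    jitter_sd_ms: float = 0.0,
    noise_sd_mv: float = 0.05,
    geometry: CatheterGeometry | None = None,
    source_position=None,
    chirality: int = 1,
    duration_s: float | None = None,
    **field_kwargs,
) -> Acquisition:
    """Convenience wrapper: geometry -> activation field -> sampled EGMs.

    Focal patterns place the source directly under a mid-catheter electrode
    by default (electrode 7, ring 3 of the second spline) — the clinical
    acquisition geometry, catheter centred over the focus — and use the QS
    template there; planar and rotational patterns use the biphasic
    template everywhere.
    """
    if geometry is None:
        geometry = make_catheter_geometry()
    if pattern == "focal" and source_position is None:
        source_position = geometry.electrode_positions[6].copy()
    field = simulate_activation_field(
        geometry,
        pattern,
        cycle_length_ms=cycle_length_ms,
        n_beats=n_beats,
        source_position=source_position,
        chirality=chirality,
        jitter_sd_ms=jitter_sd_ms,
        seed=seed,
        **field_kwargs,
    )
    return synthesize_unipolar(
        field,
        geometry,
        template="qs" if pattern == "focal" else "biphasic",
        noise_sd_mv=noise_sd_mv,
        duration_s=duration_s,
        seed=seed + 1_000_003,
        acquisition_id=f"{pattern}-{seed}",
    )
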