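"""Synthetic ground-truthed radar inputs.

The simulator produces three layers, each usable on its own in tests:

1. interbeat-interval (IBI) sequences with a prescribed mean and SDNN,
2. chest-wall displacement = slow mm-scale breathing + sub-mm beat pulses,
3. complex intermediate-frequency (IF) data cubes on the azimuth virtual
   array, following the FMCW mixer model: each point scatterer at range R
   contributes A*exp(j(2*pi*f_b*t + 4*pi*R/lambda)) with beat frequency
   f_b = 2*S*R/c, multiplied across antennas by the steering phase
   exp(-j*2*pi*m*d*sin(theta)/lambda).

Fast-time phase is referenced to the center of the ADC sampling window, so
the phase of the range-FFT bin equals 4*pi*R/lambda exactly (no window
group-delay term); intra-chirp motion is frozen (stop-and-go approximation)
and the Tx time-division multiplexing is collapsed to one synchronized
snapshot per frame, both negligible at chest-wall velocities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ChirpConfig

__all__ = [
    "MotionProfile",
    "IFDataCube",
    "Interferer",
    "generate_ibis",
    "synthesize_motion",
    "synthesize_if_cube",
    "constant_motion",
    "biphasic_kernel",
]

IBI_MIN_MS = 400.0
IBI_MAX_MS = 1500.0


@dataclass
class MotionProfile:
    """Ground-truth chest-wall motion with its component decomposition.

    ``displacement`` is the absolute range R(t) seen by the radar:
    nominal_range_r0 + respiration + heartbeat + noise, pointwise.
    ``true_ibis_ms`` are exact (continuous-time) intervals; beat onsets are
    stored both as exact times and as nearest sample indices.
    """

    displacement: np.ndarray
    respiration_component: np.ndarray
    heartbeat_component: np.ndarray
    noise_component: np.ndarray
    fs: float
    nominal_range_r0: float
    azimuth_theta: float
    true_ibis_ms: np.ndarray
    true_beat_onsets: np.ndarray  # sample indices (rounded)
    true_onset_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        n = len(self.displacement)
        for name in ("respiration_component", "heartbeat_component", "noise_component"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from displacement")
        if np.any(np.diff(self.true_beat_onsets) <= 0):
            raise ValueError("true_beat_onsets must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.displacement)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass
class Interferer:
    """Point scatterer at (range, azimuth) with optional own motion.

    ``displacement`` (m, one value per frame) is added to ``range_m``; a
    breathing second person is modeled by passing their chest motion here.
    """

    range_m: float
    azimuth_rad: float
    amplitude: float
    displacement: np.ndarray | None = None


@dataclass
class IFDataCube:
    """Complex IF samples indexed [frame, virtual_antenna, fast_sample]."""

    samples: np.ndarray
    config: ChirpConfig
    noise_snr_db: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.samples.ndim != 3:
            raise ValueError("samples must be a 3-D [frame, antenna, fast] array")
        f, m, n = self.samples.shape
        if m != self.config.azimuth_virtual_count or n != self.config.samples_per_chirp:
            raise ValueError("cube dimensions inconsistent with ChirpConfig")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("cube contains non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


def generate_ibis(
    n_beats: int,
    mean_ms: float = 850.0,
    sdnn_ms: float = 40.0,
    ar_coefficient: float = 0.3,
    seed: int | None = None,
) -> np.ndarray:
    """Draw an AR(1)-jittered IBI sequence (ms).

    Deviations around ``mean_ms`` follow a stationary first-order
    autoregression with standard deviation ``sdnn_ms``; the lag-1 coefficient
    trades SDNN against RMSSD (RMSSD ~= SDNN*sqrt(2*(1-rho))).  Intervals are
    clamped to the physiological band [400, 1500] ms.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    if not (IBI_MIN_MS <= mean_ms <= IBI_MAX_MS):
        raise ValueError(f"mean_ms must lie in [{IBI_MIN_MS}, {IBI_MAX_MS}]")
    if sdnn_ms < 0:
        raise ValueError("sdnn_ms must be nonnegative")
    if not (0 <= ar_coefficient < 1):
        raise ValueError("ar_coefficient must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rho = ar_coefficient
    x = np.empty(n_beats)
    x[0] = rng.normal(0.0, sdnn_ms)
    innov_sd = sdnn_ms * math.sqrt(1 - rho**2)
    eps = rng.normal(0.0, 1.0, n_beats - 1) * innov_sd
    for i in range(1, n_beats):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return np.clip(mean_ms + x, IBI_MIN_MS, IBI_MAX_MS)


def biphasic_kernel(u: np.ndarray) -> np.ndarray:
    """Unit-peak biphasic pulse on u in [0, 1): one sine cycle under a Hann
    window, mimicking the sharp up-down acceleration event of a heartbeat."""
    k = np.where(
        (u >= 0) & (u < 1),
        np.sin(2 * np.pi * u) * 0.5 * (1 - np.cos(2 * np.pi * u)),
        0.0,
    )
    return k / _BIPHASIC_PEAK


_u = np.linspace(0, 1, 4001)
_BIPHASIC_PEAK = float(
    np.max(np.abs(np.sin(2 * np.pi * _u) * 0.5 * (1 - np.cos(2 * np.pi * _u))))
)
del _u


def synthesize_motion(
    ibis_ms,
    *,
    resp_rate_hz: float = 0.25,
    resp_amp_m: float = 5.0e-3,
    resp_harmonics: tuple[float, ...] = (1.0, 0.3),
    heart_amp_m: float = 3.0e-4,
    beat_kernel=biphasic_kernel,
    beat_kernel_duration_s: float = 0.12,
    fs_hz: float = 100.0,
    r0_m: float = 0.6,
    theta_rad: float = 0.0,
    noise_sd_m: float = 0.0,
    resp_phase_rad: float | None = None,
    pad_s: float = 0.25,
    lead_in_s: float = 0.25,
    seed: int | None = None,
) -> MotionProfile:
    """Render chest displacement from an IBI sequence.

    Respiration is a quasi-sinusoid (``resp_harmonics`` weights the
    fundamental and higher harmonics of ``resp_rate_hz``); the heartbeat is a
    short sub-mm pulse of shape ``beat_kernel`` placed at each beat onset.
    Onsets sit at ``lead_in_s`` plus the cumulative sums of ``ibis_ms``, at
    continuous times, so ground-truth intervals are exact; the lead-in keeps
    the first beat clear of the record edge, as in a capture that starts
    mid-stream (set it to 0 for an onset at t = 0 exactly).
    """
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.ndim != 1 or len(ibis) < 1:
        raise ValueError("ibis_ms must be a non-empty 1-D sequence")
    if np.any(ibis <= 0):
        raise ValueError("all intervals must be positive")
    if beat_kernel_duration_s * 1e3 >= float(np.min(ibis)):
        raise ValueError("beat kernel is longer than the shortest interval")
    if fs_hz < 100:
        raise ValueError("fs_hz must be at least 100 Hz")

    rng = np.random.default_rng(seed)
    if resp_phase_rad is None:
        resp_phase_rad = float(rng.uniform(0, 2 * np.pi)) if seed is not None else 0.0

    onset_times = lead_in_s + np.concatenate(([0.0], np.cumsum(ibis))) / 1e3
    duration = onset_times[-1] + beat_kernel_duration_s + pad_s
    n = int(round(duration * fs_hz)) + 1
    t = np.arange(n) / fs_hz

    resp = np.zeros(n)
    for k, w in enumerate(resp_harmonics, start=1):
        resp += w * np.sin(2 * np.pi * k * resp_rate_hz * t + k * resp_phase_rad)
    resp *= resp_amp_m

    heart = np.zeros(n)
    span = int(math.ceil(beat_kernel_duration_s * fs_hz)) + 2
    for t0 in onset_times:
        i0 = max(0, int(math.floor(t0 * fs_hz)))
        i1 = min(n, i0 + span)
        u = (t[i0:i1] - t0) / beat_kernel_duration_s
        heart[i0:i1] += heart_amp_m * beat_kernel(u)

    noise = rng.normal(0.0, noise_sd_m, n) if noise_sd_m > 0 else np.zeros(n)

    return MotionProfile(
        displacement=r0_m + resp + heart + noise,
        respiration_component=resp,
        heartbeat_component=heart,
        noise_component=noise,
        fs=fs_hz,
        nominal_range_r0=r0_m,
        azimuth_theta=theta_rad,
        true_ibis_ms=ibis.copy(),
        true_beat_onsets=np.rint(onset_times * fs_hz).astype(int),
        true_onset_times_s=onset_times,
    )


def constant_motion(
    r0_m: float, n_frames: int, fs_hz: float = 100.0, theta_rad: float = 0.0
) -> MotionProfile:
    """A static target: constant range, no breathing or heartbeat."""
    z = np.zeros(n_frames)
    return MotionProfile(
        displacement=np.full(n_frames, r0_m),
        respiration_component=z,
        heartbeat_component=z.copy(),
        noise_component=z.copy(),
        fs=fs_hz,
        nominal_range_r0=r0_m,
        azimuth_theta=theta_rad,
        true_ibis_ms=np.empty(0),
        true_beat_onsets=np.array([0]),
        true_onset_times_s=np.array([0.0]),
    )


def _steering_phases(theta: float, cfg: ChirpConfig) -> np.ndarray:
    m = np.arange(cfg.azimuth_virtual_count)
    return np.exp(-2j * np.pi * m * cfg.d_over_lambda * np.sin(theta))


def _add_point_source(
    cube: np.ndarray,
    ranges_m: np.ndarray,
    theta: float,
    amplitude: float,
    cfg: ChirpConfig,
) -> None:
    if amplitude == 0:
        return
    lam = cfg.wavelength_m
    n = cfg.samples_per_chirp
    # fast-time axis centered on the sampling window (see module docstring)
    t_fast = (np.arange(n) - (n - 1) / 2) / cfg.fast_fs_hz
    f_b = 2 * cfg.slope_hz_per_s * ranges_m / cfg.speed_of_light_m_s
    phase0 = 4 * np.pi * ranges_m / lam
    sig = amplitude * np.exp(1j * (2 * np.pi * np.outer(f_b, t_fast) + phase0[:, None]))
    cube += sig[:, None, :] * _steering_phases(theta, cfg)[None, :, None]


def synthesize_if_cube(
    motion: MotionProfile,
    cfg: ChirpConfig,
    interferers=(),
    snr_db: float | None = None,
    target_amplitude: float = 1.0,
    seed: int | None = None,
) -> IFDataCube:
    """Render the IF data cube for a moving chest plus optional interferers.

    ``snr_db`` sets complex white noise relative to the per-sample target
    amplitude; ``None`` means noise-free.  ``interferers`` accepts
    :class:`Interferer` objects or plain ``(range_m, azimuth_rad, amplitude)``
    tuples (static points).
    """
    if abs(motion.fs - cfg.frame_rate_hz) > 1e-9 * cfg.frame_rate_hz:
        raise ValueError("motion.fs must equal the chirp frame rate")
    n_frames = motion.n_frames
    sources: list[tuple[np.ndarray, float, float]] = [
        (np.asarray(motion.displacement, dtype=float), motion.azimuth_theta, target_amplitude)
    ]
    for itf in interferers:
        if not isinstance(itf, Interferer):
            itf = Interferer(*itf)
        r = np.full(n_frames, itf.range_m, dtype=float)
        if itf.displacement is not None:
            d = np.asarray(itf.displacement, dtype=float)
            if len(d) != n_frames:
                raise ValueError("interferer displacement length must match frames")
            r = r + d
        sources.append((r, itf.azimuth_rad, itf.amplitude))

    r_max = cfg.unambiguous_range_m
    for ranges, _, _ in sources:
        if np.any(ranges <= 0) or np.any(ranges >= r_max):
            raise ValueError(
                f"source range outside (0, {r_max:.2f}) m: beat frequency would alias"
            )

    cube = np.zeros(
        (n_frames, cfg.azimuth_virtual_count, cfg.samples_per_chirp), dtype=complex
    )
    for ranges, theta, amp in sources:
        _add_point_source(cube, ranges, theta, amp, cfg)

    if snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = abs(target_amplitude) * 10 ** (-snr_db / 20)
        noise = rng.standard_normal(cube.shape) + 1j * rng.standard_normal(cube.shape)
        cube += noise * (sigma / math.sqrt(2))

    return IFDataCube(samples=cube, config=cfg, noise_snr_db=snr_db, seed=seed)
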