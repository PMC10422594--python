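"""IF data cube -> chest-wall displacement R(n).

Chain: fast-time FFT per chirp, range-bin selection at the operator-supplied
nominal range R0, MVDR beamforming toward the known azimuth theta on the
8-element virtual array, phase extraction/unwrapping, conversion to
displacement (R = phi * lambda / 4pi), and cubic-spline resampling to the
250 Hz working rate.

MVDR weights w = R_xx^-1 a / (a^H R_xx^-1 a) minimize output power subject to
unit gain toward the steering vector a(theta); the sample covariance is taken
over the whole record after per-antenna temporal mean removal (static clutter
otherwise dominates R_xx), with diagonal loading loading*trace(R)/M.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import LinAlgError, cholesky, solve_triangular

from .config import ChirpConfig
from .sim import IFDataCube

__all__ = [
    "RangeSnapshotSeries",
    "BeamWeights",
    "PhaseSignal",
    "range_fft",
    "select_range_bin",
    "snapshots_at_bin",
    "steering_vector",
    "mvdr_weights",
    "conventional_weights",
    "demodulate_phase",
    "resample_to",
    "demodulate_cube",
]


@dataclass
class RangeSnapshotSeries:
    """Complex array snapshots [frame, virtual_antenna] at one range bin."""

    values: np.ndarray
    bin_index: int
    bin_range_m: float
    frame_rate: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("snapshots must be [frame, antenna]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite snapshot values")


@dataclass
class BeamWeights:
    weights: np.ndarray
    theta: float
    steering: np.ndarray
    covariance: np.ndarray
    diagonal_loading: float

    @property
    def distortionless_residual(self) -> float:
        """|w^H a - 1|; zero for a valid distortionless beamformer."""
        return abs(np.vdot(self.weights, self.steering) - 1.0)


@dataclass
class PhaseSignal:
    """Real displacement series R(n) in meters with its sampling rate."""

    displacement: np.ndarray
    fs: float
    origin: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("non-finite displacement")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.displacement)) / self.fs


def range_fft(
    cube: IFDataCube, window_name: str = "rect", remove_dc: bool = True
) -> np.ndarray:
    """N-point FFT along fast time for every frame/antenna.

    ``remove_dc`` subtracts the per-chirp mean first (kills the zero bin
    only); ``window_name`` is "rect" or any scipy window name ("hann", ...).
    """
    x = cube.samples
    if x.size == 0:
        raise ValueError("empty cube")
    if remove_dc:
        x = x - x.mean(axis=-1, keepdims=True)
    if window_name != "rect":
        from scipy.signal import get_window

        x = x * get_window(window_name, x.shape[-1])
    return np.fft.fft(x, axis=-1)


def select_range_bin(r0_m: float, cfg: ChirpConfig) -> int:
    """Range bin whose beat frequency f = 2*S*R0/c is closest to R0's.

    Rounds half away from zero; rejects R0 outside (0, unambiguous range).
    """
    if not (0 < r0_m < cfg.unambiguous_range_m):
        raise ValueError(
            f"R0 must lie in (0, {cfg.unambiguous_range_m:.2f}) m"
        )
    f_beat = 2 * cfg.slope_hz_per_s * r0_m / cfg.speed_of_light_m_s
    x = f_beat * cfg.samples_per_chirp / cfg.fast_fs_hz
    return int(np.floor(x + 0.5))


def snapshots_at_bin(
    profiles: np.ndarray, bin_index: int, cfg: ChirpConfig
) -> RangeSnapshotSeries:
    if not (0 <= bin_index < profiles.shape[-1]):
        raise ValueError("bin_index outside the FFT length")
    bin_range = (
        bin_index
        * cfg.range_bin_width_hz
        * cfg.speed_of_light_m_s
        / (2 * cfg.slope_hz_per_s)
    )
    return RangeSnapshotSeries(
        values=np.ascontiguousarray(profiles[:, :, bin_index]),
        bin_index=bin_index,
        bin_range_m=bin_range,
        frame_rate=cfg.frame_rate_hz,
    )


def steering_vector(theta: float, m: int, d_over_lambda: float = 0.5) -> np.ndarray:
    """a(theta): element k = exp(-j*2*pi*k*d/lambda*sin(theta)), k = 0..M-1."""
    if m < 1:
        raise ValueError("M must be at least 1")
    k = np.arange(m)
    return np.exp(-2j * np.pi * k * d_over_lambda * np.sin(theta))


def conventional_weights(
    theta: float, m: int, d_over_lambda: float = 0.5
) -> BeamWeights:
    """Delay-and-sum beamformer w = a/M (the large-loading limit of MVDR)."""
    a = steering_vector(theta, m, d_over_lambda)
    return BeamWeights(
        weights=a / m,
        theta=theta,
        steering=a,
        covariance=np.eye(m, dtype=complex),
        diagonal_loading=np.inf,
    )


def mvdr_weights(
    snapshots: RangeSnapshotSeries,
    theta: float,
    loading: float = 1e-3,
    d_over_lambda: float = 0.5,
) -> BeamWeights:
    """Minimum-variance distortionless-response weights toward ``theta``.

    Covariance is estimated over all frames after per-antenna mean removal,
    then loaded with ``loading * trace(R)/M`` on the diagonal.  Raises a
    conditioning error (advising loading > 0) when R is numerically singular.
    """
    x = snapshots.values
    n_frames, m = x.shape
    if n_frames < m:
        raise ValueError("need at least M frames of snapshots")
    if loading < 0:
        raise ValueError("loading must be nonnegative")
    xc = x - x.mean(axis=0, keepdims=True)
    r = np.einsum("fa,fb->ab", xc, xc.conj()) / n_frames
    tr = float(np.trace(r).real)
    r_loaded = r + (loading * tr / m if tr > 0 else loading) * np.eye(m)
    a = steering_vector(theta, m, d_over_lambda)
    try:
        chol = cholesky(r_loaded, lower=True)
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is numerically singular; use diagonal loading > 0"
        ) from exc
    y = solve_triangular(chol, a, lower=True)
    rinv_a = solve_triangular(chol.conj().T, y, lower=False)
    w = rinv_a / np.vdot(a, rinv_a)
    return BeamWeights(
        weights=w, theta=theta, steering=a, covariance=r, diagonal_loading=loading
    )


def demodulate_phase(
    snapshots: RangeSnapshotSeries,
    weights: BeamWeights,
    cfg: ChirpConfig,
    unwrap: bool = True,
) -> PhaseSignal:
    """Beamform each frame (y = w^H x), unwrap the phase, convert to
    displacement R = phi*lambda/(4*pi), and mean-center.

    Frames with zero beamformed magnitude have undefined phase; they are
    interpolated from neighbors with a warning.
    """
    if snapshots.values.shape[1] != len(weights.weights):
        raise ValueError("snapshot/weight dimensions inconsistent")
    y = snapshots.values @ weights.weights.conj()
    mag = np.abs(y)
    valid = mag > 0
    if not np.any(valid):
        raise ValueError("all beamformed samples have zero magnitude")
    phase = np.angle(y)
    idx = np.arange(len(y))
    ph_valid = np.unwrap(phase[valid]) if unwrap else phase[valid]
    if not np.all(valid):
        warnings.warn(
            "zero-magnitude beamformed samples: phase interpolated from neighbors",
            RuntimeWarning,
            stacklevel=2,
        )
    full = np.interp(idx, idx[valid], ph_valid)
    disp = full * cfg.wavelength_m / (4 * np.pi)
    disp = disp - disp.mean()
    return PhaseSignal(
        displacement=disp,
        fs=snapshots.frame_rate,
        origin=f"demod bin={snapshots.bin_index} theta={weights.theta:.4f}",
    )


def resample_to(signal: PhaseSignal, target_fs: float) -> PhaseSignal:
    """Cubic-spline interpolation onto a uniform grid at ``target_fs``
    spanning the original support.  Upsampling only."""
    if target_fs < signal.fs:
        raise ValueError("downsampling is not supported")
    if abs(target_fs - signal.fs) <= 1e-12 * signal.fs:
        return PhaseSignal(signal.displacement.copy(), signal.fs, signal.origin)
    n = len(signal.displacement)
    t_old = np.arange(n) / signal.fs
    n_new = int(np.floor((n - 1) * target_fs / signal.fs + 1e-9)) + 1
    t_new = np.arange(n_new) / target_fs
    cs = CubicSpline(t_old, signal.displacement)
    return PhaseSignal(
        displacement=cs(t_new),
        fs=target_fs,
        origin=signal.origin + f"; resampled {signal.fs:g}->{target_fs:g} Hz",
    )


def demodulate_cube(
    cube: IFDataCube,
    r0_m: float,
    theta_rad: float,
    *,
    window_name: str = "rect",
    diagonal_loading: float = 1e-3,
    use_mvdr: bool = True,
) -> PhaseSignal:
    """Convenience chain: range FFT -> bin at R0 -> (MVDR) beamform -> phase."""
    cfg = cube.config
    profiles = range_fft(cube, window_name)
    snaps = snapshots_at_bin(profiles, select_range_bin(r0_m, cfg), cfg)
    if use_mvdr:
        w = mvdr_weights(snaps, theta_rad, diagonal_loading, cfg.d_over_lambda)
    else:
        w = conventional_weights(theta_rad, cfg.azimuth_virtual_count, cfg.d_over_lambda)
    return demodulate_phase(snaps, w, cfg)
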