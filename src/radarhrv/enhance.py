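"""Heartbeat enhancement and initial segmentation.

Breathing moves the chest slowly over millimeters while each heartbeat adds
a brief, sharp sub-millimeter pulse, so the second difference

    a(n) = (R(n+1) + R(n-1) - 2 R(n)) / Ts^2

suppresses respiration and enhances heartbeats.  The short-time average
power P(n) (centered window, 0.4 s by default) smooths a(n) into a
near-sinusoidal waveform whose crests give the initial cut-off points S0.
A zero-phase IIR bandpass (0.8-1.5 Hz by default) on R(n) provides the
classical baseline extractor for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import PhaseSignal

__all__ = [
    "AccelSignal",
    "PowerSignal",
    "Segmentation",
    "SignalTooShortError",
    "second_difference",
    "short_time_power",
    "initial_cutpoints",
    "bandpass_baseline",
]


class SignalTooShortError(ValueError):
    """Raised when too few heartbeat candidates survive peak selection."""


@dataclass
class AccelSignal:
    """Chest-wall acceleration a(n) (m/s^2) at sampling interval Ts = 1/fs."""

    values: np.ndarray
    fs: float

    @property
    def ts(self) -> float:
        return 1.0 / self.fs

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite acceleration")


@dataclass
class PowerSignal:
    """Short-time average power P(n) of the acceleration (nonnegative)."""

    values: np.ndarray
    half_window_l: int
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class Segmentation:
    """Strictly increasing cut-off sample indices S = {s1, s2, ...}."""

    cutoffs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=int)
        if len(self.cutoffs) >= 2 and np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cutoffs)

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.cutoffs)


def second_difference(r: PhaseSignal) -> AccelSignal:
    """Second difference of the displacement, length preserved.

    Interior samples follow the exact formula; the first and last samples
    replicate the nearest interior value to avoid spurious edge spikes.
    """
    x = np.asarray(r.displacement, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    ts = 1.0 / r.fs
    a = np.empty_like(x)
    a[1:-1] = (x[2:] + x[:-2] - 2 * x[1:-1]) / ts**2
    a[0] = a[1]
    a[-1] = a[-2]
    return AccelSignal(values=a, fs=r.fs)


def short_time_power(a: AccelSignal, half_window_l: int | None = None) -> PowerSignal:
    """Centered moving mean of |a|^2 over 2L+1 samples.

    Default L spans a 0.4 s full window (about half a heartbeat cycle).
    Near the edges the window truncates to the available samples and is
    normalized by the actual count.
    """
    if half_window_l is None:
        half_window_l = max(1, int(round(0.2 * a.fs)))
    if half_window_l < 1:
        raise ValueError("L must be at least 1")
    sq = np.abs(a.values) ** 2
    kernel = np.ones(2 * half_window_l + 1)
    num = np.convolve(sq, kernel, mode="same")
    cnt = np.convolve(np.ones_like(sq), kernel, mode="same")
    return PowerSignal(values=num / cnt, half_window_l=half_window_l, fs=a.fs)


def initial_cutpoints(
    p: PowerSignal, min_beat_s: float = 0.5, max_beat_s: float = 1.2
) -> Segmentation:
    """Initial segmentation S0 from the crests of P(n).

    Local maxima are accepted greedily by descending prominence under a
    minimum separation of ``min_beat_s``; each accepted crest is then
    located as the center of its half-prominence width (the power bump of a
    short beat event is flat-topped, so the raw argmax position is
    ill-conditioned while the bump center is stable).  Gaps longer than
    ``max_beat_s`` are filled with the highest remaining local maximum
    inside the gap that keeps the minimum separation to both gap edges (a
    gap with no such candidate is left unfilled).
    """
    if min_beat_s >= max_beat_s:
        raise ValueError("min_beat_s must be below max_beat_s")
    x = p.values
    min_d = int(round(min_beat_s * p.fs))
    max_d = int(round(max_beat_s * p.fs))
    peaks, _ = sps.find_peaks(x)
    if len(peaks) == 0:
        raise SignalTooShortError("no local maxima in the power signal")
    prom_data = sps.peak_prominences(x, peaks)
    prom = prom_data[0]
    widths = sps.peak_widths(x, peaks, rel_height=0.5, prominence_data=prom_data)
    centers = np.rint((widths[2] + widths[3]) / 2).astype(int)
    order = np.lexsort((peaks, -prom))  # prominence desc, index asc on ties
    accepted: list[int] = []
    for k in order:
        pk = int(centers[k])
        if all(abs(pk - a) >= min_d for a in accepted):
            accepted.append(pk)
    accepted.sort()
    remaining = sorted(set(int(q) for q in centers) - set(accepted))

    # fill over-long gaps with the best leftover local maximum inside them
    changed = True
    while changed:
        changed = False
        for i in range(len(accepted) - 1):
            lo, hi = accepted[i], accepted[i + 1]
            if hi - lo <= max_d:
                continue
            pool = [
                q for q in remaining if q - lo >= min_d and hi - q >= min_d
            ]
            if not pool:
                continue
            best = max(pool, key=lambda q: x[q])
            accepted.insert(i + 1, best)
            remaining.remove(best)
            changed = True
            break

    if len(accepted) < 2:
        raise SignalTooShortError("fewer than 2 heartbeat candidates found")
    return Segmentation(cutoffs=np.asarray(accepted), fs=p.fs)


def bandpass_baseline(
    r: PhaseSignal,
    low_hz: float = 0.8,
    high_hz: float = 1.5,
    min_beat_s: float = 0.5,
    order: int = 4,
    noise_floor_frac: float = 0.01,
):
    """Baseline IBI extractor: zero-phase IIR bandpass + positive-peak picking.

    Returns the interbeat intervals (ms) between successive positive peaks of
    the filtered displacement.  Peaks below ``noise_floor_frac`` of the input
    standard deviation are treated as stopband residue and discarded, and the
    zero-phase filter's edge transients (about two periods of the low cut-off
    at each end) are excluded from peak picking.
    """
    from .hrv import IBISeries

    if not (0 < low_hz < high_hz < r.fs / 2):
        raise ValueError("need 0 < low < high < fs/2")
    try:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=r.fs, output="sos")
    except ValueError as exc:
        raise ValueError(f"unstable/invalid bandpass design: {exc}") from exc
    x = r.displacement - np.mean(r.displacement)
    y = sps.sosfiltfilt(sos, x)
    trim = min(int(round(2 / low_hz * r.fs)), (len(y) - 1) // 3)
    floor = noise_floor_frac * float(np.std(x))
    interior = y[trim : len(y) - trim] if trim > 0 else y
    peaks, _ = sps.find_peaks(
        interior, height=floor, distance=max(1, int(round(min_beat_s * r.fs)))
    )
    peaks = peaks + trim
    ibis = np.diff(peaks) / r.fs * 1e3
    return IBISeries(intervals=ibis, source="baseline")
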