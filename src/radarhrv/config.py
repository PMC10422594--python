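"""Configuration models for the radar waveform, array geometry, and optimizer.

All physical quantities carry SI units in their field names (``_hz``, ``_s``,
``_m``, ``_ms``).  Defaults mirror a 77 GHz single-chip MIMO sensor with
3 Tx / 4 Rx antennas: 70 MHz/us chirp slope, 50 us chirps, 128 ADC samples at
4 MHz, 100 Hz frame rate, and the 8-element azimuth virtual array (half-
wavelength spacing) used for beamforming.
"""
from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

SPEED_OF_LIGHT_M_S = 3.0e8
#: Working rate (Hz) the displacement signal is interpolated to before
#: heartbeat enhancement; one sample is 4 ms.
WORKING_FS_HZ = 250.0


class ChirpConfig(BaseModel):
    """FMCW waveform and virtual-array geometry.

    The ADC sampling window (``samples_per_chirp / fast_fs_hz``) may be
    shorter than the chirp itself; it must not exceed it.
    """

    model_config = ConfigDict(extra="forbid")

    start_frequency_hz: float = 77.0e9
    slope_hz_per_s: float = Field(default=70.0e12, gt=0)
    chirp_duration_s: float = Field(default=50.0e-6, gt=0)
    samples_per_chirp: int = Field(default=128, ge=2)
    fast_fs_hz: float = Field(default=4.0e6, gt=0)
    frame_rate_hz: float = Field(default=100.0, gt=0)
    speed_of_light_m_s: float = SPEED_OF_LIGHT_M_S
    n_tx: int = Field(default=3, ge=1)
    n_rx: int = Field(default=4, ge=1)
    rx_spacing_m: float | None = None  # default lambda/2
    tx_spacing_m: float | None = None  # default lambda
    azimuth_virtual_count: int = Field(default=8, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "ChirpConfig":
        if self.azimuth_virtual_count > self.n_tx * self.n_rx:
            raise ValueError(
                "azimuth_virtual_count exceeds the Tx x Rx virtual array size"
            )
        window_s = self.samples_per_chirp / self.fast_fs_hz
        if window_s > self.chirp_duration_s * (1 + 1e-9):
            raise ValueError(
                "ADC sampling window samples_per_chirp/fast_fs exceeds the chirp duration"
            )
        if self.rx_spacing_m is None:
            self.rx_spacing_m = self.wavelength_m / 2
        if self.tx_spacing_m is None:
            self.tx_spacing_m = self.wavelength_m
        return self

    @property
    def wavelength_m(self) -> float:
        return self.speed_of_light_m_s / self.start_frequency_hz

    @property
    def d_over_lambda(self) -> float:
        """Azimuth element spacing in wavelengths (0.5 for lambda/2 Rx rows)."""
        return self.rx_spacing_m / self.wavelength_m

    @property
    def range_bin_width_hz(self) -> float:
        return self.fast_fs_hz / self.samples_per_chirp

    @property
    def unambiguous_range_m(self) -> float:
        """Largest range whose beat frequency stays below the ADC rate."""
        return self.speed_of_light_m_s * self.fast_fs_hz / (2 * self.slope_hz_per_s)


class OptimizerParams(BaseModel):
    """Tunables of the joint template/segmentation optimization.

    ``neighborhood_b_ms`` is half the width of the search neighborhood around
    each current cut-off point (20 ms -> 5 samples at 250 Hz).  A cut-off is
    "stable" between iterations when it moved by at most ``alpha1_ms``; the
    loop stops once the stable fraction reaches ``alpha2``.
    """

    model_config = ConfigDict(extra="forbid")

    neighborhood_b_ms: float = Field(default=20.0, ge=0)
    alpha1_ms: float = Field(default=5.0, ge=0)
    alpha2: float = Field(default=0.80, gt=0, le=1)
    max_iterations: int = Field(default=50, ge=1)
    template_length: int | None = Field(default=None, ge=4)
    znormalize: bool = True
    min_segment_samples: int = Field(default=4, ge=4)

    def b_samples(self, fs_hz: float) -> int:
        return int(round(self.neighborhood_b_ms * 1e-3 * fs_hz))


class SimParams(BaseModel):
    """Synthetic-recording parameters: heartbeat statistics and chest motion."""

    model_config = ConfigDict(extra="forbid")

    duration_s: float = Field(default=15.0, gt=0)
    mean_ibi_ms: float = Field(default=850.0, ge=400, le=1500)
    sdnn_ms: float = Field(default=40.0, ge=0)
    ar_coefficient: float = Field(default=0.3, ge=0, lt=1)
    resp_rate_hz: float = Field(default=0.25, gt=0)
    resp_amp_m: float = Field(default=5.0e-3, ge=0)
    resp_harmonics: tuple[float, ...] = (1.0, 0.3)
    heart_amp_m: float = Field(default=3.0e-4, ge=0)
    beat_kernel_duration_s: float = Field(default=0.12, gt=0)
    noise_sd_m: float = Field(default=0.0, ge=0)
    r0_m: float = Field(default=0.6, gt=0)
    theta_rad: float = 0.0
    snr_db: float | None = 20.0

    def n_beats(self) -> int:
        return max(2, int(round(self.duration_s * 1e3 / self.mean_ibi_ms)))


class EnhanceParams(BaseModel):
    """Heartbeat-enhancement parameters (power window and beat-length bounds)."""

    model_config = ConfigDict(extra="forbid")

    power_window_s: float = Field(default=0.4, gt=0)
    min_beat_s: float = Field(default=0.5, gt=0)
    max_beat_s: float = Field(default=1.2, gt=0)
    bpf_low_hz: float = Field(default=0.8, gt=0)
    bpf_high_hz: float = Field(default=1.5, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "EnhanceParams":
        if self.min_beat_s >= self.max_beat_s:
            raise ValueError("min_beat_s must be below max_beat_s")
        if self.bpf_low_hz >= self.bpf_high_hz:
            raise ValueError("bpf_low_hz must be below bpf_high_hz")
        return self


class EvalParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cdf_thresholds_ms: tuple[float, ...] = (4.0, 8.0, 16.0)
    max_shift_s: float = Field(default=5.0, gt=0)


class PipelineConfig(BaseModel):
    """Full end-to-end run configuration (simulate -> demod -> enhance ->
    segment -> evaluate).  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    chirp: ChirpConfig = ChirpConfig()
    sim: SimParams = SimParams()
    enhance: EnhanceParams = EnhanceParams()
    optimizer: OptimizerParams = OptimizerParams()
    evaluation: EvalParams = EvalParams()
    working_fs_hz: float = Field(default=WORKING_FS_HZ, gt=0)
    diagonal_loading: float = Field(default=1e-3, ge=0)
    seed: int = 0
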