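"""File formats: CSV series, JSON reports/configs, and the binary IF-cube
container.

Cube container (``.rvh``): an 8-byte little-endian unsigned header length,
a UTF-8 JSON header (magic ``RVH1``, the chirp configuration, the cube
shape, SNR and seed), then float32 interleaved real/imag samples in
frame-major order (frame, antenna, fast sample).  A raw-capture variant
(interleaved int16 I/Q, frame-major, chirp configuration in a JSON sidecar)
is read through the same entry point with ``fmt="raw"``.

All writes are atomic (temp file + rename).
"""
from __future__ import annotations

import json
import os
import struct
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ChirpConfig
from .enhance import AccelSignal, PowerSignal, Segmentation
from .hrv import IBISeries
from .preprocess import PhaseSignal
from .sim import IFDataCube, MotionProfile

MAGIC = "RVH1"


@contextmanager
def atomic_write(path, mode="w"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cube(path, cube: IFDataCube) -> None:
    header = {
        "magic": MAGIC,
        "config": cube.config.model_dump(),
        "shape": list(cube.samples.shape),
        "noise_snr_db": cube.noise_snr_db,
        "seed": cube.seed,
        "dtype": "float32-interleaved-iq",
    }
    blob = json.dumps(header).encode()
    inter = np.empty(cube.samples.shape + (2,), dtype="<f4")
    inter[..., 0] = cube.samples.real
    inter[..., 1] = cube.samples.imag
    with atomic_write(path, "wb") as fh:
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        fh.write(inter.tobytes())


def read_cube(path, fmt: str = "rvh", sidecar=None) -> IFDataCube:
    """Read an IF cube: native container (``rvh``) or raw int16 I/Q capture
    (``raw``, chirp config from the JSON ``sidecar``)."""
    path = Path(path)
    if fmt == "rvh":
        with open(path, "rb") as fh:
            (hlen,) = struct.unpack("<Q", fh.read(8))
            header = json.loads(fh.read(hlen).decode())
            if header.get("magic") != MAGIC:
                raise ValueError("not a cube container (bad magic)")
            shape = tuple(header["shape"])
            raw = np.frombuffer(fh.read(), dtype="<f4").reshape(shape + (2,))
        cfg = ChirpConfig(**header["config"])
        samples = (raw[..., 0] + 1j * raw[..., 1]).astype(complex)
        return IFDataCube(
            samples=samples,
            config=cfg,
            noise_snr_db=header.get("noise_snr_db"),
            seed=header.get("seed"),
        )
    if fmt == "raw":
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        with open(sidecar) as fh:
            cfg = ChirpConfig(**json.load(fh))
        flat = np.fromfile(path, dtype="<i2").astype(float)
        iq = flat.reshape(-1, 2)
        m, n = cfg.azimuth_virtual_count, cfg.samples_per_chirp
        samples = (iq[:, 0] + 1j * iq[:, 1]).reshape(-1, m, n)
        return IFDataCube(samples=samples, config=cfg)
    raise ValueError(f"unknown cube format {fmt!r}")


def write_motion_csv(path, motion: MotionProfile) -> None:
    df = pd.DataFrame(
        {
            "time_s": motion.times_s,
            "displacement_m": motion.displacement,
            "resp_m": motion.respiration_component,
            "heart_m": motion.heartbeat_component,
        }
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_phase_csv(path, signal: PhaseSignal) -> None:
    df = pd.DataFrame(
        {"time_s": signal.times_s, "displacement_m": signal.displacement}
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def read_phase_csv(path, origin: str = "csv") -> PhaseSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("phase CSV needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return PhaseSignal(
        displacement=df["displacement_m"].to_numpy(), fs=fs, origin=origin
    )


def write_accel_csv(path, a: AccelSignal, p: PowerSignal | None = None) -> None:
    data = {"time_s": np.arange(len(a.values)) / a.fs, "accel": a.values}
    if p is not None:
        data["power"] = p.values
    with atomic_write(path) as fh:
        pd.DataFrame(data).to_csv(fh, index=False)


def read_accel_csv(path) -> AccelSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return AccelSignal(values=df["accel"].to_numpy(), fs=fs)


def write_cutoffs_csv(path, s: Segmentation) -> None:
    df = pd.DataFrame(
        {"index": np.arange(len(s.cutoffs)), "cutoff_sample": s.cutoffs}
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def read_cutoffs_csv(path, fs: float) -> Segmentation:
    df = pd.read_csv(path)
    return Segmentation(cutoffs=df["cutoff_sample"].to_numpy(dtype=int), fs=fs)


def write_ibis_csv(path, ibis: IBISeries) -> None:
    df = pd.DataFrame(
        {"index": np.arange(len(ibis.intervals)), "ibi_ms": ibis.intervals}
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def read_ibis_csv(path, source: str = "reference") -> IBISeries:
    df = pd.read_csv(path)
    return IBISeries(intervals=df["ibi_ms"].to_numpy(), source=source)


def write_json(path, obj) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
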