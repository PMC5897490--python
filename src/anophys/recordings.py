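"""Data model and portable on-disk container for episodic recordings.

An episodic whole-cell recording is a sweep matrix (sweeps x samples, pA)
driven by a step protocol.  The container is deliberately language
neutral and diffable: a directory holding ``meta.json`` (protocol +
metadata with explicit units) and ``sweeps.csv`` (first column time in
ms, one column per sweep).  Fluorescence time courses use ``fluor.csv``
(time_min, F_raw, F_background).  Readers tolerate trailing newlines and
``#`` comment lines; writers print floats with 17 significant digits so
round trips are bit exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dataclasses_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "VoltageProtocol",
    "RecordingMeta",
    "Recording",
    "FluorTrace",
    "FormatError",
    "build_step_protocol",
    "voltage_at",
    "write_recording",
    "read_recording",
    "write_fluor_trace",
    "read_fluor_trace",
]


class FormatError(ValueError):
    """Malformed on-disk container; the message names the offending field."""


class VoltageProtocol(BaseModel):
    """Episodic step protocol: baseline -> (optional prepulse) -> step -> tail.

    The standard activation protocol holds at 0 mV, steps for 300 ms from
    -100 to +180 mV in 20-mV increments and closes with a 175-ms tail to
    -80 mV.  Reversal-potential (tail) protocols add a fixed activating
    prepulse before the variable step.
    """

    holding_mV: float = 0.0
    start_mV: float
    stop_mV: float
    increment_mV: float
    step_ms: float
    tail_mV: Optional[float] = None
    tail_ms: float = 0.0
    baseline_ms: float = 50.0
    prepulse_mV: Optional[float] = None
    prepulse_ms: float = 0.0
    sampling_khz: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "VoltageProtocol":
        if self.increment_mV == 0:
            raise ValueError("increment must be non-zero")
        span = self.stop_mV - self.start_mV
        n = span / self.increment_mV
        if abs(n - round(n)) > 1e-9 or round(n) < 0:
            raise ValueError("(stop - start) must be a non-negative multiple of increment")
        for name in ("step_ms", "sampling_khz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tail_ms", "baseline_ms", "prepulse_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tail_ms > 0 and self.tail_mV is None:
            raise ValueError("tail_mV required when tail_ms > 0")
        if self.prepulse_ms > 0 and self.prepulse_mV is None:
            raise ValueError("prepulse_mV required when prepulse_ms > 0")
        return self

    @property
    def n_sweeps(self) -> int:
        return int(round((self.stop_mV - self.start_mV) / self.increment_mV)) + 1

    @property
    def step_voltages(self) -> np.ndarray:
        return self.start_mV + self.increment_mV * np.arange(self.n_sweeps)

    @property
    def total_ms(self) -> float:
        return self.baseline_ms + self.prepulse_ms + self.step_ms + self.tail_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.total_ms * self.sampling_khz))

    @property
    def step_start_ms(self) -> float:
        return self.baseline_ms + self.prepulse_ms

    @property
    def tail_start_ms(self) -> float:
        return self.step_start_ms + self.step_ms

    def time_ms(self) -> np.ndarray:
        """Sample times (ms), left-aligned on each sampling interval."""
        return np.arange(self.n_samples) / self.sampling_khz


def build_step_protocol(holding_mV: float = 0.0, start_mV: float = -100.0,
                        stop_mV: float = 180.0, increment_mV: float = 20.0,
                        step_ms: float = 300.0, tail_mV: float | None = -80.0,
                        tail_ms: float = 175.0, rate_khz: float = 5.0,
                        baseline_ms: float = 50.0,
                        prepulse_mV: float | None = None,
                        prepulse_ms: float = 0.0) -> VoltageProtocol:
    """Standard episodic step protocol; defaults give the -100..+180 mV IV."""
    return VoltageProtocol(
        holding_mV=holding_mV, start_mV=start_mV, stop_mV=stop_mV,
        increment_mV=increment_mV, step_ms=step_ms, tail_mV=tail_mV,
        tail_ms=tail_ms, baseline_ms=baseline_ms, prepulse_mV=prepulse_mV,
        prepulse_ms=prepulse_ms, sampling_khz=rate_khz,
    )


def voltage_at(protocol: VoltageProtocol, sweep_index: int, t_ms: float) -> float:
    """Piecewise-constant command voltage of ``sweep_index`` at time ``t_ms``."""
    if not 0 <= sweep_index < protocol.n_sweeps:
        raise IndexError(f"sweep index {sweep_index} out of range")
    if not 0.0 <= t_ms <= protocol.total_ms:
        raise IndexError(f"time {t_ms} ms outside protocol span")
    if t_ms < protocol.baseline_ms:
        return protocol.holding_mV
    if t_ms < protocol.step_start_ms:
        return float(protocol.prepulse_mV)
    if t_ms < protocol.tail_start_ms:
        return float(protocol.step_voltages[sweep_index])
    return float(protocol.tail_mV if protocol.tail_mV is not None
                 else protocol.holding_mV)


@dataclass
class RecordingMeta:
    """Cell-level metadata attached to a recording."""

    construct: str = "unknown"
    cell_line: str = "HEK293"
    ca_free_um: float = 0.0
    cell_id: str = "cell0"
    seed: Optional[int] = None
    transfected: bool = True
    extra: dict = dataclasses_field(default_factory=dict)

    def model_dump(self) -> dict:
        return asdict(self)


@dataclass
class Recording:
    """Sweep matrix (sweeps x samples, pA) plus protocol and metadata."""

    sweeps_pA: np.ndarray
    protocol: VoltageProtocol
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.sweeps_pA = np.asarray(self.sweeps_pA, dtype=float)
        if self.sweeps_pA.ndim != 2:
            raise ValueError("sweep matrix must be 2-D (sweeps x samples)")
        if self.sweeps_pA.shape[0] != self.protocol.n_sweeps:
            raise ValueError(
                f"sweep count {self.sweeps_pA.shape[0]} != protocol "
                f"step count {self.protocol.n_sweeps}"
            )
        if self.sweeps_pA.shape[1] != self.protocol.n_samples:
            raise ValueError(
                f"sample count {self.sweeps_pA.shape[1]} != protocol "
                f"duration x rate = {self.protocol.n_samples}"
            )

    @property
    def time_ms(self) -> np.ndarray:
        return self.protocol.time_ms()


@dataclass
class FluorTrace:
    """Annexin-V ROI fluorescence time course for one cell.

    ``f_norm`` is populated by the cohort-level normalisation
    (:func:`anophys.scrambling.delta_f_norm`); raw traces carry None there.
    """

    time_min: np.ndarray
    f_raw: np.ndarray
    f_background: float
    cell_id: str = "cell0"
    transfected: bool = True
    f_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        if self.time_min.shape != self.f_raw.shape:
            raise ValueError("time and fluorescence arrays differ in length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time base must be strictly increasing")


# ---------------------------------------------------------------------------
# on-disk container

_FLOAT_FMT = "%.17g"


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write ``meta.json`` + ``sweeps.csv`` into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "units": {"current": "pA", "voltage": "mV", "time": "ms"},
        "protocol": recording.protocol.model_dump(),
        "meta": recording.meta.model_dump(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    header = "time_ms," + ",".join(
        f"sweep{j:02d}" for j in range(recording.protocol.n_sweeps))
    table = np.column_stack([recording.time_ms, recording.sweeps_pA.T])
    np.savetxt(path / "sweeps.csv", table, delimiter=",", fmt=_FLOAT_FMT,
               header=header, comments="")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording container, validating shapes against the protocol."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    raw = json.loads(meta_path.read_text())
    for key in ("protocol", "meta"):
        if key not in raw:
            raise FormatError(f"meta.json missing field {key!r}")
    protocol = VoltageProtocol(**raw["protocol"])
    meta = RecordingMeta(**raw["meta"])
    table = _read_csv(path / "sweeps.csv")
    if table.shape[1] != protocol.n_sweeps + 1:
        raise FormatError(
            f"sweeps.csv has {table.shape[1] - 1} sweep columns, protocol "
            f"defines {protocol.n_sweeps}"
        )
    sweeps = table.iloc[:, 1:].to_numpy().T
    return Recording(sweeps_pA=sweeps, protocol=protocol, meta=meta)


def write_fluor_trace(trace: FluorTrace, path: str | Path) -> Path:
    """Write a fluorescence time course as ``fluor.csv`` + ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "units": {"time": "min", "fluorescence": "a.u."},
        "f_background": trace.f_background,
        "cell_id": trace.cell_id,
        "transfected": trace.transfected,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    bg = np.full_like(trace.time_min, trace.f_background)
    table = np.column_stack([trace.time_min, trace.f_raw, bg])
    np.savetxt(path / "fluor.csv", table, delimiter=",", fmt=_FLOAT_FMT,
               header="time_min,F_raw,F_background", comments="")
    return path


def read_fluor_trace(path: str | Path) -> FluorTrace:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    raw = json.loads(meta_path.read_text())
    table = _read_csv(path / "fluor.csv")
    if table.shape[1] != 3:
        raise FormatError("fluor.csv must have columns time_min,F_raw,F_background")
    return FluorTrace(
        time_min=table.iloc[:, 0].to_numpy(),
        f_raw=table.iloc[:, 1].to_numpy(),
        f_background=float(raw["f_background"]),
        cell_id=str(raw.get("cell_id", "cell0")),
        transfected=bool(raw.get("transfected", True)),
    )
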