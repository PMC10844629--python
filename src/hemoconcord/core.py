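"""Shared domain types, unit conventions, resampling and delimited-text I/O.

The analyses in this package operate on per-device hemodynamic time series
(cardiac output, stroke volume, heart rate, pressures) sampled at device-
specific cadences.  Streams are paired on a common fixed-step grid (default
5 s, the fastest native cadence among the devices considered) by
last-observation-carried-forward, never interpolation, so that no dynamics
are invented between slow samples.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("hemoconcord")

#: Default common analysis grid step in seconds.
DEFAULT_GRID_STEP = 5.0

#: A grid point may carry an observation forward at most this many native
#: cadences before it is declared missing.
LOCF_HOLD_FACTOR = 3.0


class Device(str, enum.Enum):
    """Measurement device identity."""

    UFS = "UFS"            # ultrasonic flow sensor around the pulmonary artery
    EIT = "EIT"            # electrical impedance tomography monitor
    PAC_CCO = "PAC_CCO"    # continuous thermodilution via pulmonary-artery catheter
    APCO = "APCO"          # arterial-pressure pulse-contour cardiac output
    MONITOR = "MONITOR"    # bedside patient monitor (pressures, HR)


class Modality(str, enum.Enum):
    CO = "CO"      # cardiac output, L/min
    SV = "SV"      # stroke volume, mL (or a.u. before calibration)
    HR = "HR"      # heart rate, bpm
    MAP = "MAP"    # mean arterial pressure, mmHg
    ABP = "ABP"    # arterial blood pressure, mmHg
    CVP = "CVP"    # central venous pressure, mmHg
    PAP = "PAP"    # pulmonary artery pressure, mmHg


#: Units admissible for each modality.
UNITS_FOR_MODALITY: Mapping[Modality, tuple[str, ...]] = {
    Modality.CO: ("L/min", "a.u."),
    Modality.SV: ("mL", "a.u."),
    Modality.HR: ("bpm",),
    Modality.MAP: ("mmHg",),
    Modality.ABP: ("mmHg",),
    Modality.CVP: ("mmHg",),
    Modality.PAP: ("mmHg",),
}


class StudyArm(str, enum.Enum):
    STUDY1 = "STUDY1"  # no flow probe; continuous thermodilution is the reference
    STUDY2 = "STUDY2"  # flow probe present and used as reference


@dataclass(frozen=True)
class DeviceStream:
    """One measured channel: irregular timestamps plus finite values.

    ``times`` are seconds from study start and must be strictly increasing;
    sample time is the end of the device's internal averaging interval.
    """

    device: Device
    modality: Modality
    unit: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and of equal length")
        if t.size < 2:
            raise ValueError("stream must contain at least 2 samples")
        if not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"non-increasing time at row {bad + 1}")
        if not np.all(np.isfinite(v)):
            raise ValueError("stream values must be finite")
        if not np.all(np.isfinite(t)):
            raise ValueError("stream times must be finite")
        allowed = UNITS_FOR_MODALITY[self.modality]
        if self.unit not in allowed:
            raise ValueError(
                f"unit {self.unit!r} inconsistent with modality {self.modality.value}"
                f" (expected one of {allowed})"
            )

    @property
    def cadence(self) -> float:
        """Native sampling cadence, estimated as the median time step."""
        return float(np.median(np.diff(self.times)))

    def shifted(self, offset: float) -> "DeviceStream":
        """Return a copy with ``offset`` seconds added to every timestamp."""
        return replace(self, times=self.times + offset)


@dataclass
class StudyRecord:
    """All streams for one animal, plus synthetic-only ground truth."""

    animal_id: str
    streams: list[DeviceStream]
    study_arm: StudyArm
    ground_truth: dict[Modality, "GridSeries"] | None = None
    clock_offsets: dict[Device, float] | None = None
    injected: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.study_arm is StudyArm.STUDY1 and any(
            s.device is Device.UFS for s in self.streams
        ):
            raise ValueError("STUDY1 records must not contain UFS streams")

    def get(self, device: Device, modality: Modality) -> DeviceStream:
        for s in self.streams:
            if s.device is device and s.modality is modality:
                return s
        raise KeyError(f"no {device.value}/{modality.value} stream in record {self.animal_id}")

    def has(self, device: Device, modality: Modality) -> bool:
        return any(s.device is device and s.modality is modality for s in self.streams)

    @property
    def devices(self) -> list[Device]:
        seen: list[Device] = []
        for s in self.streams:
            if s.device not in seen:
                seen.append(s.device)
        return seen


@dataclass(frozen=True)
class GridSeries:
    """Values on a fixed-step time grid; missing entries are NaN.

    Sample ``k`` is at time ``t0 + k * step``.
    """

    t0: float
    step: float
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(self.values.size)

    @property
    def end(self) -> float:
        return self.t0 + self.step * (self.values.size - 1)

    def __len__(self) -> int:
        return int(self.values.size)

    def index_of(self, t: float) -> int:
        k = (t - self.t0) / self.step
        ki = int(round(k))
        if abs(k - ki) > 1e-9 or not (0 <= ki < len(self)):
            raise KeyError(f"time {t} not on grid")
        return ki

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "GridSeries":
        return GridSeries(self.t0, self.step, values, self.unit if unit is None else unit)


def same_grid(a: GridSeries, b: GridSeries, tol: float = 1e-9) -> bool:
    return (
        abs(a.t0 - b.t0) <= tol
        and abs(a.step - b.step) <= tol
        and len(a) == len(b)
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Stream files are two-column text (time_s, value) with
# an optional header; the naming convention is {animal}_{device}_{modality}.csv.
# ---------------------------------------------------------------------------

def read_stream(path: str | Path, device: Device, modality: Modality,
                unit: str | None = None, delimiter: str = ",") -> DeviceStream:
    """Read a two-column delimited text file into a validated DeviceStream.

    Rows with non-finite values are dropped (count logged); non-monotone
    timestamps are a hard error naming the first offending row.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}: row {lineno} does not have 2 columns")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}: unparseable row {lineno}: {line!r}")
            times.append(t)
            values.append(v)
    if not times:
        raise ValueError(f"{path}: empty stream file")
    t = np.array(times)
    v = np.array(values)
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValueError(f"{path}: non-increasing time at row {bad}")
    keep = np.isfinite(v)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d rows with non-finite values", path, dropped)
    if unit is None:
        unit = UNITS_FOR_MODALITY[modality][0]
    return DeviceStream(device, modality, unit, t[keep], v[keep])


def write_stream(stream: DeviceStream, path: str | Path, delimiter: str = ",") -> None:
    """Write a stream as two-column delimited text with a header row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"time_s{delimiter}value\n")
        for t, v in zip(stream.times, stream.values):
            fh.write(f"{t:.6g}{delimiter}{v:.6g}\n")


def stream_filename(animal_id: str, device: Device, modality: Modality) -> str:
    return f"{animal_id}_{device.value}_{modality.value}.csv"


# ---------------------------------------------------------------------------
# Resampling and derived quantities
# ---------------------------------------------------------------------------

def resample_to_grid(stream: DeviceStream, step: float = DEFAULT_GRID_STEP,
                     span: tuple[float, float] | None = None) -> GridSeries:
    """Last-observation-carried-forward resampling onto a fixed grid.

    Each grid point holds the most recent observation at or before it.  An
    observation is held for at most ``LOCF_HOLD_FACTOR`` native cadences;
    grid points beyond that (or before the first observation) are missing.
    """
    t, v = stream.times, stream.values
    if span is None:
        span = (float(t[0]), float(t[-1]))
    start, end = span
    if end < t[0] or start > t[-1]:
        raise ValueError("empty overlap between span and stream")
    n = int(np.floor((end - start) / step + 1e-9)) + 1
    grid_t = start + step * np.arange(n)
    # index of most recent observation at or before each grid time
    idx = np.searchsorted(t, grid_t + 1e-9) - 1
    out = np.full(n, np.nan)
    valid = idx >= 0
    hold = LOCF_HOLD_FACTOR * stream.cadence
    age = np.where(valid, grid_t - t[np.clip(idx, 0, None)], np.inf)
    ok = valid & (age <= hold + 1e-9)
    out[ok] = v[idx[ok]]
    return GridSeries(start, step, out, stream.unit)


def centered_moving_average(values: np.ndarray, step: float, window: float) -> np.ndarray:
    """Centered boxcar mean over ``window`` seconds; edges use the available
    part of the window.  A centered window adds no phase shift, so smoothing
    and latency stay separate concerns."""
    half = int(round(window / (2.0 * step)))
    if half <= 0:
        return values
    w = 2 * half + 1
    kern = np.ones(w)
    finite = np.isfinite(values)
    num = np.convolve(np.where(finite, values, 0.0), kern, mode="same")
    den = np.convolve(finite.astype(float), kern, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def sample_to_grid(stream: DeviceStream, step: float = DEFAULT_GRID_STEP,
                   span: tuple[float, float] | None = None) -> GridSeries:
    """Place each observation at its nearest grid point; no carry-forward.

    Grid points farther than half a step from any observation stay missing.
    Used where held (LOCF) values would bias a time estimate — a value held
    forward for a slow device's whole cadence looks, to a lag estimator,
    like extra delay of half that cadence.
    """
    t, v = stream.times, stream.values
    if span is None:
        span = (float(t[0]), float(t[-1]))
    start = step * np.ceil((span[0] - 1e-9) / step)
    end = min(span[1], float(t[-1]))
    n = int(np.floor((end - start) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty overlap between span and stream")
    out = np.full(n, np.nan)
    idx = np.round((t - start) / step).astype(int)
    near = np.abs(t - (start + idx * step)) <= step / 2 + 1e-9
    ok = near & (idx >= 0) & (idx < n)
    out[idx[ok]] = v[ok]
    return GridSeries(start, step, out, stream.unit)


def derive_co(sv: GridSeries, hr: GridSeries) -> GridSeries:
    """Cardiac output in L/min from stroke volume (mL) and heart rate (bpm).

    CO = SV * HR / 1000, pointwise on a shared grid; missing propagates.
    """
    if not same_grid(sv, hr):
        raise ValueError("stroke-volume and heart-rate series are on different grids")
    unit = "L/min" if sv.unit == "mL" else "a.u."
    return sv.with_values(sv.values * hr.values / 1000.0, unit)


def overlap_grids(a: GridSeries, b: GridSeries) -> tuple[GridSeries, GridSeries]:
    """Trim two same-step series to their common time span."""
    if abs(a.step - b.step) > 1e-9:
        raise ValueError("grid steps differ")
    start = max(a.t0, b.t0)
    end = min(a.end, b.end)
    if end < start:
        raise ValueError("grids do not overlap")

    def cut(g: GridSeries) -> GridSeries:
        i0 = int(round((start - g.t0) / g.step))
        i1 = int(round((end - g.t0) / g.step))
        return GridSeries(start, g.step, g.values[i0:i1 + 1], g.unit)

    return cut(a), cut(b)
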