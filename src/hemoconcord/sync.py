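"""Clock alignment across devices by heart-rate cross-correlation.

Each monitor records heart rate from the same animal, so HR is the one
channel shared by every device; maximizing the lagged Pearson correlation
between HR channels over the whole study recovers the constant clock offset
between a device and the reference recorder.  Lags are searched at grid-step
resolution only — held (LOCF) data cannot support finer alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Device, GridSeries, StudyRecord, centered_moving_average, logger

#: Default lag search half-window, s; device clocks differ by minutes at most.
DEFAULT_MAX_LAG = 600.0

#: Minimum usable overlap between the two HR channels after shifting, s.
MIN_OVERLAP = 600.0

#: Both HR channels are averaged over this window before correlating.  The
#: symmetric window shifts no timing but averages monitor jitter down, which
#: keeps the correlation peak from wandering a grid step under noise.
DEFAULT_HR_SMOOTH = 30.0


@dataclass(frozen=True)
class AlignmentResult:
    device: Device
    offset: float                 # seconds to ADD to the device's timestamps
    peak_corr: float
    lag_profile: list[tuple[float, float]]  # (lag, correlation)


def _corr_at_index_shift(ref: np.ndarray, dev: np.ndarray, shift: int) -> tuple[float, int]:
    """Pearson correlation between ref[k] and dev[k + shift] over complete pairs."""
    n_ref, n_dev = len(ref), len(dev)
    k0 = max(0, -shift)
    k1 = min(n_ref, n_dev - shift)
    if k1 - k0 < 2:
        return np.nan, 0
    a = ref[k0:k1]
    b = dev[k0 + shift:k1 + shift]
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 2:
        return np.nan, n
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan, n
    return float(np.mean((a - a.mean()) / sa * (b - b.mean()) / sb)), n


def estimate_offset(hr_ref: GridSeries, hr_dev: GridSeries,
                    max_lag: float = DEFAULT_MAX_LAG,
                    device: Device = Device.MONITOR,
                    presmooth: float = DEFAULT_HR_SMOOTH) -> AlignmentResult:
    """Estimate the clock offset of a device HR channel against a reference.

    Searches lags L in [-max_lag, +max_lag] at grid resolution for the L
    maximizing corr(ref(t), dev(t+L)); the offset to add to the device's
    timestamps is -L.  Ties break toward the smallest |L|, then negative L.
    ``presmooth`` averages both channels symmetrically first (0 disables).
    """
    if abs(hr_ref.step - hr_dev.step) > 1e-9:
        raise ValueError("HR series must share the grid step")
    step = hr_ref.step
    rv, dv = hr_ref.values, hr_dev.values
    if np.nanstd(rv) == 0 or np.nanstd(dv) == 0:
        raise ValueError("HR uninformative for alignment (zero variance)")
    if presmooth > 0:
        rv = centered_moving_average(rv, step, presmooth)
        dv = centered_moving_average(dv, step, presmooth)
    kmax = int(round(max_lag / step))
    base_shift = (hr_ref.t0 - hr_dev.t0) / step
    if abs(base_shift - round(base_shift)) > 1e-6:
        raise ValueError("HR series grids are not commensurate")
    base_shift = int(round(base_shift))
    min_pairs = max(2, int(round(MIN_OVERLAP / step)))

    profile: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None  # (corr, lag)
    for k in range(-kmax, kmax + 1):
        lag = k * step
        c, n = _corr_at_index_shift(rv, dv, base_shift + k)
        if n < min_pairs:
            c = np.nan
        profile.append((lag, c))
        if np.isnan(c):
            continue
        if best is None:
            best = (c, lag)
        else:
            bc, bl = best
            # ties: smallest |lag|, then negative lag
            if c > bc + 1e-12 or (abs(c - bc) <= 1e-12 and
                                  (abs(lag) < abs(bl) - 1e-9 or
                                   (abs(abs(lag) - abs(bl)) <= 1e-9 and lag < bl))):
                best = (c, lag)
    if best is None:
        raise ValueError("no lag with sufficient overlap in the search window")
    peak_corr, lag = best
    return AlignmentResult(device=device, offset=-lag, peak_corr=peak_corr,
                           lag_profile=profile)


def apply_alignment(rec: StudyRecord, results: list[AlignmentResult],
                    reference: Device) -> StudyRecord:
    """Shift every stream of each non-reference device by its estimated offset.

    The reference device is left untouched; a present non-reference device
    without a result is an error (silent misalignment is worse than failure).
    """
    by_dev = {r.device: r for r in results}
    missing = [d for d in rec.devices if d is not reference and d not in by_dev]
    if missing:
        raise ValueError(
            f"missing alignment result for device(s) {[d.value for d in missing]}")
    new_streams = []
    for s in rec.streams:
        if s.device is reference:
            new_streams.append(s)
        else:
            off = by_dev[s.device].offset
            new_streams.append(s.shifted(off))
            if off != 0:
                logger.debug("%s: %s shifted by %+g s", rec.animal_id,
                             s.device.value, off)
    return replace(rec, streams=new_streams)
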