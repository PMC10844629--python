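"""Single-point volume calibration of relative stroke-volume streams.

Impedance-based monitors report stroke volume in arbitrary units (and
pulse-contour devices carry demographic-formula bias), so each device-under-
test stream is brought to the reference scale with one multiplicative
factor, ScaleFactor = SV_REF(t0) / SV_DUT(t0), taken at the first paired
datum of the baseline/stabilization period.  No additive offset is used.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Device, GridSeries, same_grid

#: Default stabilization period skipped before picking the calibration
#: datum, s; pressures are held in the target band for at least this long
#: at the start of an experiment.
DEFAULT_STABILIZATION_SKIP = 600.0


@dataclass(frozen=True)
class CalibrationFactor:
    scale: float          # unitless multiplier, SV_REF(t0)/SV_DUT(t0)
    t0: float             # time of the calibration pair, s
    ref_device: Device
    dut_device: Device
    sv_ref_t0: float
    sv_dut_t0: float
    ref_unit: str = "mL"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("calibration scale must be positive")


def compute_scale(sv_ref: GridSeries, sv_dut: GridSeries,
                  baseline_window: tuple[float, float],
                  ref_device: Device = Device.UFS,
                  dut_device: Device = Device.EIT,
                  t0: float | None = None,
                  window_mean: bool = False) -> CalibrationFactor:
    """Scale factor from the first complete pair in the baseline window.

    With ``t0`` given, the pair at exactly that grid time is used instead
    (so several device-under-test streams can share one reference datum).
    ``window_mean=True`` averages all complete pairs in the window rather
    than using a single pair; it is off by default — the single-point rule
    is the defined procedure, robustness notwithstanding.
    """
    if abs(sv_ref.step - sv_dut.step) > 1e-9:
        raise ValueError("series must share the grid step")
    lo, hi = baseline_window
    tr, vr = sv_ref.times, sv_ref.values
    td, vd = sv_dut.times, sv_dut.values

    def value_at(g: GridSeries, t: float) -> float:
        k = (t - g.t0) / g.step
        ki = int(round(k))
        if abs(k - ki) > 1e-6 or not (0 <= ki < len(g)):
            return np.nan
        return float(g.values[ki])

    if t0 is not None:
        r, d = value_at(sv_ref, t0), value_at(sv_dut, t0)
        if not (np.isfinite(r) and np.isfinite(d)):
            raise ValueError(f"no complete pair at requested t0={t0}")
        chosen_t0 = float(t0)
    else:
        start = max(sv_ref.t0, sv_dut.t0, lo)
        end = min(sv_ref.end, sv_dut.end, hi)
        if end < start:
            raise ValueError("no overlap between series and baseline window")
        candidates = sv_ref.t0 + sv_ref.step * np.arange(len(sv_ref))
        candidates = candidates[(candidates >= start - 1e-9) & (candidates <= end + 1e-9)]
        pairs = [(t, value_at(sv_ref, t), value_at(sv_dut, t)) for t in candidates]
        pairs = [(t, r, d) for t, r, d in pairs if np.isfinite(r) and np.isfinite(d)]
        if not pairs:
            raise ValueError("no complete pair inside the baseline window")
        if window_mean:
            chosen_t0 = pairs[0][0]
            r = float(np.mean([p[1] for p in pairs]))
            d = float(np.mean([p[2] for p in pairs]))
        else:
            chosen_t0, r, d = pairs[0]
    if d <= 0:
        raise ValueError("device-under-test value at t0 must be positive")
    return CalibrationFactor(scale=r / d, t0=chosen_t0, ref_device=ref_device,
                             dut_device=dut_device, sv_ref_t0=r, sv_dut_t0=d,
                             ref_unit=sv_ref.unit)


def apply_scale(series: GridSeries, factor: CalibrationFactor) -> GridSeries:
    """Pointwise multiplication; the unit becomes the reference unit."""
    return series.with_values(series.values * factor.scale, factor.ref_unit)
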