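"""Internal processing-delay estimation for continuous thermodilution output.

Heating-coil thermodilution monitors average several minutes of data before
displaying a cardiac-output value, so their output lags the physiology by
5-12 minutes.  The lag is estimated per animal by sliding the device series
backward over a candidate-delay grid and minimizing the relative standard
deviation of the differences against a concurrently measured reference —
arterial pressure when no flow probe is present, flow-probe cardiac output
when one is.

Pressure (mmHg) and flow (L/min) cannot be differenced directly, so at each
candidate delay the device series is least-squares-scaled to the reference
over the overlap before differencing; the objective SD(diff)/mean(ref) is
then unit-free.  The full objective profile is retained so alternative
normalizations can be compared.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import DeviceStream, GridSeries, centered_moving_average, logger

#: Default candidate delays: 0-900 s at grid resolution, covering the
#: device's known 5-12 min latency with margin.
DEFAULT_MAX_DELAY = 900.0

#: Candidate delays with fewer complete pairs than this are excluded.
MIN_PAIRS = 100

#: Nominal averaging time of the thermodilution monitor's output, s.  The
#: reference is pre-averaged over this window before differencing (bandwidth
#: matching): the device output is a several-minute average, and comparing
#: it against an unaveraged reference leaves a shape mismatch at every
#: transition that a pure-shift fit misreads as extra delay.
DEFAULT_BANDWIDTH_MATCH = 300.0


@dataclass(frozen=True)
class DelayEstimate:
    tau: float                    # s; estimated internal delay
    objective: float              # relative SD of differences at tau
    profile: list[tuple[float, float]]  # (candidate delay, objective)
    reference_used: str           # "MAP" or "CO_UFS"


def default_delay_grid(step: float = 5.0,
                       max_delay: float = DEFAULT_MAX_DELAY) -> np.ndarray:
    return np.arange(0.0, max_delay + 1e-9, step)


def estimate_delay(ref: GridSeries, dut: GridSeries,
                   grid: Sequence[float] | None = None,
                   reference_used: str = "CO_UFS",
                   bandwidth_match: float = DEFAULT_BANDWIDTH_MATCH) -> DelayEstimate:
    """Minimize the relative SD of (ref - scaled, delay-advanced dut).

    For each candidate delay tau the device series is advanced by tau
    (device sample at t is paired with reference at t - tau), least-squares
    scaled to the reference over the complete overlap, and the objective
    SD(ref - a*dut) / mean(ref) evaluated.  Ties break toward the smallest
    tau.  The reference is first averaged over ``bandwidth_match`` seconds
    to match the device's output bandwidth (0 disables).
    """
    if abs(ref.step - dut.step) > 1e-9:
        raise ValueError("reference and device series must share the grid step")
    step = ref.step
    if bandwidth_match > 0:
        ref = ref.with_values(centered_moving_average(ref.values, step,
                                                      bandwidth_match))
    if grid is None:
        grid = default_delay_grid(step)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("candidate delays must be non-negative")

    rv, dv = ref.values, dut.values
    base = (ref.t0 - dut.t0) / step
    if abs(base - round(base)) > 1e-6:
        raise ValueError("series grids are not commensurate")
    base = int(round(base))
    shifts = []
    for tau in grid:
        m = tau / step
        if abs(m - round(m)) > 1e-6:
            raise ValueError(f"candidate delay {tau} is not a grid multiple")
        shifts.append(int(round(m)))
    max_shift = max(shifts)

    # Fixed support: only device samples whose reference partner exists at
    # EVERY candidate delay enter the objective.  A support that changed
    # with the candidate would tilt the profile — larger delays would drop
    # early-record (typically quiet baseline) pairs and shift the minimum.
    jidx = np.flatnonzero(np.isfinite(dv))
    jidx = jidx[(jidx - base - max_shift >= 0) & (jidx - base < len(rv))]
    if jidx.size < 2:
        raise ValueError("no candidate delay had sufficient overlap")
    b_all = dv[jidx]
    if np.nanmean(rv) <= 0:
        raise ValueError("reference mean must be positive")

    profile: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None  # (objective, tau)
    for tau, m in zip(grid, shifts):
        # device sample at time t is paired with the reference at t - tau
        a = rv[jidx - base - m]
        ok = np.isfinite(a)
        n = int(ok.sum())
        if n < MIN_PAIRS:
            logger.warning("delay candidate %g s excluded: only %d complete pairs",
                           tau, n)
            profile.append((float(tau), np.nan))
            continue
        aa, bb = a[ok], b_all[ok]
        mean_ref = aa.mean()
        if mean_ref <= 0:
            raise ValueError("reference mean must be positive")
        denom = float(np.dot(bb, bb))
        scale = float(np.dot(aa, bb)) / denom if denom > 0 else 0.0
        d = aa - scale * bb
        obj = float(d.std()) / mean_ref
        profile.append((float(tau), obj))
        if best is None or obj < best[0] - 1e-15:
            best = (obj, float(tau))
    if best is None:
        raise ValueError("no candidate delay had sufficient overlap")
    objective, tau = best
    return DelayEstimate(tau=tau, objective=objective, profile=profile,
                         reference_used=reference_used)


def combine_delay_profiles(estimates: Sequence[DelayEstimate]) -> DelayEstimate:
    """Pool delay estimates from channels sharing one internal delay.

    A thermodilution monitor derives its stroke-volume and cardiac-output
    outputs from the same delayed internal processing, so their objective
    profiles are evidence about a single delay; averaging the profiles over
    channels halves the noise variance of the minimum's location.  All
    estimates must share the candidate grid.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    if len(estimates) == 1:
        return estimates[0]
    taus = [tuple(t for t, _ in e.profile) for e in estimates]
    if len(set(taus)) != 1:
        raise ValueError("estimates use different candidate grids")
    objs = np.array([[o for _, o in e.profile] for e in estimates])
    with np.errstate(invalid="ignore"):
        mean_obj = np.nanmean(objs, axis=0)
    grid = np.asarray(taus[0])
    valid = np.isfinite(mean_obj)
    if not valid.any():
        raise ValueError("no candidate delay valid in all profiles")
    best = int(np.flatnonzero(valid)[np.argmin(mean_obj[valid])])
    return DelayEstimate(tau=float(grid[best]), objective=float(mean_obj[best]),
                         profile=list(zip(grid.tolist(), mean_obj.tolist())),
                         reference_used=estimates[0].reference_used)


def apply_delay(stream: DeviceStream, tau: float,
                study_start: float = 0.0) -> DeviceStream:
    """Attribute delayed device output to when the physiology occurred.

    Timestamps are decreased by tau; samples that would fall before the
    study start are dropped (their physiology predates the record).
    """
    if tau < 0:
        raise ValueError("delay must be non-negative")
    if tau >= stream.times[-1] - stream.times[0]:
        raise ValueError("delay exceeds the record length")
    if tau == 0:
        return stream
    t = stream.times - tau
    keep = t >= study_start - 1e-9
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("apply_delay: dropped %d samples preceding study start", dropped)
    return replace(stream, times=t[keep], values=stream.values[keep])
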