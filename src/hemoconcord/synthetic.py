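"""Synthetic multi-device hemodynamic study generator.

Emulates a 2-3 hour anesthetized-pig experiment in which preload, afterload
and contractility are perturbed in sequence (vasodilator, vasopressor,
inotropes, bleeding, volume resuscitation) while several cardiac-output
monitors record simultaneously:

* a flow-probe-like reference stream (5-s cadence, low noise),
* an impedance-monitor-like stream (5-s cadence, arbitrary units),
* a continuous-thermodilution-like stream (60-s cadence, heavily smoothed
  and delayed by 5-12 minutes),
* a pulse-contour-like stream (20-s cadence, noisier),
* a bedside monitor providing pressures.

Ground truth lives on a 5-s grid.  Hemodynamic state follows first-order
lags toward per-segment targets; mean arterial pressure is cardiac output
times a systemic-vascular-resistance latent, so pressure and flow co-move
the way the drug responses demand.  Each device observes the truth through
scale, centered moving-average smoothing, a pure delay, cadence
subsampling, multiplicative lognormal noise, and a clock offset.  All
randomness derives from a single seed.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_GRID_STEP,
    Device,
    DeviceStream,
    GridSeries,
    Modality,
    StudyArm,
    StudyRecord,
    centered_moving_average as _centered_moving_average,
    stream_filename,
    write_stream,
)


class InterventionKind(str, enum.Enum):
    BASELINE = "BASELINE"
    VASODILATOR = "VASODILATOR"
    VASOPRESSOR = "VASOPRESSOR"
    PULM_VASOPRESSOR = "PULM_VASOPRESSOR"
    POS_INOTROPE = "POS_INOTROPE"
    NEG_INOTROPE = "NEG_INOTROPE"
    BLEED = "BLEED"
    RESUSCITATE = "RESUSCITATE"


@dataclass(frozen=True)
class InterventionSegment:
    kind: InterventionKind
    start: float
    end: float
    magnitude: float = 0.3  # unitless effect scale in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.magnitude <= 1.0):
            raise ValueError("magnitude must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass(frozen=True)
class DeviceModel:
    """Observation model mapping ground truth to one device's output."""

    device: Device
    cadence: float            # s between flow/volume samples; one of 5, 20, 60
    delay: float = 0.0        # s of internal processing latency (pure shift)
    smooth_window: float = 0.0  # s, centered moving average
    scale: float = 1.0        # multiplicative gain (a.u. devices: far from 1)
    noise_cv: float = 0.0     # coefficient of variation, multiplicative lognormal
    clock_offset: float = 0.0  # s added to reported timestamps
    hr_cadence: float = 5.0   # HR channels update near-continuously on all monitors
    hr_noise_cv: float = 0.01
    unit: str = "mL"          # unit of the SV channel ("mL" or "a.u.")

    def __post_init__(self) -> None:
        if self.cadence not in (5.0, 20.0, 60.0, 5, 20, 60):
            raise ValueError("cadence must be one of 5, 20, 60 s")
        if self.delay < 0 or self.noise_cv < 0 or self.scale <= 0:
            raise ValueError("delay >= 0, noise_cv >= 0, scale > 0 required")


def study_segments(arm: StudyArm, duration: float = 9000.0) -> list[InterventionSegment]:
    """Default intervention sequence: baseline stabilization, then afterload,
    contractility and preload perturbations with recovery gaps; the second
    study arm adds a pulmonary vasopressor challenge."""
    K = InterventionKind
    # magnitudes sized so the effect-slope products give clinically typical
    # responses at study doses: dobutamine CO +30..40%, esmolol CO -20%,
    # controlled hemorrhage SV -25%, nitroprusside/phenylephrine MAP -/+20%
    segs = [
        InterventionSegment(K.BASELINE, 0, 1200, 0.0),
        InterventionSegment(K.VASODILATOR, 1200, 2100, 0.5),
        InterventionSegment(K.VASOPRESSOR, 2700, 3600, 0.5),
        InterventionSegment(K.POS_INOTROPE, 4100, 5000, 0.6),
        InterventionSegment(K.NEG_INOTROPE, 5500, 6400, 0.5),
    ]
    if arm is StudyArm.STUDY2:
        segs.append(InterventionSegment(K.PULM_VASOPRESSOR, 6700, 7300, 0.4))
    segs.append(InterventionSegment(K.BLEED, 7600, 8200, 0.5))
    segs.append(InterventionSegment(K.RESUSCITATE, 8200, min(9000, duration), 0.5))
    return [s for s in segs if s.end <= duration + 1e-9]


def default_device_models(arm: StudyArm) -> dict[Device, DeviceModel]:
    """Study-condition device models.  Delays and clock offsets marked NaN are
    drawn per animal by :func:`generate_study`."""
    models = {
        Device.EIT: DeviceModel(Device.EIT, cadence=5, scale=0.025,
                                noise_cv=0.08, unit="a.u."),
        Device.PAC_CCO: DeviceModel(Device.PAC_CCO, cadence=60, delay=np.nan,
                                    smooth_window=300.0, scale=1.0,
                                    noise_cv=0.05, clock_offset=np.nan),
        Device.APCO: DeviceModel(Device.APCO, cadence=20, smooth_window=20.0,
                                 scale=1.0, noise_cv=0.15, clock_offset=np.nan),
        Device.MONITOR: DeviceModel(Device.MONITOR, cadence=5, noise_cv=0.02,
                                    clock_offset=np.nan, unit="mmHg"),
    }
    if arm is StudyArm.STUDY2:
        models[Device.UFS] = DeviceModel(Device.UFS, cadence=5, noise_cv=0.03)
    return models


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_animals: int = 7
    arm: StudyArm = StudyArm.STUDY2
    duration: float = 9000.0
    grid_step: float = DEFAULT_GRID_STEP
    segments: list[InterventionSegment] | None = None
    device_models: dict[Device, DeviceModel] | None = None
    baseline: dict[str, float] = field(
        default_factory=lambda: {"SV0": 70.0, "HR0": 80.0, "MAP0": 75.0,
                                 "CVP0": 5.0, "PAP0": 20.0})
    lag_tau: float = 60.0          # s, first-order response time constant
    variability_cv: float = 0.03   # stationary CV of slow physiologic wander
    variability_tau: float = 120.0  # s, wander correlation time
    delay_range: tuple[float, float] = (282.0, 666.0)  # thermodilution latency draw
    clock_offset_max: float = 120.0  # s, +/- range of per-device clock error

    def __post_init__(self) -> None:
        if self.segments is None:
            self.segments = study_segments(self.arm, self.duration)
        if self.device_models is None:
            self.device_models = default_device_models(self.arm)
        ends = [s.end for s in self.segments]
        if ends and max(ends) > self.duration + 1e-9:
            raise ValueError("duration does not cover all segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("segments must be non-overlapping and ordered")
        if self.arm is StudyArm.STUDY1 and any(
                s.kind is InterventionKind.PULM_VASOPRESSOR for s in self.segments):
            raise ValueError("PULM_VASOPRESSOR only occurs in STUDY2 arms")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

# Multiplicative target per (intervention, channel); channels are stroke
# volume, heart rate, systemic vascular resistance, pulmonary pressure and
# central venous pressure.  Signs follow the pharmacology: vasodilator lowers
# resistance (pressure falls), vasopressor raises it, a positive inotrope
# raises stroke volume and heart rate, bleeding empties the preload.
_EFFECTS: Mapping[InterventionKind, Mapping[str, float]] = {
    InterventionKind.BASELINE: {},
    InterventionKind.VASODILATOR: {"SVR": -0.50, "HR": +0.15},   # SV sign is preload-dependent
    InterventionKind.VASOPRESSOR: {"SVR": +0.50, "HR": -0.10, "SV": -0.10},
    InterventionKind.PULM_VASOPRESSOR: {"PAP": +0.60, "SV": -0.05},
    InterventionKind.POS_INOTROPE: {"SV": +0.30, "HR": +0.30},
    InterventionKind.NEG_INOTROPE: {"SV": -0.25, "HR": -0.20},
    InterventionKind.BLEED: {"SV": -0.50, "HR": +0.25, "CVP": -0.30},
    InterventionKind.RESUSCITATE: {"SV": +0.15, "CVP": +0.10, "HR": -0.05},
}

#: Vasodilator stroke-volume response magnitude; its sign is set per animal
#: by the stressed-volume latent (high venous reserve -> SV rises as
#: afterload falls; depleted reserve -> SV falls with venodilation).
_VASODILATOR_SV = 0.20

_CHANNELS = ("SV", "HR", "SVR", "PAP", "CVP")


def _segment_targets(cfg: SyntheticConfig, times: np.ndarray,
                     stressed_volume: float,
                     magnitudes: Mapping[int, float] | None = None
                     ) -> dict[str, np.ndarray]:
    """Per-channel multiplicative target trajectory (1.0 = baseline)."""
    targets = {c: np.ones_like(times) for c in _CHANNELS}
    for i, seg in enumerate(cfg.segments):
        mag = seg.magnitude if magnitudes is None else magnitudes.get(i, seg.magnitude)
        mask = (times >= seg.start) & (times < seg.end)
        eff = dict(_EFFECTS[seg.kind])
        if seg.kind is InterventionKind.VASODILATOR:
            eff["SV"] = eff.get("SV", 0.0) + _VASODILATOR_SV * (2.0 * stressed_volume - 1.0)
        for ch, slope in eff.items():
            targets[ch][mask] = 1.0 + slope * mag
    return targets


def _first_order_lag(target: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """x' = (target - x)/tau, x(0) = target(0), exact exponential update."""
    alpha = 1.0 - np.exp(-dt / tau)
    x = np.empty_like(target)
    x[0] = target[0]
    for k in range(1, len(target)):
        x[k] = x[k - 1] + alpha * (target[k] - x[k - 1])
    return x


def _ou_log_wander(n: int, dt: float, cv: float, tau: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck wander on the log scale (mean 1)."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    phi = np.exp(-dt / tau)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    z = np.empty(n)
    z[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        z[k] = phi * z[k - 1] + eps[k - 1]
    return np.exp(z - 0.5 * sigma * sigma)


def generate_truth(cfg: SyntheticConfig, animal_index: int,
                   rng: np.random.Generator | None = None,
                   baseline: Mapping[str, float] | None = None,
                   stressed_volume: float = 0.8,
                   magnitudes: Mapping[int, float] | None = None,
                   ) -> dict[Modality, GridSeries]:
    """Ground-truth trajectories on the analysis grid.

    Returns stroke volume (mL), heart rate (bpm), mean arterial pressure
    (mmHg), central venous and pulmonary pressures (mmHg) and cardiac
    output (L/min), with CO = SV * HR / 1000 holding exactly pointwise.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 11, animal_index]))
    base = dict(cfg.baseline)
    if baseline:
        base.update(baseline)
    dt = cfg.grid_step
    n = int(np.floor(cfg.duration / dt)) + 1
    times = dt * np.arange(n)
    targets = _segment_targets(cfg, times, stressed_volume, magnitudes)
    mult = {ch: _first_order_lag(targets[ch], dt, cfg.lag_tau) for ch in _CHANNELS}
    wander_cv = {"SV": cfg.variability_cv, "HR": cfg.variability_cv * 0.6,
                 "SVR": cfg.variability_cv, "PAP": cfg.variability_cv,
                 "CVP": cfg.variability_cv}
    for ch in _CHANNELS:
        mult[ch] = mult[ch] * _ou_log_wander(n, dt, wander_cv[ch],
                                             cfg.variability_tau, rng)
    sv = base["SV0"] * mult["SV"]
    hr = base["HR0"] * mult["HR"]
    co = sv * hr / 1000.0
    co0 = base["SV0"] * base["HR0"] / 1000.0
    svr = (base["MAP0"] / co0) * mult["SVR"]  # mmHg per L/min
    mapp = co * svr
    cvp = base["CVP0"] * mult["CVP"]
    pap = base["PAP0"] * mult["PAP"]

    def g(vals: np.ndarray, unit: str) -> GridSeries:
        return GridSeries(0.0, dt, vals, unit)

    return {
        Modality.SV: g(sv, "mL"),
        Modality.HR: g(hr, "bpm"),
        Modality.CO: g(co, "L/min"),
        Modality.MAP: g(mapp, "mmHg"),
        Modality.CVP: g(cvp, "mmHg"),
        Modality.PAP: g(pap, "mmHg"),
    }


# ---------------------------------------------------------------------------
# Device observation
# ---------------------------------------------------------------------------



def _lognormal_factors(cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=n) - 0.5 * sigma * sigma)


def _sample_shifted(truth: GridSeries, sample_times: np.ndarray, delay: float) -> np.ndarray:
    """Evaluate truth at (sample_times - delay) by linear interpolation."""
    src = sample_times - delay
    return np.interp(src, truth.times, truth.values)


def observe(truth: Mapping[Modality, GridSeries], model: DeviceModel,
            rng: np.random.Generator | int) -> list[DeviceStream]:
    """Apply one device's observation model to the ground truth.

    Output value at device sample time s is
    ``scale * movingaverage(truth, smooth_window)(s - delay)`` with
    multiplicative lognormal noise of the model's CV; reported timestamps
    are s + clock_offset.  Every device also emits an HR channel (no delay,
    light jitter) — heart rate displays update in real time even on devices
    whose flow output is delayed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    any_truth = next(iter(truth.values()))
    duration = any_truth.end
    if model.delay + model.smooth_window >= duration:
        raise ValueError("device delay plus smoothing window exceeds record duration")

    streams: list[DeviceStream] = []

    def emit(modality: Modality, src: GridSeries, cadence: float, delay: float,
             window: float, scale: float, cv: float, unit: str) -> None:
        first = max(cadence, delay)  # no output before the device has data
        sample_times = np.arange(first, duration + 1e-9, cadence)
        smoothed = src.with_values(
            _centered_moving_average(src.values, src.step, window))
        vals = scale * _sample_shifted(smoothed, sample_times, delay)
        vals = vals * _lognormal_factors(cv, len(vals), rng)
        streams.append(DeviceStream(model.device, modality, unit,
                                    sample_times + model.clock_offset, vals))

    if model.device is Device.MONITOR:
        for m, unit in ((Modality.MAP, "mmHg"), (Modality.CVP, "mmHg"),
                        (Modality.PAP, "mmHg")):
            if m in truth:
                emit(m, truth[m], model.cadence, 0.0, 0.0, 1.0,
                     model.noise_cv, unit)
    else:
        sv_unit = model.unit
        co_unit = "a.u." if sv_unit == "a.u." else "L/min"
        emit(Modality.SV, truth[Modality.SV], model.cadence, model.delay,
             model.smooth_window, model.scale, model.noise_cv, sv_unit)
        emit(Modality.CO, truth[Modality.CO], model.cadence, model.delay,
             model.smooth_window, model.scale, model.noise_cv, co_unit)
    emit(Modality.HR, truth[Modality.HR], model.hr_cadence, 0.0, 0.0, 1.0,
         model.hr_noise_cv, "bpm")
    return streams


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def _draw_animal_models(cfg: SyntheticConfig, rng: np.random.Generator
                        ) -> dict[Device, DeviceModel]:
    """Fill per-animal free parameters: thermodilution delay and clock
    offsets.  Clock offsets are whole grid steps (device clocks are set by
    hand to the second; the analysis grid cannot resolve finer)."""
    from dataclasses import replace
    out: dict[Device, DeviceModel] = {}
    kmax = int(round(cfg.clock_offset_max / cfg.grid_step))
    for dev, m in cfg.device_models.items():
        delay = m.delay
        if np.isnan(delay):
            delay = float(rng.uniform(*cfg.delay_range))
        off = m.clock_offset
        if np.isnan(off):
            off = cfg.grid_step * float(rng.integers(-kmax, kmax + 1))
        out[dev] = replace(m, delay=delay, clock_offset=off)
    return out


def generate_study(cfg: SyntheticConfig) -> list[StudyRecord]:
    """Generate ``cfg.n_animals`` complete study records, deterministically
    from ``cfg.seed``.  Each record retains its ground truth, the injected
    clock offsets and the injected thermodilution delay for recovery tests."""
    records: list[StudyRecord] = []
    for i in range(cfg.n_animals):
        ss = np.random.SeedSequence([cfg.seed, 1000 + i])
        r_param, r_truth, r_obs = [np.random.default_rng(s) for s in ss.spawn(3)]
        baseline = {
            "SV0": float(r_param.uniform(55.0, 85.0)),
            "HR0": float(r_param.uniform(70.0, 95.0)),
            "MAP0": float(r_param.uniform(70.0, 80.0)),
            "CVP0": float(r_param.uniform(3.0, 8.0)),
            "PAP0": float(r_param.uniform(15.0, 25.0)),
        }
        stressed = float(r_param.uniform(0.0, 1.0))
        mags = {j: float(np.clip(s.magnitude * r_param.uniform(0.7, 1.3), 0.0, 1.0))
                for j, s in enumerate(cfg.segments) if s.kind is not InterventionKind.BASELINE}
        truth = generate_truth(cfg, i, rng=r_truth, baseline=baseline,
                               stressed_volume=stressed, magnitudes=mags)
        models = _draw_animal_models(cfg, r_param)
        streams: list[DeviceStream] = []
        for dev in sorted(models, key=lambda d: d.value):
            streams.extend(observe(truth, models[dev], r_obs))
        injected = {"pac_cco_delay": models[Device.PAC_CCO].delay,
                    "stressed_volume": stressed}
        injected.update({f"SV0": baseline["SV0"], "HR0": baseline["HR0"],
                         "MAP0": baseline["MAP0"]})
        records.append(StudyRecord(
            animal_id=f"pig{i + 1:02d}",
            streams=streams,
            study_arm=cfg.arm,
            ground_truth=truth,
            clock_offsets={d: m.clock_offset for d, m in models.items()},
            injected=injected,
        ))
    return records


def write_study(records: Sequence[StudyRecord], out_dir: str | Path) -> Path:
    """Write per-animal stream CSVs plus a truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for rec in records:
        for s in rec.streams:
            write_stream(s, out / stream_filename(rec.animal_id, s.device, s.modality))
        manifest[rec.animal_id] = {
            "study_arm": rec.study_arm.value,
            "clock_offsets": {d.value: o for d, o in (rec.clock_offsets or {}).items()},
            "injected": rec.injected,
        }
    path = out / "truth_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
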