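"""End-to-end study analysis: synchronize, delay-adjust, calibrate, compare.

The full procedure for one study arm:

1. load (or synthesize) per-animal, per-device streams;
2. align device clocks to the reference recorder via HR cross-correlation;
3. estimate the continuous-thermodilution internal delay per animal
   (against arterial pressure when no flow probe exists, flow-probe CO
   otherwise) and keep both raw and delay-adjusted variants;
4. resample everything onto the common 5-s grid over the shared span;
5. volume-calibrate every device-under-test stroke-volume stream with a
   single scale factor at one shared baseline datum per animal;
6. for every available reference/device pair, compute the weighted
   Bland-Altman report, percentage error, and 1/5/10-min trending
   concordance, pooled across animals;
7. render a summary table (one row per pair, PE and concordance columns)
   plus a manifest of every setting, seed, estimated offset and delay.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import (AgreementReport, PairedSample, Verdict, bland_altman,
                        interchangeability_verdict, pair_series)
from .calibration import (DEFAULT_STABILIZATION_SKIP, compute_scale, apply_scale)
from .concordance import (DEFAULT_BAND, DEFAULT_INTERVALS, ConcordanceReport,
                          concordance_from_pairs, make_delta_pairs)
from .core import (DEFAULT_GRID_STEP, Device, DeviceStream, GridSeries,
                   Modality, StudyArm, StudyRecord, derive_co, logger,
                   read_stream, resample_to_grid, sample_to_grid)
from .delay import (DEFAULT_MAX_DELAY, DelayEstimate, apply_delay,
                    combine_delay_profiles, default_delay_grid, estimate_delay)
from .sync import DEFAULT_MAX_LAG, AlignmentResult, apply_alignment, estimate_offset
from .synthetic import SyntheticConfig, generate_study

#: Stream variants entering the comparison table; the delay-adjusted
#: thermodilution stream is a first-class variant, mirroring the two
#: table rows (with / without time-delay adjustment).
VARIANTS = ("UFS", "EIT", "PAC_CCO", "PAC_CCO_ADJ", "APCO")

#: (reference variant, device-under-test variant) rows, per modality.
PAIR_ROWS: tuple[tuple[str, str], ...] = (
    ("UFS", "EIT"),
    ("UFS", "PAC_CCO"),
    ("UFS", "PAC_CCO_ADJ"),
    ("UFS", "APCO"),
    ("PAC_CCO", "EIT"),
    ("PAC_CCO", "APCO"),
    ("PAC_CCO_ADJ", "EIT"),
    ("PAC_CCO_ADJ", "APCO"),
    ("APCO", "EIT"),
)


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                 # "synthetic" or "files"
    input_dir: str | None = None            # files mode
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    grid_step: float = DEFAULT_GRID_STEP
    band: float = DEFAULT_BAND
    intervals: tuple[float, ...] = DEFAULT_INTERVALS
    stabilization_skip: float = DEFAULT_STABILIZATION_SKIP
    max_clock_lag: float = DEFAULT_MAX_LAG
    max_delay: float = DEFAULT_MAX_DELAY
    delay_reference: str = "auto"           # "auto", "map" or "co_ufs"
    calibrate_mode: str = "sv"              # scale SV and derive CO, or "co"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if abs(iv / self.grid_step - round(iv / self.grid_step)) > 1e-9:
                raise ValueError("intervals must be multiples of the grid step")
        if self.calibrate_mode not in ("sv", "co"):
            raise ValueError("calibrate_mode must be 'sv' or 'co'")


@dataclass
class PairResult:
    modality: Modality
    ref_variant: str
    dut_variant: str
    n_animals: int
    agreement: AgreementReport | None
    verdict: Verdict | None
    concordance: dict[float, ConcordanceReport]
    skipped_reason: str | None = None


@dataclass
class AnimalDiagnostics:
    animal_id: str
    alignment: dict[str, float]           # device -> estimated offset (s)
    delay: DelayEstimate | None
    calibration_t0: float | None
    calibration_scales: dict[str, float]


@dataclass
class PipelineResult:
    pairs: list[PairResult]
    diagnostics: list[AnimalDiagnostics]
    manifest: dict

    @property
    def table(self) -> pd.DataFrame:
        return render_table(self)

    def get_pair(self, modality: Modality, ref: str, dut: str) -> PairResult:
        for p in self.pairs:
            if p.modality is modality and p.ref_variant == ref and p.dut_variant == dut:
                return p
        raise KeyError(f"no pair {modality.value}: {ref} vs {dut}")


# ---------------------------------------------------------------------------
# Per-record processing
# ---------------------------------------------------------------------------

def _snap(t: float, step: float, up: bool) -> float:
    k = t / step
    return step * (np.ceil(k - 1e-9) if up else np.floor(k + 1e-9))


def _resample(stream: DeviceStream, step: float,
              span: tuple[float, float] | None = None) -> GridSeries:
    """Resample with the grid origin snapped to a multiple of the step, so
    every series in a record lands on one commensurate grid."""
    if span is None:
        span = (float(stream.times[0]), float(stream.times[-1]))
    start = _snap(max(span[0], stream.times[0]), step, up=True)
    end = _snap(min(span[1], stream.times[-1]), step, up=False)
    return resample_to_grid(stream, step, (start, end))


def _reference_device(arm: StudyArm) -> Device:
    return Device.UFS if arm is StudyArm.STUDY2 else Device.PAC_CCO


def process_record(rec: StudyRecord, cfg: PipelineConfig
                   ) -> tuple[dict[str, dict[Modality, GridSeries]], AnimalDiagnostics]:
    """Run alignment, delay adjustment, resampling and calibration for one
    animal; returns per-variant SV/CO grid series plus diagnostics."""
    step = cfg.grid_step
    ref_dev = _reference_device(rec.study_arm)

    # --- clock alignment on HR channels -------------------------------------
    hr_ref = _resample(rec.get(ref_dev, Modality.HR), step)
    align_results: list[AlignmentResult] = []
    for dev in rec.devices:
        if dev is ref_dev:
            continue
        hr_dev = _resample(rec.get(dev, Modality.HR), step)
        align_results.append(estimate_offset(hr_ref, hr_dev,
                                             max_lag=cfg.max_clock_lag,
                                             device=dev))
    rec = apply_alignment(rec, align_results, reference=ref_dev)
    offsets = {r.device.value: r.offset for r in align_results}

    # --- thermodilution delay ------------------------------------------------
    delay_est: DelayEstimate | None = None
    if rec.has(Device.PAC_CCO, Modality.CO):
        mode = cfg.delay_reference
        if mode == "auto":
            mode = "co_ufs" if rec.study_arm is StudyArm.STUDY2 else "map"
        if mode == "co_ufs":
            refs = {m: _resample(rec.get(Device.UFS, m), step)
                    for m in (Modality.CO, Modality.SV)}
        else:
            mapg = _resample(rec.get(Device.MONITOR, Modality.MAP), step)
            refs = {Modality.CO: mapg, Modality.SV: mapg}
        grid = default_delay_grid(step, cfg.max_delay)
        # sample-point gridding: holding a 60-s-cadence value forward would
        # masquerade as ~half a cadence of extra delay; CO and SV outputs
        # share the device's one internal delay, so their profiles pool
        ests = [estimate_delay(refs[m],
                               sample_to_grid(rec.get(Device.PAC_CCO, m), step),
                               grid, reference_used=mode.upper())
                for m in (Modality.CO, Modality.SV)]
        delay_est = combine_delay_profiles(ests)

    # --- assemble per-variant raw streams ------------------------------------
    variant_streams: dict[str, dict[Modality, DeviceStream]] = {}
    for variant, dev in (("UFS", Device.UFS), ("EIT", Device.EIT),
                         ("PAC_CCO", Device.PAC_CCO), ("APCO", Device.APCO)):
        if rec.has(dev, Modality.SV):
            variant_streams[variant] = {
                Modality.SV: rec.get(dev, Modality.SV),
                Modality.CO: rec.get(dev, Modality.CO),
                Modality.HR: rec.get(dev, Modality.HR),
            }
    if delay_est is not None and "PAC_CCO" in variant_streams:
        raw = variant_streams["PAC_CCO"]
        variant_streams["PAC_CCO_ADJ"] = {
            Modality.SV: apply_delay(raw[Modality.SV], delay_est.tau),
            Modality.CO: apply_delay(raw[Modality.CO], delay_est.tau),
            Modality.HR: raw[Modality.HR],  # HR is real-time, not delayed
        }

    # --- common span and resampling -----------------------------------------
    lo = max(s[Modality.SV].times[0] for s in variant_streams.values())
    hi = min(s[Modality.SV].times[-1] for s in variant_streams.values())
    if hi - lo < 2 * max(cfg.intervals):
        raise ValueError(f"{rec.animal_id}: common span too short for analysis")
    grids: dict[str, dict[Modality, GridSeries]] = {}
    for variant, streams in variant_streams.items():
        grids[variant] = {m: _resample(streams[m], step, (lo, hi))
                          for m in (Modality.SV, Modality.CO, Modality.HR)}

    # --- single-point volume calibration -------------------------------------
    ref_variant = "PAC_CCO_ADJ" if (ref_dev is Device.PAC_CCO
                                    and "PAC_CCO_ADJ" in grids) else ref_dev.value
    dut_variants = [v for v in grids if v != ref_variant]
    cal_modality = Modality.SV if cfg.calibrate_mode == "sv" else Modality.CO
    ref_cal = grids[ref_variant][cal_modality]
    window = (cfg.stabilization_skip, hi)
    # one shared calibration datum per animal: the first grid time at which
    # the reference and every device-under-test stream are simultaneously
    # present (the same reference datum scales every device)
    present = np.isfinite(ref_cal.values)
    for v in dut_variants:
        present &= np.isfinite(grids[v][cal_modality].values)
    times = ref_cal.times
    eligible = times[present & (times >= cfg.stabilization_skip - 1e-9)]
    if eligible.size == 0:
        raise ValueError(f"{rec.animal_id}: no shared calibration datum")
    t0 = float(eligible[0])
    scales: dict[str, float] = {}
    for v in dut_variants:
        factor = compute_scale(ref_cal, grids[v][cal_modality], window,
                               ref_device=ref_dev,
                               dut_device=Device[v.removesuffix("_ADJ")],
                               t0=t0)
        scales[v] = factor.scale
        grids[v][cal_modality] = apply_scale(grids[v][cal_modality], factor)

    # --- cardiac output ------------------------------------------------------
    if cfg.calibrate_mode == "sv":
        for v in grids:
            grids[v][Modality.CO] = derive_co(grids[v][Modality.SV],
                                              grids[v][Modality.HR])
    else:  # CO scaled directly; SV left as derived CO/HR for completeness
        for v in grids:
            co, hr = grids[v][Modality.CO], grids[v][Modality.HR]
            grids[v][Modality.SV] = co.with_values(
                1000.0 * co.values / hr.values, "mL")

    diag = AnimalDiagnostics(animal_id=rec.animal_id, alignment=offsets,
                             delay=delay_est, calibration_t0=t0,
                             calibration_scales=scales)
    return grids, diag


# ---------------------------------------------------------------------------
# Whole-study pipeline
# ---------------------------------------------------------------------------

def load_study(input_dir: str | Path) -> list[StudyRecord]:
    """Load a study from per-animal stream CSVs named
    {animal}_{device}_{modality}.csv; the arm is inferred from the presence
    of flow-probe streams."""
    files = sorted(Path(input_dir).glob("*_*_*.csv"))
    by_animal: dict[str, list[DeviceStream]] = {}
    for f in files:
        parts = f.stem.split("_")
        modality = Modality(parts[-1])
        device = Device("_".join(parts[1:-1]))
        animal = parts[0]
        unit = None
        if device is Device.EIT and modality in (Modality.SV, Modality.CO):
            unit = "a.u."
        by_animal.setdefault(animal, []).append(
            read_stream(f, device, modality, unit=unit))
    records = []
    for animal, streams in sorted(by_animal.items()):
        arm = (StudyArm.STUDY2 if any(s.device is Device.UFS for s in streams)
               else StudyArm.STUDY1)
        records.append(StudyRecord(animal, streams, arm))
    return records


def run_pipeline(cfg: PipelineConfig,
                 records: Sequence[StudyRecord] | None = None) -> PipelineResult:
    """Analyze a whole study; see the module docstring for the stages."""
    if records is None:
        if cfg.mode == "synthetic":
            records = generate_study(cfg.synthetic)
        elif cfg.mode == "files":
            if cfg.input_dir is None:
                raise ValueError("files mode requires input_dir")
            records = load_study(cfg.input_dir)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")

    per_animal: dict[str, dict[str, dict[Modality, GridSeries]]] = {}
    diagnostics: list[AnimalDiagnostics] = []
    for rec in records:
        grids, diag = process_record(rec, cfg)
        per_animal[rec.animal_id] = grids
        diagnostics.append(diag)

    pairs: list[PairResult] = []
    for modality in (Modality.CO, Modality.SV):
        for ref_v, dut_v in PAIR_ROWS:
            samples: list[PairedSample] = []
            conc_pairs: dict[float, list] = {iv: [] for iv in cfg.intervals}
            animals = 0
            for animal, grids in per_animal.items():
                if ref_v not in grids or dut_v not in grids:
                    continue
                ref_g, dut_g = grids[ref_v][modality], grids[dut_v][modality]
                ps = pair_series(animal, ref_g, dut_g)
                if len(ps) < 2:
                    continue
                animals += 1
                samples.extend(ps)
                for iv in cfg.intervals:
                    conc_pairs[iv].extend(make_delta_pairs(animal, ref_g, dut_g, iv))
            if animals < 2:
                reason = ("pair unavailable" if animals == 0
                          else "only one animal with data")
                logger.info("skipping %s: %s vs %s (%s)", modality.value,
                            ref_v, dut_v, reason)
                pairs.append(PairResult(modality, ref_v, dut_v, animals,
                                        None, None, {}, skipped_reason=reason))
                continue
            agreement = bland_altman(samples)
            conc = {iv: concordance_from_pairs(conc_pairs[iv], band=cfg.band,
                                               interval=iv)
                    for iv in cfg.intervals}
            pairs.append(PairResult(modality, ref_v, dut_v, animals, agreement,
                                    interchangeability_verdict(agreement.pe_overall),
                                    conc))

    manifest = {
        "config": _config_dict(cfg),
        "n_records": len(records),
        "study_arms": sorted({r.study_arm.value for r in records}),
        "animals": [d.animal_id for d in diagnostics],
        "estimated_offsets_s": {d.animal_id: d.alignment for d in diagnostics},
        "estimated_delays_s": {d.animal_id: (d.delay.tau if d.delay else None)
                               for d in diagnostics},
        "calibration_scales": {d.animal_id: d.calibration_scales
                               for d in diagnostics},
        "settings": {
            "pe_denominator": "equal-animal-weight mean of reference values",
            "variance_model": "one-way random effects over animals",
            "exclusion_rule": "both axes inside the band",
            "windows": "non-overlapping consecutive intervals",
        },
    }
    result = PipelineResult(pairs=pairs, diagnostics=diagnostics, manifest=manifest)
    if cfg.output_dir:
        write_outputs(result, cfg.output_dir)
    return result


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {(k.value if hasattr(k, "value") else k): clean(v)
                    for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if hasattr(x, "value"):
            return x.value
        if isinstance(x, float) and np.isnan(x):
            return None
        return x

    return clean(d)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _variant_label(variant: str, modality: Modality) -> str:
    base = variant.removesuffix("_ADJ").replace("_", "-")
    label = f"{modality.value}_{base}"
    if variant.endswith("_ADJ"):
        label += " (delay adjusted)"
    return label


def render_table(result: PipelineResult,
                 intervals: Sequence[float] = DEFAULT_INTERVALS) -> pd.DataFrame:
    """Summary table: one row per analyzed pair with PE and concordance
    columns at each interval, plus the number of source animals."""
    rows = []
    for p in result.pairs:
        if p.agreement is None:
            continue
        row = {
            "x_ref": _variant_label(p.ref_variant, p.modality),
            "x_dut": _variant_label(p.dut_variant, p.modality),
            "pe_pct": round(p.agreement.pe_overall, 1),
        }
        for iv in intervals:
            rep = p.concordance.get(iv)
            key = f"conc_{int(iv) // 60}min_pct"
            row[key] = (round(rep.concordance, 1)
                        if rep is not None and not rep.undefined else float("nan"))
        row["n_animals"] = p.n_animals
        rows.append(row)
    cols = (["x_ref", "x_dut", "pe_pct"]
            + [f"conc_{int(iv) // 60}min_pct" for iv in intervals]
            + ["n_animals"])
    return pd.DataFrame(rows, columns=cols)


def _report_dict(p: PairResult) -> dict:
    out = {"modality": p.modality.value, "ref": p.ref_variant,
           "dut": p.dut_variant, "n_animals": p.n_animals}
    if p.skipped_reason:
        out["skipped"] = p.skipped_reason
        return out
    a = p.agreement
    out["agreement"] = {
        "n_pairs": a.n_pairs, "bias": a.bias,
        "loa": [a.loa_low, a.loa_high],
        "ci_bias": list(a.ci_bias),
        "ci_loa_low": list(a.ci_loa_low), "ci_loa_high": list(a.ci_loa_high),
        "pe_overall_pct": a.pe_overall, "pe_per_animal_pct": a.pe_per_animal,
        "mean_ref": a.mean_ref, "sd_total": a.sd_total,
        "variance_model": a.variance_model,
    }
    out["verdict"] = p.verdict.value
    out["concordance"] = {
        str(int(iv)): {"n_total": c.n_total, "n_excluded": c.n_excluded,
                       "n_concordant": c.n_concordant,
                       "concordance_pct": (None if c.undefined else c.concordance),
                       "band_pct": c.band, "exclusion_rule": c.exclusion_rule}
        for iv, c in p.concordance.items()}
    return out


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_table(result).to_csv(out / "summary_table.csv", index=False)
    with open(out / "reports.json", "w") as fh:
        json.dump([_report_dict(p) for p in result.pairs], fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
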