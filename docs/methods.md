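# Methods

This note documents the statistical procedures, the synthetic study
generator, and the numerical choices behind `hemoconcord`, in the order the
pipeline runs.

## Data model and grid conventions

All analysis happens on a fixed-step time grid (default 5 s, the fastest
native cadence among the devices considered). Time is seconds from study
start; a sample's timestamp is the end of the device's internal averaging
interval. Slower streams (20-s pulse-contour, 60-s thermodilution) are
placed on the grid by last-observation-carried-forward, never
interpolation, so no dynamics are invented between samples; an observation
is held for at most three native cadences, after which grid points are
missing. Every pairwise statistic uses complete pairs only and reports the
N used.

One exception is deliberate: the delay estimator reads the slow device
through *sample-point* gridding (each observation only at its own grid
point). A value held forward for a 60-s cadence looks, to a lag estimator,
like ~30 s of extra delay; sample-point pairing removes that bias at the
cost of fewer pairs.

## Synthetic study generator

The generator emulates an anesthetized-pig monitor-validation experiment.
It exists so that every estimator in the pipeline can be validated by
parameter recovery; its defaults are the package's standard study
conditions and are not tuned per analysis.

**Ground truth.** Stroke volume, heart rate, systemic vascular resistance
(SVR), central venous and pulmonary pressures each follow a multiplicative
first-order lag (time constant 60 s — the simplest monotone response; the
drugs' onset kinetics are not otherwise modelled) toward per-segment
targets, times a slow stationary log-Ornstein–Uhlenbeck wander (default CV
3%, correlation time 120 s) representing drift in anesthetic depth and
volume status. Cardiac output is SV·HR/1000 exactly; mean arterial
pressure is CO·SVR, so pressure and flow co-move the way the drug
responses demand (baseline MAP is held in the 70–80 mmHg band).

**Interventions.** The default 2.5-h sequence is baseline (20 min), then
vasodilator, vasopressor, positive and negative inotrope, a pulmonary
vasopressor (second study arm only), hemorrhage, and resuscitation, with
recovery gaps. Effect magnitudes are sized to clinically typical responses
at study doses — dobutamine CO +30–40%, esmolol CO −20%, controlled
hemorrhage SV −25%, nitroprusside/phenylephrine MAP ∓20% — and are jittered
±30% per animal. The vasodilator's SV response is preload-dependent: a
per-animal "stressed volume" latent in [0,1] sets its sign (venodilation
reduces SV in volume-depleted animals, afterload reduction raises it in
replete ones).

**Device observation.** Each device sees the truth through
`scale · movingaverage(truth, window)(t − delay)`, sampled at its cadence,
with multiplicative lognormal noise of the stated CV and timestamps offset
by its clock error. The moving average is *centered*: smoothing then adds
no phase shift, so the `delay` field is the device's total effective
latency and smoothing is pure dispersion — this keeps the injected delay
well-defined for recovery tests. Defaults, chosen so the device ranking is
qualitatively realistic (reference flow probe best, pulse contour worst):

| device   | cadence | smoothing | delay        | scale      | noise CV | clock offset |
|----------|---------|-----------|--------------|------------|----------|--------------|
| UFS      | 5 s     | —         | —            | 1          | 3%       | — (reference)|
| EIT      | 5 s     | —         | —            | 0.025 a.u. | 8%       | 0            |
| PAC-CCO  | 60 s    | 300 s     | U(282,666) s | 1          | 5%       | ±120 s       |
| APCO     | 20 s    | 20 s      | —            | 1          | 15%      | ±120 s       |
| monitor  | 5 s     | —         | —            | 1          | 2%       | ±120 s       |

Clock offsets are drawn as whole grid steps (device clocks are set by hand
to the second; the grid-resolution aligner cannot resolve finer). Every
device also emits a heart-rate channel at 5-s cadence with 1% jitter —
bedside monitors update HR near-continuously regardless of their flow
cadence — which is what makes clock alignment possible.

**What the generator does not emulate.** No beat-to-beat or respiratory
variation (the pipeline starts at 5-s averages), no time-varying
thermodilution delay, no clock drift (one constant offset per device), no
sensor dropout, and noise is purely multiplicative lognormal. Passing
recovery tests therefore demonstrate correctness of the estimators under
these idealizations, not robustness to artifacts real recordings may
contain.

## Clock alignment

For each non-reference device, the offset is the lag L ∈ [−600, +600] s
(grid resolution) maximizing the Pearson correlation between the reference
and device HR channels over their overlap; the device's timestamps are
then shifted by −L. Both channels are first averaged over a symmetric 30-s
window: this shifts no timing but averages monitor jitter down, keeping
the correlation peak from wandering a grid step under noise. Ties break
toward the smallest |L|, then negative L; lags with under 10 min of
overlap are skipped; a constant HR channel is an error (alignment would be
meaningless). One constant offset per device — no drift correction.

## Thermodilution delay estimation

For each candidate delay τ on a 0–900-s grid (5-s steps, covering the
device's documented 5–12-min latency), the device series advanced by τ is
least-squares-scaled to the reference over their overlap and the objective
SD(ref − a·dut)/mean(ref) is evaluated; τ̂ minimizes the objective, ties
toward smaller τ. The reference is flow-probe CO when a probe is present,
mean arterial pressure otherwise. Three implementation details matter:

* **Unit reconciliation.** Pressure (mmHg) and flow (L/min) cannot be
  differenced directly; the per-candidate least-squares scaling makes the
  relative-SD objective unit-free. This is one reading of an
  underdetermined convention; the full objective profile is retained in
  every `DelayEstimate` so alternatives can be compared.
* **Bandwidth matching.** The device output is a several-minute average;
  comparing it against an unaveraged reference leaves a shape mismatch at
  every transition that a pure-shift fit misreads as ~10–15 s of extra
  delay even without noise. The reference is therefore pre-averaged over
  the device's nominal 300-s output window before differencing.
* **Fixed support.** Only device samples whose reference partner exists at
  *every* candidate delay enter the objective. A support that changed with
  the candidate would drop early-record (quiet baseline) pairs as the
  candidate grows and tilt the profile.

The device derives its CO and SV outputs from the same delayed internal
processing, so their two objective profiles are pooled (averaged) before
minimizing. Pressure-referenced profiles are *not* pooled with
flow-referenced ones when both exist: MAP = CO·SVR, so pressure transitions
have systematically different shapes and bias the pure-shift fit.

The estimator is nonlinear least squares for the shift-plus-scale model
and so operates near the information bound set by the device noise (5% CV
per 60-s sample against ~14 intervention transitions in 2.5 h). The
recovery tests measure the resulting accuracy directly: median error at
grid resolution, with a tail of a few grid steps that no estimator of this
objective can remove under these conditions.

Delay adjustment shifts the device's timestamps back by τ̂ (attributing
output to when the physiology occurred) and drops samples that would
precede the study start. The raw and delay-adjusted streams are carried
through the rest of the pipeline as separate variants, so every comparison
is reported both ways.

## Volume calibration

Single-point, multiplicative, per animal:
ScaleFactor = SV_REF(t0)/SV_DUT(t0), no offset. t0 is the first grid time
after a 10-min stabilization skip (pressures are held in the target band
for at least that long at the start of an experiment) at which the
reference and *all* device-under-test streams are simultaneously present —
one shared reference datum scales every device, so cross-device
comparisons rest on the same anchor. An optional window-mean mode
(averaging all complete pairs in the window) exists but is off by default:
the single-point rule is the defined procedure, robustness notwithstanding.

By default SV is the calibrated quantity and CO is derived as
scaled SV × device HR / 1000; a config switch (`calibrate_mode="co"`)
scales the native CO streams directly instead, since which quantity was
anchored is itself a convention.

## Agreement statistics

With differences d = X_DUT − X_REF pooled over A animals (n_a pairs each):

* **Bias** = (1/A) Σ_a mean_a(d) — each observation effectively weighted
  1/n_a, so animals contribute equally regardless of recording length.
* **Variance** — one-way random-effects decomposition over animals (the
  repeated-measures Bland–Altman for the case where the true value varies
  within subject, which interventions guarantee):
  s²_w = Σ_a Σ_i (d_ai − d̄_a)²/(N−A);
  MSB = Σ_a n_a (d̄_a − d̄)²/(A−1) with d̄ the observation grand mean;
  n₀ = (N − Σ n_a²/N)/(A−1); s²_b = max(0, (MSB − s²_w)/n₀);
  SD_total = √(s²_b + s²_w).
* **95% LoA** = bias ± 1.96·SD_total. CIs use normal quantiles (per-animal
  n is large in this design, so t-corrections are immaterial):
  Var(bias) = Σ_a (s²_b + s²_w/n_a)/A²; Var(SD_total) by the delta method
  from Var(MSW) = 2·MSW²/df_w and Var(MSB) = 2·MSB²/df_b;
  Var(LoA) = Var(bias) + 1.96²·Var(SD_total).
* **Percentage error** = 100·1.96·SD_total / mean_ref, with mean_ref the
  equal-animal-weight mean of the reference values. The denominator is a
  convention; the reference mean is the reproducible choice and is
  recorded in the run manifest. Per-animal PE uses that animal's pairs
  alone (plain SD). Verdicts: PE ≤ 30% interchangeable with bolus
  thermodilution, 30–42% practically equivalent to continuous
  thermodilution, else not met; both boundaries inclusive.

Degenerate inputs are handled explicitly: identical streams give bias 0,
LoA (0, 0) and PE 0 with a degenerate-variance flag; a single animal is an
error directing to the single-subject variant (the two-level decomposition
is undefined).

## Trending concordance

Percent changes Δ% = 100·(x(t_k) − x(t_{k−1}))/x(t_{k−1}) over
*non-overlapping* consecutive windows (sliding windows would inflate and
correlate the pair count) at 1-, 5- and 10-min intervals, paired by
endpoint time within animal and pooled. A pair is excluded when it lies
inside the central square — |Δ%_ref| ≤ 15 *and* |Δ%_dut| ≤ 15 (the
both-axes reading of a centered exclusion square; an either-axis variant
is available and every report records which rule was used). Among retained
pairs, concordant means equal signs, with an exact zero concordant with
either direction; the rate is 100·n_concordant/(n_total − n_excluded).
When every pair is excluded the rate is undefined and flagged rather than
raised. Percent (not absolute) changes are used because the band is stated
in percent. Missing endpoints skip the pair; a non-positive previous value
skips it with a warning.

## Pipeline and reporting

Per record: align clocks to the arm's reference device (flow probe when
present, thermodilution otherwise) → estimate and apply the thermodilution
delay (keeping raw and adjusted variants) → resample all variants to the
common grid over the shared span → calibrate SV at the shared baseline
datum → derive CO. Pairs are then pooled across animals for each
reference/device row of the standard comparison table (both thermodilution
variants appear as separate rows), and each row gets the weighted
Bland–Altman report, PE with verdict, and concordance at each interval. A
pair with under two contributing animals is skipped with a logged reason;
the run manifest records every setting, estimated offset, delay and scale,
so exclusions and adjustments are auditable.

## Numerical choices

* Grid arithmetic uses absolute tolerances of 1e-9 s; series must be
  commensurate (origins differing by whole steps).
* Calibration recovers a noiseless device gain s as 1/s to better than
  1e-12 relative error; the scaled value at t0 equals the reference to
  within two ULPs (one rounding each in the divide and the multiply).
* Tie-breaks are deterministic everywhere: smallest |lag| then negative
  lag for alignment; smallest τ for delay; first grid time for t0.
* All randomness descends from one integer seed via `SeedSequence`
  spawning; equal seeds give byte-identical studies.

## Problem sizes

The test suite and acceptance script run the default scenario at 7 animals
× 2.5 h × 5-s grid (≈1,800 grid points per stream, ≈11,000 pooled pairs
per device comparison), 50-seed recovery simulations for delays and clock
offsets, 10⁵-sample Monte-Carlo checks of LoA coverage, and 10⁴-pair
concordance calibrations — sizes at which the Monte-Carlo error of each
check is well below its assertion tolerance.

## Known limitations

* A single constant delay and a single constant clock offset per device;
  real thermodilution delay varies with flow and temperature.
* The least-squares-scaling reading of the delay objective is one of
  several defensible normalizations (profiles are exposed for comparison).
* Single-point calibration propagates the noise of one datum into a
  persistent per-animal scale error; this is faithful to the procedure,
  and is the dominant contributor to the impedance monitor's percentage
  error under the default noise model.
* The generator's idealizations (above) mean pipeline validation does not
  certify behavior on artifact-laden clinical recordings.
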