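"""Weighted Bland-Altman agreement and percentage error.

Method-comparison studies pool thousands of paired readings from a handful
of animals, with wildly different pair counts per animal.  Treating every
pair as independent would let one long recording dominate and understate
the uncertainty, so:

* the bias is the equal-animal-weight mean of the differences (each
  observation carries weight 1/n_a, animal a's pair count);
* the SD behind the 95% limits of agreement combines within-animal and
  between-animal variance by a one-way random-effects decomposition over
  animals — the Bland-Altman procedure for multiple observations per
  subject when the true value varies (interventions change cardiac output
  within each animal);
* confidence intervals use normal quantiles (per-animal n is large in this
  design) with standard errors from the same decomposition.

The percentage error follows the Critchley convention,
PE = 100 * 1.96 * SD(differences) / mean(reference), with the reference
mean computed with the same equal-animal weights.  PE <= 30% indicates
interchangeability with bolus thermodilution; PE <= 42% practical clinical
equivalence with continuous thermodilution.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import GridSeries, logger

Z95 = 1.96  # normal 97.5% quantile, used for LoA and CIs throughout

#: Percentage-error acceptance thresholds (percent).
PE_INTERCHANGEABLE = 30.0  # ~ sqrt(2) x 20% bolus-thermodilution error
PE_PRACTICAL = 42.0        # ~ sqrt(2) x 30% continuous-thermodilution error


class Verdict(str, enum.Enum):
    ICO_INTERCHANGEABLE = "ICO_INTERCHANGEABLE"
    CCO_PRACTICAL = "CCO_PRACTICAL"
    NOT_MET = "NOT_MET"


@dataclass(frozen=True)
class PairedSample:
    """One complete (reference, device-under-test) pair."""

    animal_id: str
    time: float
    x_ref: float
    x_dut: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_ref) and np.isfinite(self.x_dut)):
            raise ValueError("paired sample values must be finite")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class AgreementReport:
    n_pairs: int
    n_animals: int
    bias: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    pe_overall: float                   # percent
    pe_per_animal: dict[str, float]
    mean_ref: float
    sd_total: float = 0.0
    sd_within: float = 0.0
    sd_between: float = 0.0
    variance_model: str = ("one-way random effects over animals; "
                           "true value varies within animal")
    degenerate_variance: bool = False


def pair_series(animal_id: str, ref: GridSeries, dut: GridSeries
                ) -> list[PairedSample]:
    """Complete pairs from two same-grid series."""
    from .core import same_grid
    if not same_grid(ref, dut):
        raise ValueError("series must share the grid")
    ok = np.isfinite(ref.values) & np.isfinite(dut.values)
    t = ref.times[ok]
    return [PairedSample(animal_id, float(tt), float(r), float(d))
            for tt, r, d in zip(t, ref.values[ok], dut.values[ok])]


def _group(samples: Sequence[PairedSample]):
    groups: dict[str, list[PairedSample]] = {}
    for s in samples:
        groups.setdefault(s.animal_id, []).append(s)
    return groups


def _variance_components(groups: dict[str, list[PairedSample]]):
    """One-way random-effects decomposition of the differences over animals.

    Returns (s2_within, s2_between, sd_total, msb, n0, df_within, df_between)
    with the between component clamped at zero when the between-animal mean
    square falls below the within mean square.
    """
    d_by = {a: np.array([s.x_dut - s.x_ref for s in g]) for a, g in groups.items()}
    n_a = {a: len(d) for a, d in d_by.items()}
    A = len(d_by)
    N = sum(n_a.values())
    means = {a: d.mean() for a, d in d_by.items()}
    df_w = N - A
    ssw = sum(float(((d - means[a]) ** 2).sum()) for a, d in d_by.items())
    s2_w = ssw / df_w if df_w > 0 else 0.0
    grand = sum(n_a[a] * means[a] for a in d_by) / N
    df_b = A - 1
    msb = sum(n_a[a] * (means[a] - grand) ** 2 for a in d_by) / df_b
    n0 = (N - sum(n * n for n in n_a.values()) / N) / df_b
    s2_b = max(0.0, (msb - s2_w) / n0)
    sd_total = float(np.sqrt(s2_b + s2_w))
    return s2_w, s2_b, sd_total, msb, n0, df_w, df_b


def bland_altman(samples: Sequence[PairedSample]) -> AgreementReport:
    """Weighted Bland-Altman report for repeated measures over animals.

    Differences are device-under-test minus reference.  Requires at least
    two animals with at least two pairs each; with a single animal the
    two-level decomposition is undefined — use the per-animal statistics
    (``percentage_error_single``) instead.
    """
    groups = _group(samples)
    A = len(groups)
    if A < 2:
        raise ValueError(
            "weighted Bland-Altman needs >= 2 animals; for a single animal "
            "use the unweighted single-subject variant")
    small = [a for a, g in groups.items() if len(g) < 2]
    if small:
        raise ValueError(f"animals with fewer than 2 pairs: {small}")

    means = {a: float(np.mean([s.x_dut - s.x_ref for s in g]))
             for a, g in groups.items()}
    n_a = {a: len(g) for a, g in groups.items()}
    bias = float(np.mean(list(means.values())))  # each observation weighted 1/n_a

    s2_w, s2_b, sd_total, msb, n0, df_w, df_b = _variance_components(groups)
    degenerate = s2_w == 0.0 and s2_b == 0.0
    if s2_w == 0.0:
        logger.warning("bland_altman: zero within-animal variance everywhere")

    loa_low = bias - Z95 * sd_total
    loa_high = bias + Z95 * sd_total

    # SE of the equal-animal-weight bias: per-animal means are independent
    # with variance s2_b + s2_w / n_a.
    var_bias = sum(s2_b + s2_w / n_a[a] for a in groups) / (A * A)
    se_bias = float(np.sqrt(var_bias))

    # SE of the LoA: delta method on sd_total^2 expressed in mean squares.
    var_msw = 2.0 * s2_w ** 2 / df_w if df_w > 0 else 0.0
    var_msb = 2.0 * msb ** 2 / df_b
    if s2_b > 0.0:
        var_sd2 = var_msb / n0 ** 2 + (1.0 - 1.0 / n0) ** 2 * var_msw
    else:
        var_sd2 = var_msw
    var_sd = var_sd2 / (4.0 * sd_total ** 2) if sd_total > 0 else 0.0
    se_loa = float(np.sqrt(var_bias + Z95 ** 2 * var_sd))

    mean_ref = float(np.mean([np.mean([s.x_ref for s in g])
                              for g in groups.values()]))
    pe_overall = percentage_error(samples)
    pe_per_animal = {a: percentage_error_single(g) for a, g in groups.items()}

    return AgreementReport(
        n_pairs=sum(n_a.values()), n_animals=A, bias=bias,
        loa_low=loa_low, loa_high=loa_high,
        ci_bias=(bias - Z95 * se_bias, bias + Z95 * se_bias),
        ci_loa_low=(loa_low - Z95 * se_loa, loa_low + Z95 * se_loa),
        ci_loa_high=(loa_high - Z95 * se_loa, loa_high + Z95 * se_loa),
        pe_overall=pe_overall, pe_per_animal=pe_per_animal,
        mean_ref=mean_ref, sd_total=sd_total,
        sd_within=float(np.sqrt(s2_w)), sd_between=float(np.sqrt(s2_b)),
        degenerate_variance=degenerate,
    )


def percentage_error(samples: Sequence[PairedSample]) -> float:
    """PE = 100 * 1.96 * SD_total(differences) / weighted mean reference.

    SD_total comes from the same two-level decomposition as the limits of
    agreement; the denominator is the equal-animal-weight reference mean.
    """
    groups = _group(samples)
    if len(groups) < 2:
        return percentage_error_single(list(samples))
    _, _, sd_total, *_ = _variance_components(groups)
    mean_ref = float(np.mean([np.mean([s.x_ref for s in g])
                              for g in groups.values()]))
    if mean_ref <= 0:
        raise ValueError("mean reference value must be positive")
    return 100.0 * Z95 * sd_total / mean_ref


def percentage_error_single(samples: Sequence[PairedSample]) -> float:
    """Single-animal PE: plain SD of that animal's differences."""
    d = np.array([s.x_dut - s.x_ref for s in samples])
    ref = np.array([s.x_ref for s in samples])
    mean_ref = float(ref.mean())
    if mean_ref <= 0:
        raise ValueError("mean reference value must be positive")
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return 100.0 * Z95 * sd / mean_ref


def interchangeability_verdict(pe: float) -> Verdict:
    """Classify a percentage error against the 30% / 42% thresholds
    (both boundaries inclusive)."""
    if pe < 0:
        raise ValueError("percentage error must be non-negative")
    if pe <= PE_INTERCHANGEABLE:
        return Verdict.ICO_INTERCHANGEABLE
    if pe <= PE_PRACTICAL:
        return Verdict.CCO_PRACTICAL
    return Verdict.NOT_MET
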