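"""Four-quadrant trending concordance with a central exclusion band.

Whether a monitor tracks *changes* in cardiac output is a different
question from whether its level agrees.  Concordance takes the percent
change of each device over consecutive non-overlapping intervals, drops
change pairs too small to call a direction (inside a centered 15% exclusion
square), and reports the fraction of the remainder in which both devices
moved the same way.  Intervals of 1, 5 and 10 minutes probe trending at
different time scales; longer intervals average out monitor noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridSeries, logger

DEFAULT_BAND = 15.0  # percent; half-width of the central exclusion square
DEFAULT_INTERVALS = (60.0, 300.0, 600.0)


@dataclass(frozen=True)
class DeltaPair:
    animal_id: str
    t: float
    delta_ref: float   # percent change over the interval
    delta_dut: float
    excluded: bool = False


@dataclass
class ConcordanceReport:
    interval: float
    n_total: int
    n_excluded: int
    n_concordant: int
    concordance: float        # percent; NaN when every pair is excluded
    band: float = DEFAULT_BAND
    exclusion_rule: str = "both"  # "both": excluded iff |ref|<=band AND |dut|<=band
    undefined: bool = False


def compute_deltas(x: GridSeries, interval: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Percent changes over consecutive non-overlapping windows.

    Window endpoints are t_k = x.t0 + k*interval; the change at t_k is
    100*(x(t_k) - x(t_{k-1}))/x(t_{k-1}).  Pairs with a missing endpoint
    are skipped; a non-positive previous value is skipped with a warning
    (a percent change from it is meaningless).
    """
    m = interval / x.step
    if abs(m - round(m)) > 1e-9:
        raise ValueError("interval must be a multiple of the grid step")
    m = int(round(m))
    if m < 1 or len(x) <= m:
        raise ValueError("record shorter than one interval")
    idx = np.arange(0, len(x), m)
    times, deltas = [], []
    skipped_nonpos = 0
    for prev, cur in zip(idx[:-1], idx[1:]):
        a, b = x.values[prev], x.values[cur]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a <= 0:
            skipped_nonpos += 1
            continue
        times.append(x.t0 + cur * x.step)
        deltas.append(100.0 * (b - a) / a)
    if skipped_nonpos:
        logger.warning("compute_deltas: skipped %d pairs with non-positive "
                       "previous value", skipped_nonpos)
    return np.asarray(times), np.asarray(deltas)


def make_delta_pairs(animal_id: str, ref: GridSeries, dut: GridSeries,
                     interval: float) -> list[DeltaPair]:
    """Interval changes of two same-grid series, paired by endpoint time."""
    t_r, d_r = compute_deltas(ref, interval)
    t_d, d_d = compute_deltas(dut, interval)
    by_t = {round(t, 6): d for t, d in zip(t_d, d_d)}
    out = []
    for t, dr in zip(t_r, d_r):
        dd = by_t.get(round(t, 6))
        if dd is not None:
            out.append(DeltaPair(animal_id, float(t), float(dr), float(dd)))
    return out


def concordance_rate(delta_ref: np.ndarray | list, delta_dut: np.ndarray | list,
                     band: float = DEFAULT_BAND, exclusion: str = "both",
                     interval: float = float("nan")) -> ConcordanceReport:
    """Four-quadrant concordance of paired percent changes.

    A pair is excluded when it falls inside the central square: with the
    default rule, both |delta_ref| <= band and |delta_dut| <= band (the
    "either" rule excludes when either axis is small).  Among retained
    pairs, a pair is concordant when the changes share a sign; an exact
    zero is concordant with either direction.  When every pair is excluded
    the rate is undefined (flagged), not an error.
    """
    r = np.asarray(delta_ref, dtype=float)
    d = np.asarray(delta_dut, dtype=float)
    if r.shape != d.shape:
        raise ValueError("delta arrays must be paired")
    if exclusion == "both":
        excluded = (np.abs(r) <= band) & (np.abs(d) <= band)
    elif exclusion == "either":
        excluded = (np.abs(r) <= band) | (np.abs(d) <= band)
    else:
        raise ValueError("exclusion must be 'both' or 'either'")
    kept_r, kept_d = r[~excluded], d[~excluded]
    concordant = (np.sign(kept_r) == np.sign(kept_d)) | (kept_r == 0) | (kept_d == 0)
    n_total = int(r.size)
    n_excluded = int(excluded.sum())
    n_conc = int(concordant.sum())
    n_kept = n_total - n_excluded
    if n_kept == 0:
        return ConcordanceReport(interval, n_total, n_excluded, 0, float("nan"),
                                 band, exclusion, undefined=True)
    return ConcordanceReport(interval, n_total, n_excluded, n_conc,
                             100.0 * n_conc / n_kept, band, exclusion)


def concordance_from_pairs(pairs: list[DeltaPair], band: float = DEFAULT_BAND,
                           exclusion: str = "both",
                           interval: float = float("nan")) -> ConcordanceReport:
    return concordance_rate([p.delta_ref for p in pairs],
                            [p.delta_dut for p in pairs],
                            band=band, exclusion=exclusion, interval=interval)
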