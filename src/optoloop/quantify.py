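"""Quantification and quality control for mother-machine detection regions.

Implements the measurement-side bookkeeping of the platform: segmentation-
free fluorescence extraction (nearest-rank 97th percentile of a fixed
detection box), robust growth-rate estimation from log2 cell length, the
absorbing cell-invalidation state machine, and the runaway-cell blocking
rule used to protect population-level closed loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PERCENTILE = 0.97


# ---------------------------------------------------------------------------
# fluorescence extraction
# ---------------------------------------------------------------------------

def extract_fluorescence(region: np.ndarray) -> float:
    """Nearest-rank 97th-percentile pixel intensity of a detection region.

    The value at ascending rank ``ceil(0.97 n)``; for the default 40 x 80
    box (n = 3200) that is rank 3104, leaving exactly 96 distinct-valued
    pixels strictly above the readout. Chosen over interpolated percentiles
    to reproduce that pixel bookkeeping exactly.
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty detection region")
    if not np.all(np.isfinite(region)):
        raise ValueError("detection region contains non-finite intensities")
    flat = np.sort(region, axis=None)
    rank = math.ceil(PERCENTILE * flat.size)          # 1-based
    return float(flat[rank - 1])


# ---------------------------------------------------------------------------
# growth-rate estimation
# ---------------------------------------------------------------------------

def estimate_growth_rate(lengths: np.ndarray, dt_min: float = 6.0,
                         window: int = 5, k_mad: float = 5.0,
                         div_jump: float = -0.5,
                         abs_floor: float = 0.5) -> np.ndarray:
    """Moving-average growth rate from log2 cell length, in doublings/h.

    Per-step rates ``diff(log2 length) / dt`` are computed; steps that are
    division events (log2 drop <= ``div_jump`` doublings) or local outliers
    (|rate - local median| > max(k_mad * local MAD, abs_floor)) are
    excluded, and the remainder smoothed with a centred moving average of
    ``window`` steps. Windows with every step excluded yield a missing
    value, carried forward from the last estimate. Output has one entry per
    length sample; the first repeats the second (no rate before the first
    interval).
    """
    lengths = np.asarray(lengths, float)
    if lengths.size < window + 1:
        raise ValueError("need at least window+1 length samples")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    dlog2 = np.diff(np.log2(lengths))
    rate = dlog2 / (dt_min / 60.0)                    # doublings per hour
    keep = dlog2 > div_jump
    s = pd.Series(np.where(keep, rate, np.nan))
    med = s.rolling(window, center=True, min_periods=1).median()
    mad = (s - med).abs().rolling(window, center=True, min_periods=1).median()
    dev = (s - med).abs()
    keep &= ~(dev > np.maximum(k_mad * mad.to_numpy(), abs_floor)).to_numpy()
    kept = pd.Series(np.where(keep, rate, np.nan))
    smooth = kept.rolling(window, center=True, min_periods=1).mean()
    smooth = smooth.ffill().bfill()
    out = np.empty(lengths.size)
    out[1:] = smooth.to_numpy()
    out[0] = out[1]
    return out


# ---------------------------------------------------------------------------
# validity classification
# ---------------------------------------------------------------------------

@dataclass
class ValidityThresholds:
    """Rule thresholds; values unstated in the platform description are
    configurable defaults."""

    min_growth: float = 0.3           # doublings/h
    min_reporter: float = 2.0         # constitutive-reporter a.u.
    min_responsiveness: float = 0.1   # controller-estimated E (a.u.)
    reporter_window: int = 5          # local time-average width (intervals)
    persistence: int = 3              # consecutive failing intervals
    truncate_min: float = 150.0       # post-hoc truncation (min)


@dataclass
class ValidityRecord:
    """Outcome of the classification state machine for one cell."""

    flags: pd.DataFrame               # per-interval boolean columns
    invalid_from: float | None        # time (min) invalidity becomes absorbing
    truncate_at: float | None         # invalid_from - 150 min, floored at 0
    rule: str | None                  # first rule that fired

    @property
    def valid_mask(self) -> np.ndarray:
        """Per-interval validity; False from invalid_from onward (absorbing)."""
        t = self.flags["t_min"].to_numpy()
        if self.invalid_from is None:
            return np.ones(t.size, bool)
        return t < self.invalid_from


def classify_validity(log: pd.DataFrame,
                      thresholds: ValidityThresholds | None = None,
                      ) -> ValidityRecord:
    """Evaluate presence/growth/reporter/responsiveness rules on a cell log.

    ``log`` needs columns ``t_min``, ``growth`` (doublings/h), ``reporter``
    (constitutive channel, a.u.) and ``E_hat``; an optional boolean
    ``present``. A cell is invalidated at the first interval at which any
    rule has failed for ``persistence`` consecutive intervals; invalidity is
    absorbing. ``truncate_at`` marks invalid_from minus 150 min (floored at
    0) for post-hoc analysis.
    """
    th = thresholds if thresholds is not None else ValidityThresholds()
    for col in ("t_min", "growth", "reporter", "E_hat"):
        if col not in log.columns:
            raise ValueError(f"cell log is missing channel {col!r}")
    t = log["t_min"].to_numpy(float)
    present = (log["present"].to_numpy(bool) if "present" in log.columns
               else np.ones(t.size, bool))
    growing = log["growth"].to_numpy(float) >= th.min_growth
    rep_avg = (pd.Series(log["reporter"].to_numpy(float))
               .rolling(th.reporter_window, center=True, min_periods=1).mean())
    reporter_ok = rep_avg.to_numpy() >= th.min_reporter
    responsive = log["E_hat"].to_numpy(float) >= th.min_responsiveness
    flags = pd.DataFrame({"t_min": t, "present": present, "growing": growing,
                          "reporter_ok": reporter_ok, "responsive": responsive})
    invalid_from = None
    rule = None
    fail_run = {name: 0 for name in ("present", "growing", "reporter_ok",
                                     "responsive")}
    for i in range(t.size):
        for name in fail_run:
            fail_run[name] = fail_run[name] + 1 if not flags[name].iat[i] else 0
            if fail_run[name] >= th.persistence and invalid_from is None:
                invalid_from = float(t[i])
                rule = name
        if invalid_from is not None:
            break
    truncate_at = (max(0.0, invalid_from - th.truncate_min)
                   if invalid_from is not None else None)
    return ValidityRecord(flags=flags, invalid_from=invalid_from,
                          truncate_at=truncate_at, rule=rule)


# ---------------------------------------------------------------------------
# runaway blocking (pCL protection)
# ---------------------------------------------------------------------------

def detect_runaway(y: float, population: np.ndarray, c: float = 5.0,
                   abs_cap: float = 100.0) -> bool:
    """Block a cell from the pCL population statistic if its measurement is
    an extreme outlier: ``y > median + c * MAD``; for a degenerate
    population (MAD = 0) an absolute cap applies instead. Blocking never
    alters the cell's own stimuli.
    """
    population = np.asarray(population, float)
    if population.size < 5:
        raise ValueError("population summary needs >= 5 valid cells")
    med = float(np.median(population))
    mad = float(np.median(np.abs(population - med)))
    if mad == 0.0:
        return y > abs_cap
    return y > med + c * mad
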