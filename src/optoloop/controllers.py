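"""Receding-horizon light-sequence planning and the three control modes.

The planner enumerates every binary (red/green) light sequence over a short
horizon, propagates the model-predicted mean fluorescence through each, and
picks the sequence minimizing the summed squared deviation from the target
profile (certainty-equivalent cost). The three control modes differ only in
what feeds the planner:

OL (open loop)
    the entire sequence is precomputed against the nominal average-cell
    model, then broadcast without feedback.
pCL (population closed loop)
    one shared filter is updated from the mean measurement of valid,
    non-blocked cells and a single stimulus is broadcast to all cells.
iCL (individual closed loop)
    each cell has its own filter and receives its own stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .virtual_cell import CellParams, CONTROL_INTERVAL
from .moments_filter import (FilterState, kalman_update, predict_mean,
                             propagate_moments)

MAX_HORIZON = 12          # exhaustive-search guard: 2^12 candidates
DEFAULT_HORIZON = 8


# ---------------------------------------------------------------------------
# target profiles
# ---------------------------------------------------------------------------

@dataclass
class TargetProfile:
    """Time -> desired fluorescence (a.u.); vectorized over t (minutes).

    Step profiles are right-continuous (the new level applies at its start
    time). Raster profiles map one binarized image row onto equal time bins
    with two levels.
    """

    kind: str
    lookup: Callable[[np.ndarray], np.ndarray]
    spec: dict = field(default_factory=dict)

    def __call__(self, t):
        return self.lookup(np.asarray(t, float))


def make_target_profile(spec: dict) -> TargetProfile:
    """Build a profile from a config mapping.

    Kinds::

        {"kind": "constant", "level": 15.0}
        {"kind": "steps", "times": [0, 780], "levels": [10, 20]}   # right-continuous
        {"kind": "sine", "mean": 15, "amplitude": 5, "period": 480, "phase": 0}
        {"kind": "raster_row", "row": [0,1,1,...], "duration": 1440,
         "levels": [0, 15]}
    """
    kind = spec["kind"]
    if kind == "constant":
        level = float(spec["level"])
        if level < 0:
            raise ValueError("target level must be >= 0")
        return TargetProfile(kind, lambda t: np.full_like(t, level, dtype=float),
                             dict(spec))
    if kind == "steps":
        times = np.asarray(spec["times"], float)
        levels = np.asarray(spec["levels"], float)
        if times.size != levels.size or times.size == 0:
            raise ValueError("steps require matching times and levels")
        if np.any(levels < 0):
            raise ValueError("target levels must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("step times must be increasing")

        def _steps(t, times=times, levels=levels):
            idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, None)
            return levels[idx]

        return TargetProfile(kind, _steps, dict(spec))
    if kind == "sine":
        mean = float(spec["mean"])
        amp = float(spec["amplitude"])
        period = float(spec["period"])
        phase = float(spec.get("phase", 0.0))
        if mean - abs(amp) < 0:
            raise ValueError("sine target dips below zero")

        def _sine(t):
            return mean + amp * np.sin(2.0 * math.pi * t / period + phase)

        return TargetProfile(kind, _sine, dict(spec))
    if kind == "raster_row":
        row = np.asarray(spec["row"])
        if row.size == 0:
            raise ValueError("empty raster row")
        duration = float(spec["duration"])
        lo, hi = (float(v) for v in spec.get("levels", (0.0, 15.0)))
        if lo < 0 or hi < 0:
            raise ValueError("target levels must be >= 0")
        levels = np.where(row.astype(bool), hi, lo)
        bin_w = duration / row.size

        def _raster(t, levels=levels, bin_w=bin_w):
            idx = np.clip((t // bin_w).astype(int), 0, levels.size - 1)
            return levels[idx].astype(float)

        return TargetProfile(kind, _raster, dict(spec))
    raise ValueError(f"unknown target kind: {kind!r}")


def raster_targets(image: np.ndarray, duration: float,
                   levels: tuple[float, float] = (0.0, 15.0),
                   ) -> list[TargetProfile]:
    """One two-level profile per image row; columns become equal time bins."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("raster image must be a non-empty 2-D array")
    return [make_target_profile({"kind": "raster_row", "row": row,
                                 "duration": duration, "levels": levels})
            for row in image]


# ---------------------------------------------------------------------------
# exhaustive receding-horizon planner
# ---------------------------------------------------------------------------

class ControlPlan(NamedTuple):
    sequence: tuple[int, ...]
    cost: float


def _candidate_order(N: int):
    """All 2^N binary sequences, sorted by (number of green intervals,
    lexicographic red-first); argmin over this order implements the
    tie-break."""
    codes = np.arange(2 ** N, dtype=np.int64)
    bits = (codes[:, None] >> (N - 1 - np.arange(N))) & 1     # lexicographic
    order = np.lexsort((codes, bits.sum(axis=1)))
    return bits[order].astype(float)


_ORDER_CACHE: dict[int, np.ndarray] = {}


def _candidates(N: int) -> np.ndarray:
    if N not in _ORDER_CACHE:
        _ORDER_CACHE[N] = _candidate_order(N)
    return _ORDER_CACHE[N]


def plan_batch(H0: np.ndarray, E0: np.ndarray, F0: np.ndarray,
               targets: np.ndarray, params: CellParams, N: int,
               dt: float = CONTROL_INTERVAL):
    """Plan for n cells at once.

    ``H0, E0, F0``: (n,) current state estimates; ``targets``: (n, N) target
    levels at the N future interval ends. Returns ``(sequences (n, N) int,
    costs (n,))`` where each row is that cell's optimal plan.
    """
    if N < 1:
        raise ValueError("horizon must be >= 1")
    if N > MAX_HORIZON:
        raise ValueError(f"horizon > {MAX_HORIZON} would enumerate "
                         f"{2 ** N} sequences")
    seqs = _candidates(N)                                   # (M, N)
    M = seqs.shape[0]
    H = np.broadcast_to(np.asarray(H0, float)[:, None], (len(H0), M)).copy()
    E = np.broadcast_to(np.asarray(E0, float)[:, None], (len(H0), M)).copy()
    F = np.broadcast_to(np.asarray(F0, float)[:, None], (len(H0), M)).copy()
    cost = np.zeros((len(H0), M))
    for k in range(N):
        u = seqs[:, k][None, :]                             # (1, M)
        H, E, F = predict_mean(H, E, F, u, dt, params)
        cost += (F - np.asarray(targets, float)[:, k][:, None]) ** 2
    best = np.argmin(cost, axis=1)                          # first min wins ties
    return seqs[best].astype(int), cost[np.arange(len(H0)), best]


def plan_receding_horizon(fs: FilterState, target: TargetProfile, t: float,
                          N: int, params: CellParams,
                          dt: float = CONTROL_INTERVAL) -> ControlPlan:
    """Optimal binary light sequence over the next N intervals.

    Enumerates all 2^N candidates, propagates the predicted mean F through
    each, and minimizes the summed squared target deviation at interval
    ends. Exact ties resolve toward fewer green intervals, then
    lexicographically red-first.
    """
    tgt = target(t + dt * np.arange(1, N + 1))
    seq, cost = plan_batch(np.array([fs.H_now]), np.array([fs.mean[0]]),
                           np.array([fs.mean[1]]), tgt[None, :], params, N, dt)
    return ControlPlan(tuple(int(v) for v in seq[0]), float(cost[0]))


# ---------------------------------------------------------------------------
# control modes
# ---------------------------------------------------------------------------

class ControllerStep(NamedTuple):
    stimulus: int
    fs_next: FilterState          # prediction for the next measurement time
    posterior: FilterState        # estimate after fusing this measurement


def icl_step(fs: FilterState, y: float, target: TargetProfile, t: float,
             params: CellParams, N: int = DEFAULT_HORIZON,
             dt: float = CONTROL_INTERVAL) -> ControllerStep:
    """One individual-closed-loop interval: update, plan, emit, advance."""
    post = kalman_update(fs, y, params.sigma_m)
    plan = plan_receding_horizon(post, target, t, N, params, dt)
    u = plan.sequence[0]
    fs_next = propagate_moments(post, u, dt, params)
    return ControllerStep(u, fs_next, post)


def pcl_step(ys: Sequence[float], fs: FilterState, target: TargetProfile,
             t: float, params: CellParams, N: int = DEFAULT_HORIZON,
             dt: float = CONTROL_INTERVAL) -> ControllerStep:
    """One population-closed-loop interval.

    ``ys`` are the measurements of valid, non-blocked cells; the shared
    filter is updated from their mean and one stimulus is broadcast.
    Runaway robustness comes from the blocking rule upstream
    (:func:`optoloop.quantify.detect_runaway`), so the unbiased mean is used
    as the summary statistic; a median summary would systematically offset
    the population mean from the target on skewed (log-normal)
    heterogeneity.
    """
    ys = np.asarray(list(ys), float)
    if ys.size == 0:
        raise ValueError("pCL requires at least one valid, non-blocked cell")
    return icl_step(fs, float(np.mean(ys)), target, t, params, N, dt)


def precompute_ol_sequence(target: TargetProfile, nominal: CellParams,
                           duration: float, N: int = DEFAULT_HORIZON,
                           dt: float = CONTROL_INTERVAL,
                           init: FilterState | None = None) -> np.ndarray:
    """Open-loop stimulus schedule planned against the nominal model.

    Runs the receding-horizon planner with the nominal model's own
    predictions standing in for measurements (no online learning), records
    the first stimulus of each interval's plan, and returns the fixed
    sequence to broadcast to every assigned cell.
    """
    n_int = int(round(duration / dt))
    if abs(n_int * dt - duration) > 1e-9 or n_int < 0:
        raise ValueError("duration must be a multiple of the control interval")
    fs = init if init is not None else FilterState.initial(nominal)
    H, E, F = fs.H_now, fs.mean[0], fs.mean[1]
    seq = np.empty(n_int, dtype=int)
    for k in range(n_int):
        t = k * dt
        tgt = target(t + dt * np.arange(1, N + 1))
        s, _ = plan_batch(np.array([H]), np.array([E]), np.array([F]),
                          tgt[None, :], nominal, N, dt)
        u = int(s[0, 0])
        seq[k] = u
        H, E, F = (float(v) for v in predict_mean(H, E, F, float(u), dt, nominal))
    return seq
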