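"""Hybrid bio-digital circuits: virtual inhibitory signal and cell coupling.

A delayed negative-feedback oscillator is built by virtualizing the
inhibitory species of a classic genetic oscillator: each measurement
interval ``i``, a digital signal ``S_i`` accumulates in proportion to the
cell's measured fluorescence (rate ``r``) and is removed in proportion to
its own prior level (fraction ``d``); a digital promoter state ``P`` is
fully off when ``S`` exceeds the threshold ``theta`` and fully on
otherwise, and is fed back to the cell as red/green light. Cell--cell
communication is specified by multiplying the population signal vector by a
transfer matrix ``T`` each interval, which freely sets the topology, sign
and strength of the coupling (symmetric transfer, mutual inhibition, or
directed add/remove patterns on a ring).

Update order per interval (config-gated, default): measure -> local
production/removal -> transfer -> threshold -> stimulus for the next
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .virtual_cell import (PopulationSpec, PopulationState,
                           CONTROL_INTERVAL, init_population,
                           measure_population, step_population)


@dataclass
class HybridParams:
    """Digital-circuit parameters (Fig-style defaults r=3, d=0.2, theta=60)."""

    r: float = 3.0                  # signal a.u. per fluorescence a.u. per interval
    d: float = 0.2                  # removal fraction per interval
    theta: float = 60.0             # promoter threshold (signal a.u.)
    T: np.ndarray | None = None     # n x n transfer matrix; None = uncoupled
    clamp: bool = True              # clip S at 0 after transfer
    transfer_first: bool = False    # apply T before the local update

    def __post_init__(self) -> None:
        if not (0.0 <= self.d < 1.0):
            raise ValueError("removal fraction d must lie in [0, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.T is not None:
            self.T = np.asarray(self.T, float)
            if self.T.ndim != 2 or self.T.shape[0] != self.T.shape[1]:
                raise ValueError("T must be square")
            if not np.all(np.isfinite(self.T)):
                raise ValueError("T must be finite")


@dataclass
class HybridState:
    """Vector of virtual signals and promoter states for one cell group."""

    S: np.ndarray
    P: np.ndarray                   # bool: True = on (green)
    i: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, float)
        self.P = np.asarray(self.P, bool)


def update_virtual_signal(S: np.ndarray, F_measured: np.ndarray,
                          r: float, d: float) -> np.ndarray:
    """S' = S + r*F - d*S, elementwise."""
    S = np.asarray(S, float)
    F = np.asarray(F_measured, float)
    if S.shape != F.shape:
        raise ValueError("signal and fluorescence vectors must align")
    if np.any(F < 0):
        raise ValueError("measured fluorescence must be >= 0")
    return S + r * F - d * S


def apply_transfer(S: np.ndarray, T: np.ndarray, clamp: bool = True):
    """Redistribute signal: S'' = T @ S, optionally clipped at 0.

    Returns ``(S'', n_clamped)``; a column-stochastic non-negative T
    conserves the total signal exactly.
    """
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    if T.ndim != 2 or T.shape != (S.size, S.size):
        raise ValueError("T must be n x n for an n-vector S")
    out = T @ S
    n_clamped = 0
    if clamp:
        neg = out < 0
        n_clamped = int(neg.sum())
        out = np.maximum(out, 0.0)
    return out, n_clamped


def promoter_states(S: np.ndarray, theta: float):
    """Threshold the signal: off (red) iff S > theta, else on (green).

    Returns ``(P, stimuli)`` with P boolean (True = on) and stimuli in
    {0 = red, 1 = green}. Comparison is strict: S == theta is on.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    S = np.asarray(S, float)
    P = ~(S > theta)
    return P, P.astype(int)


def ring_transfer_matrix(n: int, f: float, mode: str = "transfer") -> np.ndarray:
    """Cyclic nearest-neighbour transfer matrix.

    transfer
        fraction ``f`` of each cell's signal moves to each neighbour
        (diagonal ``1 - 2f``; conservative).
    inhibit
        each cell removes ``f`` of its signal level from each neighbour
        (diagonal 1, off-diagonals ``-f``; negatives clamped downstream).
    asymmetric
        ``f`` of each cell's signal is added to its left neighbour and
        removed from its right neighbour (diagonal ``1 - f``).
    """
    if n < 3:
        raise ValueError("a cycle needs n >= 3")
    if not (0.0 <= f < 0.5):
        raise ValueError("coupling fraction must lie in [0, 0.5)")
    T = np.eye(n)
    left = (np.arange(n) - 1) % n
    right = (np.arange(n) + 1) % n
    if mode == "transfer":
        T *= 1.0 - 2.0 * f
        T[left, np.arange(n)] += f
        T[right, np.arange(n)] += f
    elif mode == "inhibit":
        T[left, np.arange(n)] -= f
        T[right, np.arange(n)] -= f
    elif mode == "asymmetric":
        T *= 1.0 - f
        T[left, np.arange(n)] += f
        T[right, np.arange(n)] -= f
    else:
        raise ValueError(f"unknown coupling mode: {mode!r}")
    return T


def run_hybrid_experiment(n_cells: int, hp: HybridParams, duration: float,
                          spec: PopulationSpec | None = None, seed: int = 0,
                          interval: float = CONTROL_INTERVAL) -> pd.DataFrame:
    """Closed-loop hybrid-oscillator experiment on virtual cells.

    Per interval: measure all cells, update the virtual signal, apply the
    transfer matrix (if coupled), threshold into promoter states, and apply
    the resulting stimuli to the cells over the next interval. Returns a
    tidy per-cell log with columns ``cell_id, t_min, y, F, E, S, P, u,
    clamped``.
    """
    n_int = int(round(duration / interval))
    if abs(n_int * interval - duration) > 1e-9:
        raise ValueError("duration must be a multiple of the interval")
    if spec is None:
        spec = PopulationSpec(n_cells=n_cells, seed=seed)
    elif spec.n_cells != n_cells:
        raise ValueError("population spec size must match n_cells")
    cells = init_population(spec)
    params = spec.params
    pop = PopulationState(cells)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0DD]))
    state = HybridState(S=np.zeros(n_cells), P=np.ones(n_cells, bool))
    u = np.ones(n_cells)          # promoters start on -> green
    rows = []
    for i in range(n_int):
        t = i * interval
        y = measure_population(pop.F, params.sigma_m, rng)
        S = state.S
        n_clamped = 0
        if hp.transfer_first and hp.T is not None:
            S, n_clamped = apply_transfer(S, hp.T, hp.clamp)
        S = update_virtual_signal(S, y, hp.r, hp.d)
        if not hp.transfer_first and hp.T is not None:
            S, n_clamped = apply_transfer(S, hp.T, hp.clamp)
        P, stim = promoter_states(S, hp.theta)
        state = HybridState(S=S, P=P, i=i + 1)
        for c in range(n_cells):
            rows.append((c, t, y[c], pop.F[c], pop.E[c], S[c],
                         bool(P[c]), int(stim[c]), n_clamped))
        u = stim.astype(float)
        step_population(pop, params, u, interval, rng)
    return pd.DataFrame(rows, columns=["cell_id", "t_min", "y", "F", "E",
                                       "S", "P", "u", "clamped"])
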