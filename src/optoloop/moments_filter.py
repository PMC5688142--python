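"""Moment-equation prediction and Kalman updating of cell responsiveness.

Given the virtual-cell model (H deterministic, E an OU process, F linear
birth--death with Langevin noise), the conditional law of ``(E, F)`` given
the input history is Gaussian to second order, and its mean and covariance
obey closed moment ODEs:

    d m/dt   = A(t) m + c
    d P/dt   = A(t) P + P A(t)^T + Q(t)

with ``A(t) = [[-1/tau_E, 0], [k_F H(t), -gamma]]``,
``c = (E_bar/tau_E, f0)``,
``Q(t) = diag(2 sigma_E^2/tau_E, omega (f0 + k_F H m_E + gamma m_F))``
and ``H(t)`` advanced analytically from the applied input. A standard
linear-Gaussian measurement update on the F component then fuses each
fluorescence measurement, weighting prediction and measurement by their
respective uncertainties; the responsiveness estimate moves only through
the E--F covariance.

Because H is treated as known given the input history, the filter is exact
for the model (up to the Langevin closure of the F noise intensity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .virtual_cell import CellParams, CONTROL_INTERVAL

_PSD_TOL = 1e-9


@dataclass
class FilterState:
    """Posterior mean/covariance over (E, F) plus the deterministic H."""

    mean: np.ndarray                      # shape (2,): (E, F)
    cov: np.ndarray                       # shape (2, 2)
    t: float = 0.0
    H_now: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).reshape(2)
        self.cov = np.asarray(self.cov, float).reshape(2, 2)
        _check_psd(self.cov)

    @classmethod
    def initial(cls, params: CellParams, y0: float | None = None,
                prior_E_sd: float | None = None) -> "FilterState":
        """Default initialization: E at the population mean, F at the first
        measurement (or the dark steady state), diagonal covariance
        (prior_E_sd^2, sigma_m^2)."""
        f = params.f0 / params.gamma if y0 is None else max(0.0, y0)
        sd = params.sigma_E if prior_E_sd is None else prior_E_sd
        return cls(mean=np.array([params.E_bar, f]),
                   cov=np.diag([sd ** 2, params.sigma_m ** 2]))


def _check_psd(cov: np.ndarray) -> None:
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if np.min(np.linalg.eigvalsh(0.5 * (cov + cov.T))) < -_PSD_TOL:
        raise ValueError("covariance must be positive semidefinite")


# ---------------------------------------------------------------------------
# moment propagation
# ---------------------------------------------------------------------------

def _moment_rhs(t, y, n, u, H0, p: CellParams):
    """RHS of the stacked mean/covariance ODEs for n cells."""
    mE, mF, Pee, Pef, Pff = y.reshape(5, n)
    H = u + (H0 - u) * np.exp(-p.k_H * t)
    kH = p.k_F * H
    dmE = (p.E_bar - mE) / p.tau_E
    dmF = p.f0 + kH * mE - p.gamma * mF
    q_E = 2.0 * p.sigma_E ** 2 / p.tau_E
    q_F = p.omega * (p.f0 + kH * mE + p.gamma * mF)
    dPee = -2.0 * Pee / p.tau_E + q_E
    dPef = kH * Pee - (1.0 / p.tau_E + p.gamma) * Pef
    dPff = 2.0 * kH * Pef - 2.0 * p.gamma * Pff + q_F
    return np.concatenate([dmE, dmF, dPee, dPef, dPff])


def propagate_moments_batch(mean: np.ndarray, cov: np.ndarray, H0: np.ndarray,
                            u: np.ndarray, dt: float, params: CellParams,
                            rtol: float = 1e-8, atol: float = 1e-10):
    """Propagate n filter states jointly over one interval.

    ``mean``: (n, 2); ``cov``: (n, 2, 2); ``H0``, ``u``: (n,). Returns
    ``(mean', cov', H')``. One adaptive integration is shared by all cells.
    """
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    H0 = np.asarray(H0, float)
    u = np.asarray(u, float)
    n = mean.shape[0]
    y0 = np.concatenate([mean[:, 0], mean[:, 1],
                         cov[:, 0, 0], cov[:, 0, 1], cov[:, 1, 1]])
    sol = solve_ivp(_moment_rhs, (0.0, dt), y0, args=(n, u, H0, params),
                    method="RK45", rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:                                      # pragma: no cover
        raise RuntimeError(f"moment integration failed: {sol.message}")
    mE, mF, Pee, Pef, Pff = sol.y[:, -1].reshape(5, n)
    mean_out = np.stack([mE, mF], axis=1)
    cov_out = np.empty((n, 2, 2))
    cov_out[:, 0, 0] = np.maximum(Pee, 0.0)
    cov_out[:, 0, 1] = cov_out[:, 1, 0] = Pef
    cov_out[:, 1, 1] = np.maximum(Pff, 0.0)
    H_out = u + (H0 - u) * np.exp(-params.k_H * dt)
    return mean_out, cov_out, H_out


def propagate_moments(fs: FilterState, u: int, dt: float,
                      params: CellParams) -> FilterState:
    """Predict the filter state one interval ahead under binary input ``u``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if u not in (0, 1):
        raise ValueError("stimulus must be 0 (red) or 1 (green)")
    _check_psd(fs.cov)
    m, P, H = propagate_moments_batch(fs.mean[None, :], fs.cov[None, :, :],
                                      np.array([fs.H_now]), np.array([float(u)]),
                                      dt, params)
    return FilterState(mean=m[0], cov=P[0], t=fs.t + dt, H_now=float(H[0]))


# ---------------------------------------------------------------------------
# analytic mean propagation (used by the receding-horizon planner)
# ---------------------------------------------------------------------------

def predict_mean(H0, E0, F0, u, dt: float, params: CellParams):
    """Closed-form means of (H, E, F) one interval ahead.

    The mean ODEs are linear with exponential forcing; F integrates the
    four-exponential forcing ``f0 + k_F H(t) m_E(t)`` against the dilution
    decay exactly. All arguments broadcast (used vectorized over candidate
    light sequences and cells).
    """
    p = params
    H0 = np.asarray(H0, float)
    E0 = np.asarray(E0, float)
    F0 = np.asarray(F0, float)
    u = np.asarray(u, float)
    aE = 1.0 / p.tau_E
    H1 = u + (H0 - u) * math.exp(-p.k_H * dt)
    E1 = p.E_bar + (E0 - p.E_bar) * math.exp(-aE * dt)

    def phi(a):
        # int_0^dt exp(-gamma (dt - s)) exp(-a s) ds
        if abs(p.gamma - a) > 1e-12:
            return (math.exp(-a * dt) - math.exp(-p.gamma * dt)) / (p.gamma - a)
        return dt * math.exp(-p.gamma * dt)

    dE = E0 - p.E_bar
    dH = H0 - u
    F1 = (F0 * math.exp(-p.gamma * dt)
          + p.f0 * phi(0.0)
          + p.k_F * (u * p.E_bar * phi(0.0)
                     + u * dE * phi(aE)
                     + dH * p.E_bar * phi(p.k_H)
                     + dH * dE * phi(p.k_H + aE)))
    return H1, E1, F1


# ---------------------------------------------------------------------------
# measurement update
# ---------------------------------------------------------------------------

def kalman_update_batch(mean: np.ndarray, cov: np.ndarray, y: np.ndarray,
                        sigma_m: float):
    """Vectorized linear-Gaussian update observing the F component."""
    if sigma_m < 0:
        raise ValueError("sigma_m must be >= 0")
    S = cov[:, 1, 1] + sigma_m ** 2
    # S == 0 only if Pff = Pef = 0 too (PSD), where the gain is zero anyway
    safe_S = np.where(S > 0, S, 1.0)
    K = cov[:, :, 1] / safe_S[:, None]                 # (n, 2) gain
    innov = y - mean[:, 1]
    mean_out = np.maximum(mean + K * innov[:, None], 0.0)
    # Joseph-form update, specialized to H_obs = [0, 1]
    IKH = np.tile(np.eye(2), (mean.shape[0], 1, 1))
    IKH[:, 0, 1] -= K[:, 0]
    IKH[:, 1, 1] -= K[:, 1]
    cov_out = (IKH @ cov @ IKH.transpose(0, 2, 1)
               + sigma_m ** 2 * np.einsum("ni,nj->nij", K, K))
    return mean_out, cov_out


def kalman_update(predicted: FilterState, y: float,
                  sigma_m: float) -> FilterState:
    """Fuse one fluorescence measurement into the predicted state.

    Posterior covariance never exceeds the prior (Loewner order); means are
    clamped at 0 after the update, covariance untouched.
    """
    _check_psd(predicted.cov)
    m, P = kalman_update_batch(predicted.mean[None, :], predicted.cov[None],
                               np.array([float(y)]), sigma_m)
    return FilterState(mean=m[0], cov=P[0], t=predicted.t,
                       H_now=predicted.H_now)


# ---------------------------------------------------------------------------
# whole-record smoother-free estimation
# ---------------------------------------------------------------------------

def estimate_responsiveness(y: np.ndarray, stimulus: np.ndarray,
                            params: CellParams,
                            interval: float = CONTROL_INTERVAL,
                            init: FilterState | None = None) -> pd.DataFrame:
    """Filter a whole measurement record; return per-interval E estimates.

    ``y[k]`` is the measurement at time ``k * interval``; ``stimulus[k]`` is
    the input applied over the following interval. Returns a DataFrame with
    columns ``t_min, E_hat, E_sd, F_hat, innovation, innovation_sd``
    (posterior quantities at each measurement time).
    """
    y = np.asarray(y, float)
    stimulus = np.asarray(stimulus, float)
    if y.shape != stimulus.shape:
        raise ValueError("measurement and stimulus series must be aligned")
    fs = init if init is not None else FilterState.initial(params, y0=y[0])
    rows = []
    for k in range(y.size):
        innov_sd = math.sqrt(fs.cov[1, 1] + params.sigma_m ** 2)
        innov = y[k] - fs.mean[1]
        fs = kalman_update(fs, y[k], params.sigma_m)
        rows.append((k * interval, fs.mean[0], math.sqrt(max(fs.cov[0, 0], 0.0)),
                     fs.mean[1], innov, innov_sd))
        fs = propagate_moments(fs, int(stimulus[k]), interval, params)
    return pd.DataFrame(rows, columns=["t_min", "E_hat", "E_sd", "F_hat",
                                       "innovation", "innovation_sd"])
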