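"""Experiment orchestration and the platform's analysis metrics.

Runs the 6-min measure -> estimate -> plan -> stimulate loop over a
simulated population with per-cell controller assignment (OL, pCL, iCL or a
hybrid circuit), media perturbation events, and online cell invalidation,
and provides the analytics used to summarize such experiments: average
mean-subtracted power spectral densities, expression-peak detection, cross-
correlation phase lags, and windowed error/perturbation summaries.

Loop-order contract: the measurement at interval ``i`` (time ``6 i`` min)
precedes the stimulus decision, and the decided stimulus is applied over
the following interval.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import periodogram, find_peaks

from . import controllers as ctrl
from . import hybrid_circuits as hc
from . import quantify as qt
from .moments_filter import kalman_update_batch, propagate_moments_batch
from .virtual_cell import (PerturbationEvent, PopulationSpec,
                           PopulationState, CONTROL_INTERVAL, init_population,
                           measure_population, step_population)

#: constitutive-reporter level synthesized for the QC channel (a.u.)
CONST_REPORTER_LEVEL = 10.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    """One controller group: contiguous block of cells sharing a mode."""

    controller: str                      # OL | pCL | iCL | hybrid
    n_cells: int
    target: dict | None = None           # target-profile spec (non-hybrid)
    circuit: dict | None = None          # {r, d, theta, mode, f} (hybrid)
    switch_at: float | None = None       # min; controller change time
    switch_to: str | None = None

    def __post_init__(self) -> None:
        if self.controller not in ("OL", "pCL", "iCL", "hybrid"):
            raise ValueError(f"unknown controller {self.controller!r}")
        if self.n_cells < 1:
            raise ValueError("each group needs at least one cell")
        if self.controller != "hybrid" and self.target is None:
            raise ValueError("non-hybrid groups need a target spec")
        if self.controller == "hybrid" and self.circuit is None:
            raise ValueError("hybrid groups need a circuit spec")
        if (self.switch_at is None) != (self.switch_to is None):
            raise ValueError("switch_at and switch_to must be set together")


@dataclass
class ExperimentConfig:
    duration: float                       # min
    groups: list[GroupConfig]
    population: PopulationSpec | None = None   # sized to sum of groups if None
    perturbations: list[PerturbationEvent] = field(default_factory=list)
    seed: int = 0
    interval: float = CONTROL_INTERVAL
    horizon: int = ctrl.DEFAULT_HORIZON
    heterogeneity_cv: float = 0.3         # used when population is None
    validity: qt.ValidityThresholds = field(default_factory=qt.ValidityThresholds)
    qc_online: bool = True

    def __post_init__(self) -> None:
        n_int = round(self.duration / self.interval)
        if abs(n_int * self.interval - self.duration) > 1e-9 or self.duration < 0:
            raise ValueError("duration must be a non-negative multiple of "
                             "the control interval")
        n = sum(g.n_cells for g in self.groups)
        if self.population is None:
            self.population = PopulationSpec.from_mean_cv(
                n_cells=n, mean=1.0, cv=self.heterogeneity_cv, seed=self.seed)
        elif self.population.n_cells != n:
            raise ValueError("population size must equal total group size")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        groups = [GroupConfig(**g) for g in d["groups"]]
        perts = [PerturbationEvent(**p) for p in d.get("perturbations", [])]
        kwargs = {k: d[k] for k in ("duration", "seed", "interval", "horizon",
                                    "heterogeneity_cv") if k in d}
        return cls(groups=groups, perturbations=perts, **kwargs)

    @classmethod
    def from_file(cls, path: str) -> "ExperimentConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExperimentLog:
    """Tidy per-cell, per-interval record plus reproducibility metadata."""

    df: pd.DataFrame
    metadata: dict

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# the control loop
# ---------------------------------------------------------------------------

def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> ExperimentLog:
    """Run the full measure/estimate/plan/stimulate loop.

    Deterministic given the config seed. Returns one row per cell per
    interval with columns ``cell_id, group, controller, t_min, y, F_true,
    E_true, length, u, E_hat, E_sd, F_hat, target, S, P, valid, blocked,
    growth``.
    """
    p_template = config.population.params
    n = config.population.n_cells
    n_int = int(round(config.duration / config.interval))
    cells = init_population(config.population)
    pop = PopulationState(cells)
    base_gamma = pop.gamma.copy()
    base_Ebar = pop.E_bar.copy()
    base_sigE = pop.sigma_E.copy()
    ss = np.random.SeedSequence(config.seed)
    rng_dyn, rng_meas, rng_lag = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    lags = [ev.sample_lag(rng_lag) for ev in config.perturbations]

    # controller bookkeeping -------------------------------------------------
    groups = []
    idx0 = 0
    for g in config.groups:
        sl = slice(idx0, idx0 + g.n_cells)
        idx0 += g.n_cells
        entry = {"cfg": g, "slice": sl, "mode": g.controller,
                 "target": None, "ol_seq": None, "hstate": None, "hp": None}
        if g.controller != "hybrid":
            entry["target"] = ctrl.make_target_profile(g.target)
        else:
            circ = dict(g.circuit)
            mode = circ.pop("mode", None)
            f = circ.pop("f", 0.0)
            T = None
            if mode is not None and f:
                T = hc.ring_transfer_matrix(g.n_cells, f, mode)
            entry["hp"] = hc.HybridParams(T=T, **circ)
            entry["hstate"] = hc.HybridState(S=np.zeros(g.n_cells),
                                             P=np.ones(g.n_cells, bool))
        groups.append(entry)

    def _ensure_ol_sequence(entry, start_interval):
        if entry["ol_seq"] is None:
            remaining = (n_int - start_interval) * config.interval
            seq = ctrl.precompute_ol_sequence(
                entry["target"], p_template, remaining,
                N=config.horizon, dt=config.interval)
            entry["ol_seq"] = (start_interval, seq)

    # per-cell filter state (shared layout for iCL and pCL groups)
    fmean = np.tile([p_template.E_bar, p_template.f0 / p_template.gamma], (n, 1))
    fcov = np.tile(np.diag([p_template.sigma_E ** 2,
                            p_template.sigma_m ** 2]), (n, 1, 1))
    fH = np.zeros(n)

    u = np.zeros(n)                       # stimulus applied over next interval
    valid = np.ones(n, bool)
    invalid_from = np.full(n, np.nan)
    fail_run = np.zeros((n, 3), int)      # growth, reporter, responsiveness
    length_hist: list[np.ndarray] = []
    rows = []

    for i in range(n_int):
        t = i * config.interval
        # perturbations: recompute per-cell rates from baselines (idempotent)
        gamma_t = base_gamma.copy()
        Ebar_t = base_Ebar.copy()
        sigE_t = base_sigE.copy()
        for ev, lag in zip(config.perturbations, lags):
            t_eff = ev.t_switch + lag
            if t >= t_eff:
                gamma_t *= ev.gamma_factor
                ramp = max(0.0, t - t_eff - ev.resp_delay)
                fac = 1.0 + (ev.resp_factor - 1.0) * (1.0 - math.exp(-ramp / ev.resp_tau))
                Ebar_t *= fac
                sigE_t *= fac
        pop.gamma, pop.E_bar, pop.sigma_E = gamma_t, Ebar_t, sigE_t

        # measurement ------------------------------------------------------
        y = measure_population(pop.F, p_template.sigma_m, rng_meas)
        reporter = np.maximum(
            0.0, CONST_REPORTER_LEVEL
            + p_template.sigma_m * rng_meas.standard_normal(n))
        length_hist.append(pop.length.copy())

        # online QC ----------------------------------------------------------
        growth = np.full(n, np.nan)
        if len(length_hist) >= 2:
            win = np.array(length_hist[-(config.validity.reporter_window + 1):])
            for c in range(n):
                try:
                    growth[c] = qt.estimate_growth_rate(
                        win[:, c], dt_min=config.interval,
                        window=min(config.validity.reporter_window,
                                   win.shape[0] - 1))[-1]
                except ValueError:
                    growth[c] = np.nan
        if config.qc_online and i >= config.validity.persistence:
            checks = np.stack([
                np.nan_to_num(growth, nan=np.inf) >= config.validity.min_growth,
                reporter >= config.validity.min_reporter,
                fmean[:, 0] >= config.validity.min_responsiveness,
            ], axis=1)
            fail_run = np.where(checks, 0, fail_run + 1)
            newly = valid & (fail_run >= config.validity.persistence).any(axis=1)
            invalid_from[newly] = t
            valid &= ~newly

        # controller steps ---------------------------------------------------
        E_hat = np.full(n, np.nan)
        E_sd = np.full(n, np.nan)
        F_hat = np.full(n, np.nan)
        target_now = np.full(n, np.nan)
        S_log = np.full(n, np.nan)
        P_log = np.full(n, -1)
        blocked = np.zeros(n, bool)

        for entry in groups:
            g = entry["cfg"]
            sl = entry["slice"]
            if g.switch_at is not None and t >= g.switch_at:
                if entry["mode"] != g.switch_to:
                    entry["mode"] = g.switch_to
                    entry["ol_seq"] = None
            mode = entry["mode"]
            gv = valid[sl]
            if mode == "hybrid":
                hp = entry["hp"]
                st = entry["hstate"]
                S = st.S
                ncl = 0
                if hp.transfer_first and hp.T is not None:
                    S, ncl = hc.apply_transfer(S, hp.T, hp.clamp)
                S = hc.update_virtual_signal(S, y[sl], hp.r, hp.d)
                if not hp.transfer_first and hp.T is not None:
                    S, ncl = hc.apply_transfer(S, hp.T, hp.clamp)
                P, stim = hc.promoter_states(S, hp.theta)
                entry["hstate"] = hc.HybridState(S=S, P=P, i=i + 1)
                u[sl] = stim
                S_log[sl] = S
                P_log[sl] = P.astype(int)
                continue

            tgt = entry["target"]
            target_now[sl] = tgt(t)
            if mode == "OL":
                _ensure_ol_sequence(entry, i)
                k0, seq = entry["ol_seq"]
                u[sl] = seq[i - k0] if 0 <= i - k0 < seq.size else 0
                # keep per-cell filters advancing for logging/QC
                m_post, P_post = kalman_update_batch(
                    fmean[sl], fcov[sl], y[sl], p_template.sigma_m)
            elif mode == "pCL":
                ys = y[sl][gv]
                if ys.size >= 5:
                    keep = np.array([not qt.detect_runaway(v, ys) for v in ys])
                    blocked_idx = np.where(gv)[0][~keep]
                    b = np.zeros(gv.size, bool)
                    b[blocked_idx] = True
                    blocked[sl] = b
                    ys = ys[keep]
                if ys.size == 0:
                    raise RuntimeError("pCL group has no valid cells")
                y_med = float(np.mean(ys))
                m_post, P_post = kalman_update_batch(
                    fmean[sl][:1], fcov[sl][:1], np.array([y_med]),
                    p_template.sigma_m)
                tgtN = tgt(t + config.interval
                           * np.arange(1, config.horizon + 1))
                seq, _ = ctrl.plan_batch(fH[sl][:1], m_post[:1, 0],
                                         m_post[:1, 1], tgtN[None, :],
                                         p_template, config.horizon,
                                         config.interval)
                u[sl] = seq[0, 0]
                m_post = np.tile(m_post, (g.n_cells, 1))
                P_post = np.tile(P_post, (g.n_cells, 1, 1))
            else:  # iCL
                m_post, P_post = kalman_update_batch(
                    fmean[sl], fcov[sl], y[sl], p_template.sigma_m)
                tgtN = tgt(t + config.interval
                           * np.arange(1, config.horizon + 1))
                targetsN = np.tile(tgtN, (g.n_cells, 1))
                seq, _ = ctrl.plan_batch(fH[sl], m_post[:, 0], m_post[:, 1],
                                         targetsN, p_template,
                                         config.horizon, config.interval)
                u[sl] = seq[:, 0]
            # invalidated cells: default stimulus (red), excluded from stats
            u[sl] = np.where(gv, u[sl], 0.0)
            E_hat[sl] = m_post[:, 0]
            E_sd[sl] = np.sqrt(np.maximum(P_post[:, 0, 0], 0.0))
            F_hat[sl] = m_post[:, 1]
            fmean[sl] = m_post
            fcov[sl] = P_post

        # record -------------------------------------------------------------
        for entry in groups:
            g = entry["cfg"]
            sl = entry["slice"]
            ids = np.arange(sl.start, sl.stop)
            for j, c in enumerate(ids):
                rows.append((int(c), id(entry), entry["mode"], t, y[c],
                             pop.F[c], pop.E[c], pop.length[c], int(u[c]),
                             E_hat[c], E_sd[c], F_hat[c], target_now[c],
                             S_log[c], P_log[c], bool(valid[c]),
                             bool(blocked[c]), growth[c]))

        # advance filters and cells under the decided stimuli ----------------
        for entry in groups:
            sl = entry["slice"]
            if entry["mode"] != "hybrid":
                fmean[sl], fcov[sl], fH[sl] = propagate_moments_batch(
                    fmean[sl], fcov[sl], fH[sl], u[sl], config.interval,
                    p_template)
        step_population(pop, p_template, u, config.interval, rng_dyn)

    df = pd.DataFrame(rows, columns=[
        "cell_id", "group_key", "controller", "t_min", "y", "F_true",
        "E_true", "length", "u", "E_hat", "E_sd", "F_hat", "target", "S",
        "P", "valid", "blocked", "growth"])
    # stable group labels
    keymap = {id(e): gi for gi, e in enumerate(groups)}
    df["group"] = df.pop("group_key").map(keymap)
    meta = {"config_hash": _config_hash(config), "seed": config.seed,
            "n_cells": n, "duration": config.duration,
            "interval": config.interval}
    return ExperimentLog(df=df, metadata=meta)


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------

def compute_psd(trajectories: np.ndarray, interval: float = CONTROL_INTERVAL):
    """Average raw periodogram of mean-subtracted trajectories.

    ``trajectories``: (n_cells, T). Returns ``(f, mean_psd, sem)`` with f in
    min^-1 (one-sided). Each per-cell periodogram satisfies Parseval:
    sum(psd) * df equals the trajectory variance.
    """
    x = np.atleast_2d(np.asarray(trajectories, float))
    if x.shape[1] < 64:
        raise ValueError("need >= 64 time points for a spectral estimate")
    x = x - x.mean(axis=1, keepdims=True)
    f, pxx = periodogram(x, fs=1.0 / interval, detrend=False, axis=1)
    mean = pxx.mean(axis=0)
    sem = (pxx.std(axis=0, ddof=1) / math.sqrt(x.shape[0])
           if x.shape[0] > 1 else np.zeros_like(mean))
    return f, mean, sem


def psd_crossover_frequency(f: np.ndarray, psd_ref: np.ndarray,
                            psd_test: np.ndarray, smooth: int = 5) -> float:
    """Lowest frequency at which ``psd_test`` stops lying below ``psd_ref``.

    Both averaged spectra are smoothed with a ``smooth``-bin moving average
    (periodogram bins are noisy even after averaging over cells); the DC bin
    is excluded. Returns NaN if the test spectrum stays below everywhere.
    Used to locate the bound below which closed-loop feedback suppresses
    fluctuations relative to open loop.
    """
    if f.size != psd_ref.size or f.size != psd_test.size:
        raise ValueError("frequency grid and spectra must align")
    kern = np.ones(smooth) / smooth
    a = np.convolve(psd_ref[1:], kern, mode="same")
    b = np.convolve(psd_test[1:], kern, mode="same")
    below = b < a
    if below.all():
        return float("nan")
    return float(f[1:][np.argmax(~below)])


def detect_expression_peaks(trajectory: np.ndarray,
                            interval: float = CONTROL_INTERVAL,
                            smooth: int = 5,
                            prominence_frac: float = 0.2) -> np.ndarray:
    """Peak times (min) of a fluorescence trajectory.

    Moving-average smoothing, local maxima with prominence >= 20% of the
    smoothed range, peak time refined by a quadratic fit through the three
    samples around each maximum.
    """
    y = np.asarray(trajectory, float)
    if y.size < 20:
        raise ValueError("trajectory too short for peak detection")
    # edge-aware moving average (shrinking window at the boundaries)
    ys = (pd.Series(y).rolling(smooth, center=True, min_periods=1)
          .mean().to_numpy())
    rng_y = ys.max() - ys.min()
    if rng_y <= 0:
        return np.array([])
    idx, _ = find_peaks(ys, prominence=prominence_frac * rng_y)
    margin = max(1, smooth // 2)
    idx = idx[(idx >= margin) & (idx < ys.size - margin)]
    times = []
    for k in idx:
        if 0 < k < ys.size - 1:
            a, b, c = ys[k - 1], ys[k], ys[k + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        else:
            shift = 0.0
        times.append((k + shift) * interval)
    return np.asarray(times)


def phase_lag(traj_a: np.ndarray, traj_b: np.ndarray, period: float,
              interval: float = CONTROL_INTERVAL) -> float:
    """Period-normalized cross-correlation lag of b relative to a.

    The lag (in minutes) of the cross-correlation maximum between the
    mean-subtracted series, wrapped into (-period/2, period/2] and divided
    by the period; positive means b lags a. Identical series give 0,
    anti-phase gives 0.5, quadrature 0.25.
    """
    a = np.asarray(traj_a, float)
    b = np.asarray(traj_b, float)
    if a.shape != b.shape:
        raise ValueError("trajectories must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("zero-variance trajectory")
    cc = np.correlate(b, a, mode="full")
    lags = (np.arange(cc.size) - (a.size - 1)) * interval
    # search within one period: ample to identify the principal lag
    mask = np.abs(lags) <= period
    lag = lags[mask][np.argmax(cc[mask])]
    half = 0.5 * period
    wrapped = ((lag + half) % period) - half        # (-half, half]
    if wrapped <= -half:
        wrapped += period
    if wrapped == -half:
        wrapped = half
    return float(wrapped / period)


def summarize_errors(log: pd.DataFrame, pre_window: tuple[float, float],
                     post_window: tuple[float, float]) -> pd.DataFrame:
    """Per-controller error and perturbation summary.

    For each controller group: mean absolute error of the population mean to
    target, population s.d., and the relative-perturbation statistic
    (per-cell mean fluorescence in the post window divided by the group
    mean in the pre window) with its quartiles. Windows follow the
    before/after-media-switch protocol (e.g. 5 h pre vs 10--15 h post).
    """
    t = log["t_min"]
    tmax = t.max()
    # windows are half-open [t0, t1); t1 may extend to the experiment end
    dt = float(np.diff(np.unique(t))[0]) if t.nunique() > 1 else 0.0
    for w in (pre_window, post_window):
        if not (0 <= w[0] < w[1] <= tmax + dt + 1e-9):
            raise ValueError("summary windows must lie within the log")
    out = []
    for (grp, mode), sub in log[log["valid"]].groupby(["group", "controller"]):
        if sub.empty:
            continue
        err = (sub.groupby("t_min")
               .apply(lambda d: d["y"].mean() - d["target"].mean(),
                      include_groups=False))
        pop_sd = sub.groupby("t_min")["y"].std(ddof=1).mean()
        pre = sub[(sub.t_min >= pre_window[0]) & (sub.t_min < pre_window[1])]
        post = sub[(sub.t_min >= post_window[0]) & (sub.t_min < post_window[1])]
        pre_mean = pre["y"].mean()
        rel = (post.groupby("cell_id")["y"].mean() / pre_mean).to_numpy()
        q1, q2, q3 = (np.nanpercentile(rel, [25, 50, 75]) if rel.size
                      else (np.nan,) * 3)
        out.append((grp, mode, float(np.abs(err).mean()), float(pop_sd),
                    q1, q2, q3, rel))
    return pd.DataFrame(out, columns=["group", "controller", "mean_abs_error",
                                      "population_sd", "rel_q1", "rel_median",
                                      "rel_q3", "rel_perturbation"])
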