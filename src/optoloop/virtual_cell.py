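"""Stochastic virtual cells with light-switchable gene expression.

Each virtual cell stands in for one *E. coli* mother cell trapped in a
mother-machine channel, carrying a CcaSR-style optogenetic module: green
light (input ``u = 1``) activates and red light (``u = 0``) deactivates
transcription of a fluorescent reporter.

The per-cell model has three state variables:

``H(t)``
    promoter/light activation in [0, 1]. Relaxes deterministically toward
    the applied input at rate ``k_H`` (minutes-scale photoswitching).
``E(t)``
    latent "responsiveness", the per-cell, time-varying gain linking light
    activation to protein production. An Ornstein--Uhlenbeck process with
    mean ``E_bar``, relaxation time ``tau_E`` and stationary s.d.
    ``sigma_E``, reflected at 0.
``F(t)``
    reporter fluorescence (a.u.). Linear birth--death: production
    ``f0 + k_F * E * H``, dilution ``gamma * F``, with chemical-Langevin
    noise of intensity ``omega * (production + dilution)``, reflected at 0.

Cell length grows exponentially at rate ``gamma`` and halves at a noisy
division threshold; fluorescence is concentration-like (per-area image
intensity) and is therefore not halved at division.

The module also provides an exact discrete birth--death oracle
(:func:`ssa_oracle`) for cross-validating the Langevin simulator and the
moment equations, and a synthetic detection-region renderer producing the
image fixtures consumed by :mod:`optoloop.quantify`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

LN2 = math.log(2.0)

#: simulation sub-step (min); fine relative to the fastest timescale (k_H)
DEFAULT_DT_SUB = 0.1

#: measurement/control interval of the platform (min)
CONTROL_INTERVAL = 6.0


# ---------------------------------------------------------------------------
# parameter and state containers
# ---------------------------------------------------------------------------

@dataclass
class CellParams:
    """Kinetic parameters of one virtual cell.

    Defaults describe a fast-growing cell (25-min doubling) whose
    full-induction steady state ``(f0 + k_F * E_bar) / gamma`` is ~27.6 a.u.,
    leaving headroom above the 10--20 a.u. targets used in control
    experiments; the dark steady state ``f0 / gamma`` is ~0.54 a.u.
    """

    k_H: float = LN2 / 3.0        # promoter switching rate (1/min)
    E_bar: float = 1.0            # mean responsiveness (a.u.)
    tau_E: float = 240.0          # responsiveness relaxation time (min)
    sigma_E: float = 0.3          # stationary s.d. of responsiveness (a.u.)
    k_F: float = 0.75             # production gain (a.u./min per unit E at H=1)
    f0: float = 0.015             # leak production (a.u./min)
    gamma: float = LN2 / 25.0     # dilution/growth rate (1/min)
    omega: float = 0.2            # intensity per molecule (a.u.); shot-noise scale
    sigma_m: float = 0.5          # measurement noise s.d. (a.u.)
    L0: float = 2.5               # birth length (um)
    div_noise: float = 0.05       # multiplicative s.d. of division threshold

    def __post_init__(self) -> None:
        for name in ("k_H", "E_bar", "tau_E", "k_F", "gamma", "L0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CellParams.{name} must be strictly positive")
        for name in ("f0", "sigma_E", "omega", "sigma_m", "div_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"CellParams.{name} must be non-negative")


@dataclass
class CellState:
    """Instantaneous state of one virtual mother cell."""

    H: float = 0.0
    E: float = 1.0
    F: float = 0.0
    length: float = 2.5           # um
    t: float = 0.0                # min
    alive: bool = True
    div_thresh: float | None = None   # next division length; drawn lazily

    def __post_init__(self) -> None:
        if not (0.0 <= self.H <= 1.0):
            raise ValueError("H must lie in [0, 1]")
        if self.E < 0 or self.F < 0 or self.length <= 0:
            raise ValueError("E, F must be >= 0 and length > 0")


@dataclass
class PopulationSpec:
    """Specification of a heterogeneous population.

    Per-cell mean responsiveness ``E_bar`` is drawn from a log-normal with
    log-space location/scale ``(ebar_location, ebar_scale)``; scale 0 gives
    identical cells. :meth:`from_mean_cv` converts a desired mean and
    coefficient of variation into these parameters.
    """

    n_cells: int
    params: CellParams = field(default_factory=CellParams)
    ebar_location: float | None = None   # log-space mean; default: ln(template E_bar)
    ebar_scale: float = 0.0              # log-space s.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.ebar_scale < 0:
            raise ValueError("ebar_scale must be >= 0")
        if self.ebar_location is None:
            self.ebar_location = math.log(self.params.E_bar)

    @classmethod
    def from_mean_cv(cls, n_cells: int, mean: float, cv: float,
                     params: CellParams | None = None, seed: int = 0,
                     ) -> "PopulationSpec":
        """Log-normal E_bar distribution with given mean and CV."""
        if mean <= 0 or cv < 0:
            raise ValueError("mean must be > 0 and cv >= 0")
        s2 = math.log(1.0 + cv ** 2)
        loc = math.log(mean) - 0.5 * s2
        params = params if params is not None else CellParams(E_bar=mean)
        return cls(n_cells=n_cells, params=params,
                   ebar_location=loc, ebar_scale=math.sqrt(s2), seed=seed)


@dataclass
class PerturbationEvent:
    """A media-switch perturbation (doxycycline-style).

    Growth slows by ``gamma_factor`` as soon as the new media reaches the
    cell (transport lag, 1--10 min by default); the expression effect is a
    delayed rise of mean responsiveness toward ``resp_factor * E_bar``
    starting ``resp_delay`` minutes later with ramp time ``resp_tau``.
    """

    t_switch: float
    gamma_factor: float = 0.7
    resp_factor: float = 1.5
    resp_delay: float = 300.0
    resp_tau: float = 300.0
    transport_lag_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.gamma_factor <= 0 or self.resp_factor <= 0:
            raise ValueError("gamma_factor and resp_factor must be > 0")
        lo, hi = self.transport_lag_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid transport lag range")

    def sample_lag(self, rng: np.random.Generator) -> float:
        lo, hi = self.transport_lag_range
        return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def init_population(spec: PopulationSpec) -> list[tuple[CellParams, CellState]]:
    """Draw a population of cells per the spec.

    Per-cell ``E_bar`` (and proportionally ``sigma_E``) is log-normal;
    initial state has H = 0, E at the cell's own mean, F at the dark steady
    state ``f0 / gamma``, and a uniformly random phase of the cell cycle.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    ebars = np.exp(spec.ebar_location + spec.ebar_scale
                   * rng.standard_normal(spec.n_cells))
    lengths = p.L0 * np.exp(rng.uniform(0.0, LN2, spec.n_cells))
    out: list[tuple[CellParams, CellState]] = []
    rel_sig = p.sigma_E / p.E_bar
    for eb, ln in zip(ebars, lengths):
        cp = replace(p, E_bar=float(eb), sigma_E=float(rel_sig * eb))
        st = CellState(H=0.0, E=float(eb), F=p.f0 / p.gamma,
                       length=float(ln), t=0.0)
        out.append((cp, st))
    return out


# ---------------------------------------------------------------------------
# vectorized dynamics kernel
# ---------------------------------------------------------------------------

class PopulationState:
    """Struct-of-arrays population state for the vectorized kernel.

    Mirrors a list of :class:`CellState`, plus per-cell kinetic arrays for
    the parameters that vary across cells or in time (E_bar, sigma_E, gamma).
    """

    __slots__ = ("H", "E", "F", "length", "div_thresh", "alive", "t",
                 "E_bar", "sigma_E", "gamma")

    def __init__(self, cells: list[tuple[CellParams, CellState]]):
        n = len(cells)
        self.H = np.array([s.H for _, s in cells], float)
        self.E = np.array([s.E for _, s in cells], float)
        self.F = np.array([s.F for _, s in cells], float)
        self.length = np.array([s.length for _, s in cells], float)
        self.alive = np.ones(n, bool)
        self.t = float(cells[0][1].t) if n else 0.0
        self.E_bar = np.array([p.E_bar for p, _ in cells], float)
        self.sigma_E = np.array([p.sigma_E for p, _ in cells], float)
        self.gamma = np.array([p.gamma for p, _ in cells], float)
        self.div_thresh = np.full(n, np.nan)
        for i, (p, s) in enumerate(cells):
            self.div_thresh[i] = (s.div_thresh if s.div_thresh is not None
                                  else 2.0 * p.L0)

    def __len__(self) -> int:
        return self.H.size


def _draw_div_thresholds(L0, div_noise, rng, size):
    return 2.0 * L0 * (1.0 + div_noise * rng.standard_normal(size))


def step_population(pop: PopulationState, params: CellParams,
                    u: np.ndarray, dt: float, rng: np.random.Generator,
                    dt_sub: float = DEFAULT_DT_SUB) -> None:
    """Advance all cells by ``dt`` minutes under binary inputs ``u`` (in place).

    Shared kinetics (k_H, k_F, f0, omega, division geometry) come from the
    template ``params``; per-cell E_bar, sigma_E and gamma live on ``pop``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u, float)
    if np.any((u != 0.0) & (u != 1.0)):
        raise ValueError("stimulus must be binary (0 = red, 1 = green)")
    n_sub = max(1, int(round(dt / dt_sub)))
    h = dt / n_sub
    a_E = math.exp(-h / params.tau_E)
    ou_sd = pop.sigma_E * math.sqrt(1.0 - a_E * a_E)
    decay_H = math.exp(-params.k_H * h)
    # substep-averaged relaxation weight for H (exact integral of H over h)
    w_H = (1.0 - decay_H) / (params.k_H * h)
    decay_F = np.exp(-pop.gamma * h)
    for _ in range(n_sub):
        # production frozen per substep at the substep-average H and start E
        H_avg = u + (pop.H - u) * w_H
        prod = params.f0 + params.k_F * pop.E * H_avg
        # F: exponential (exact-drift) integrator on the chemical Langevin
        # equation, diffusion frozen over the substep, reflected at 0
        dil = pop.gamma * pop.F
        noise = np.sqrt(params.omega * (prod + dil) * h)
        pop.F = np.abs(pop.F * decay_F + prod * (1.0 - decay_F) / pop.gamma
                       + noise * rng.standard_normal(len(pop)))
        # H: exact exponential relaxation toward u
        pop.H = u + (pop.H - u) * decay_H
        # E: exact OU transition, reflected at 0
        pop.E = np.abs(pop.E_bar + (pop.E - pop.E_bar) * a_E
                       + ou_sd * rng.standard_normal(len(pop)))
        # length: exponential elongation with noisy-threshold division
        pop.length = pop.length * np.exp(pop.gamma * h)
        div = pop.length >= pop.div_thresh
        if np.any(div):
            pop.length[div] *= 0.5
            pop.div_thresh[div] = _draw_div_thresholds(
                params.L0, params.div_noise, rng, int(div.sum()))
    pop.t += dt


def step_cell(state: CellState, params: CellParams, u: int, dt: float,
              rng: np.random.Generator,
              dt_sub: float = DEFAULT_DT_SUB) -> CellState:
    """Advance a single cell by ``dt`` minutes under binary input ``u``."""
    if u not in (0, 1):
        raise ValueError("stimulus must be 0 (red) or 1 (green)")
    pop = PopulationState([(params, state)])
    step_population(pop, params, np.array([float(u)]), dt, rng, dt_sub)
    return CellState(H=float(pop.H[0]), E=float(pop.E[0]), F=float(pop.F[0]),
                     length=float(pop.length[0]), t=state.t + dt,
                     alive=state.alive, div_thresh=float(pop.div_thresh[0]))


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure(state: CellState, params: CellParams,
            rng: np.random.Generator) -> float:
    """Measured fluorescence: F plus Gaussian noise of s.d. sigma_m, >= 0."""
    if not state.alive:
        raise ValueError("cannot measure a dead cell")
    y = state.F + params.sigma_m * rng.standard_normal()
    return max(0.0, float(y))


def measure_population(F: np.ndarray, sigma_m: float,
                       rng: np.random.Generator) -> np.ndarray:
    return np.maximum(0.0, F + sigma_m * rng.standard_normal(F.shape))


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(params: CellParams, event: PerturbationEvent,
                       t: float, lag: float = 0.0) -> CellParams:
    """Parameters in effect at time ``t`` given a media-switch event.

    Always maps *baseline* params to perturbed params, so repeated queries at
    the same time are idempotent. ``lag`` is the cell's media transport lag,
    sampled once per cell via :meth:`PerturbationEvent.sample_lag`.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    t_eff = event.t_switch + lag
    if t < t_eff:
        return params
    gamma = params.gamma * event.gamma_factor
    ramp_t = max(0.0, t - t_eff - event.resp_delay)
    factor = 1.0 + (event.resp_factor - 1.0) * (1.0 - math.exp(-ramp_t / event.resp_tau))
    return replace(params, gamma=gamma, E_bar=params.E_bar * factor,
                   sigma_E=params.sigma_E * factor)


# ---------------------------------------------------------------------------
# exact birth-death oracle
# ---------------------------------------------------------------------------

def ssa_oracle(params: CellParams, stimulus: np.ndarray, n_reps: int,
               seed: int, interval: float = CONTROL_INTERVAL,
               dt_sub: float = DEFAULT_DT_SUB,
               F0: float | None = None):
    """Exact discrete birth--death ensemble of F, for cross-validation.

    Molecule count ``n = F / omega`` follows an immigration--death process
    with birth rate ``(f0 + k_F*E*H)/omega`` and per-molecule death rate
    ``gamma``; E and H are frozen over substeps <= ``dt_sub``. For constant
    rates over a substep the exact transition is
    ``Binomial(n, exp(-gamma h)) + Poisson(birth/gamma * (1 - exp(-gamma h)))``,
    applied here per substep and vectorized over replicates.

    Returns ``(t_grid, mean_F, var_F)`` sampled at interval boundaries
    (including t = 0).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a meaningful ensemble")
    if params.omega <= 0:
        raise ValueError("omega must be > 0 to define molecule counts")
    rng = np.random.default_rng(seed)
    stimulus = np.asarray(stimulus, float)
    n_sub = max(1, int(round(interval / dt_sub)))
    h = interval / n_sub
    surv = math.exp(-params.gamma * h)
    a_E = math.exp(-h / params.tau_E)
    ou_sd = params.sigma_E * math.sqrt(1.0 - a_E * a_E)
    F_init = params.f0 / params.gamma if F0 is None else F0
    n_mol = np.full(n_reps, int(round(F_init / params.omega)), dtype=np.int64)
    E = np.full(n_reps, params.E_bar)
    H = 0.0
    t_grid = [0.0]
    means = [n_mol.mean() * params.omega]
    var = [n_mol.var(ddof=1) * params.omega ** 2]
    decay_H = math.exp(-params.k_H * h)
    w_H = (1.0 - decay_H) / (params.k_H * h)
    for k, u in enumerate(stimulus):
        for _ in range(n_sub):
            H_avg = u + (H - u) * w_H       # substep-average light activation
            birth = (params.f0 + params.k_F * E * H_avg) / params.omega
            n_mol = (rng.binomial(n_mol, surv)
                     + rng.poisson(birth / params.gamma * (1.0 - surv)))
            H = u + (H - u) * decay_H
            E = np.abs(params.E_bar + (E - params.E_bar) * a_E
                       + ou_sd * rng.standard_normal(n_reps))
        t_grid.append((k + 1) * interval)
        means.append(n_mol.mean() * params.omega)
        var.append(n_mol.var(ddof=1) * params.omega ** 2)
    return np.array(t_grid), np.array(means), np.array(var)


# ---------------------------------------------------------------------------
# synthetic detection-region renderer
# ---------------------------------------------------------------------------

#: foreground pixel count; exactly twice the 96 pixels above the 97th
#: percentile of a 40x80 box, so the extracted rank sits at the foreground
#: median and the readout is calibrated to state.F
_FG_PIXELS = 192


def render_detection_region(state: CellState, shape: tuple[int, int] = (80, 40),
                            rng: np.random.Generator | None = None,
                            background: float = 0.3, bg_noise: float = 0.05,
                            fg_noise_frac: float = 0.02):
    """Synthetic detection-region image whose 97th-percentile readout is F.

    ``shape`` is (height, width) in pixels (default 80 x 40 = 3200 pixels).
    The cell appears as a vertical strip of ``_FG_PIXELS`` bright pixels at
    intensity ``state.F`` (multiplicative noise ``fg_noise_frac``); since the
    nearest-rank 97th percentile of the full box leaves 96 pixels above it,
    the readout sits at the foreground median = F. Returns ``(image, F)``.
    """
    h, w = shape
    if h <= 0 or w <= 0 or h * w < 2 * _FG_PIXELS:
        raise ValueError("degenerate detection-region geometry")
    rng = rng if rng is not None else np.random.default_rng()
    img = background + bg_noise * rng.standard_normal((h, w))
    np.maximum(img, 0.0, out=img)
    # vertical strip centred in the channel, mimicking the mother cell
    cols = max(2, int(round(_FG_PIXELS / min(h, 64))))
    rows = int(math.ceil(_FG_PIXELS / cols))
    r0 = (h - rows) // 2
    c0 = (w - cols) // 2
    strip = np.zeros((rows, cols), bool)
    strip.ravel()[:_FG_PIXELS] = True
    fg = state.F * (1.0 + fg_noise_frac * rng.standard_normal((rows, cols)))
    block = img[r0:r0 + rows, c0:c0 + cols]
    img[r0:r0 + rows, c0:c0 + cols] = np.where(strip, np.maximum(fg, 0.0), block)
    return img, state.F
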