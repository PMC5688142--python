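# Methods

`optoloop` is an in-silico rebuild of a measurement-and-control platform for
single bacteria: individual *E. coli* mother cells carrying a CcaSR-type
green/red light-switchable promoter are measured every six minutes and
steered by per-cell software controllers. Everything that was hardware in
the real platform (microscope, projector, microfluidics) is replaced by a
stochastic virtual-cell model; everything that was software (state
estimation, planning, digital circuits, quality control) is implemented as
it would run on the real loop. This note records the model, the defaults,
and the choices made where the design was genuinely open.

## Virtual-cell model

Each cell carries three state variables on a 6-min control grid with 0.1-min
sub-steps:

* **Light activation** `H(t) ∈ [0, 1]` — deterministic first-order
  relaxation toward the applied binary input `u` (green = 1, red = 0) at
  rate `k_H`. Default `k_H = ln2/3 min⁻¹`: photoswitching with a
  minutes-scale half-time. Light pulses are idealized as a constant binary
  input over each 6-min interval (the controller state can only change per
  interval, so sub-interval pulse shape is irrelevant to the loop).
* **Responsiveness** `E(t) ≥ 0` — the latent per-cell gain linking
  activation to protein production; an Ornstein–Uhlenbeck process with mean
  `E_bar`, relaxation time `tau_E = 240 min` and stationary s.d.
  `sigma_E = 0.3·E_bar`, reflected at 0. The hours-scale `tau_E` makes
  individual cells run above or below the population average for long
  stretches, which is the phenomenon individual-level feedback exists to
  correct. Population heterogeneity draws per-cell `E_bar` from a log-normal
  with CV 0.3 by default.
* **Fluorescence** `F(t) ≥ 0` (a.u.) — linear birth–death: production
  `f0 + k_F·E·H`, dilution `γ·F`, with chemical-Langevin noise of intensity
  `ω·(production + dilution)`, reflected at 0. Defaults `γ = ln2/25 min⁻¹`
  (fast LB-like growth), `ω = 0.2 a.u.` per molecule, `σ_m = 0.5 a.u.`
  measurement noise.

**Unit calibration.** Fluorescence units cannot be pinned to the original
instrument without real cells. `k_F = 0.75` and `f0 = 0.015 a.u.·min⁻¹` are
chosen so the full-induction steady state `(f0 + k_F·E_bar)/γ ≈ 27.6 a.u.`
sits comfortably above the largest control target used anywhere (20 a.u.)
and the dark state `f0/γ ≈ 0.54 a.u.` is a small leak. This single scale
choice fixes all emergent amplitudes.

**Integration.** `H` and `E` use their exact transition laws per sub-step;
`F` uses an exponential (exact-drift) integrator with the production
evaluated at the sub-step-average `H`, so ensemble means are free of
first-order time-discretization bias; diffusion is frozen per sub-step.
Halving the sub-step changes ensemble moments by well under 1%.

**Division.** Length grows exponentially at `γ` and halves at a threshold
`2·L0` with 5% multiplicative noise. `F` is concentration-like (per-area
image intensity), so division does not halve it.

**Perturbation (doxycycline-style).** A media switch reaching each cell
after a 1–10 min transport lag multiplies its growth rate by `gamma_factor`
(default 0.7, the ~30% slowdown) immediately, and ramps `E_bar` toward
`resp_factor × E_bar` (default 1.5) with a 300-min onset delay and 300-min
ramp constant — reproducing the observed ~300-min stable window before
open-loop trajectories diverge. `resp_factor` and the ramp constant are not
printed anywhere and are honest defaults.

## Moment equations and Kalman filtering

Given the input history, `H(t)` is known, and the first two moments of
`(E, F)` obey closed ODEs (`A(t)` lower-triangular-plus-coupling, OU and
Langevin noise intensities in `Q(t)`; see `moments_filter`). These are
integrated with an adaptive RK45 at `rtol 1e-8`. A standard linear-Gaussian
measurement update on the F component fuses each measurement; the E estimate
moves only through the E–F covariance. Because the only nonlinearity is the
mean-dependence of the Langevin noise intensity, the filter is exact for the
model when `ω = 0` and very nearly exact otherwise; calibration tests
(z-score variance within [0.7, 1.3], white innovations) quantify this.

Filter initialization: E at the population mean with prior variance
`σ_E²`, F at the first measurement with prior variance `σ_m²`. Means are
clamped at 0 after updates; the covariance is left untouched.

## Receding-horizon control

At each interval the planner enumerates all `2^N` binary light sequences
(default horizon `N = 8`, hard cap 12), propagates the predicted mean
fluorescence through each with a closed-form solution of the mean ODEs
(four-exponential forcing integrated exactly against the dilution decay),
and minimizes the summed squared deviation from the target at the N future
interval ends. The cost is certainty-equivalent (means only); a variance
penalty was deliberately left out since the objective is stated in terms of
expected levels. Exact cost ties resolve toward fewer green intervals
(minimal photostimulation), then lexicographically red-first, making plans
fully reproducible.

* **OL** precomputes the whole sequence against the nominal average-cell
  model, feeding the planner its own predictions in place of measurements,
  then broadcasts it without feedback.
* **pCL** updates one shared filter from the **mean** of valid, non-blocked
  cells and broadcasts one stimulus. The median was considered and rejected:
  on log-normal heterogeneity it systematically offsets the population mean
  from the target (the median of a skewed population lies below its mean),
  which defeats the one thing population-level feedback is supposed to fix.
  Robustness against runaway cells is instead provided by the blocking rule
  below, which is why that rule exists on the real platform.
* **iCL** runs one filter and one planner per cell.

## Hybrid bio-digital circuits

The delayed negative-feedback oscillator virtualizes the inhibitory species:
per 6-min interval `i`, `S ← S + r·y − d·S` from the measured fluorescence
`y` (defaults `r = 3`, `d = 0.2`), then optionally `S ← T·S` for an `n × n`
transfer matrix (clamped at 0 elementwise when clamping is on), then the
digital promoter `P` switches fully off iff `S > θ` (strict; default
`θ = 60`), and `P` is fed back as red/green light for the next interval.
Update order (local → transfer → threshold → stimulus) is fixed and
config-gated; permuting transfer and local update changes results and is
available as `transfer_first`.

Ring couplings on `n ≥ 3` cells, coupling fraction `f` (default 0.1):
`transfer` moves `f·S` to **each** neighbour (column-stochastic, diagonal
`1 − 2f`, conserves ΣS exactly); `inhibit` removes `f·S` from each
neighbour (diagonal 1); `asymmetric` adds `f·S` to the left and removes
`f·S` from the right neighbour (diagonal `1 − f`, keeping the positive
branch conservative — the removed portion is destroyed, not returned).
Reading "0.1·S transferred to the nearest neighbors" as 0.1 to each
neighbour (not 0.05 each) is a recorded choice.

With the default unit calibration the uncoupled oscillator runs with trough
≈ 2 a.u. and peak ≈ 9 a.u. — close to the reference amplitudes — but with a
period of ~75–80 min (spectral peak ≈ 0.012 min⁻¹) rather than ~200 min.
The period is set by the ratio of the expression range to the threshold
level; slowing it to 200 min would require a unit calibration that makes
the 20 a.u. control targets unreachable. The residual gap is what one
expects from omitting reporter maturation (tens of minutes for cyan
fluorescent proteins), a state the three-variable model deliberately does
not include. Coupling morphologies are insensitive to this: transfer
coupling locks neighbours in phase (median lag ≈ 0), inhibitory coupling
anti-phases a 4-ring (≈ 0.49 period), asymmetric coupling produces a
directed ≈ quarter-period gradient (≈ 0.24).

## Quantification and quality control

* **Fluorescence extraction** is the nearest-rank 97th percentile of the
  detection box (rank `⌈0.97·n⌉` of the ascending sort): for the default
  40 × 80 box this leaves exactly 96 pixels above the readout.
  Interpolating percentile conventions break that bookkeeping and are
  rejected. The synthetic region renderer paints a 192-pixel cell strip at
  intensity F, placing the extracted rank at the foreground median, so the
  readout is calibrated to the true F by construction.
* **Growth** is a centred moving average (window 5) of per-step
  `Δlog2(length)`, in doublings/h, excluding division steps
  (`Δlog2 ≤ −0.5`) and local outliers
  (`|rate − local median| > max(5·MAD, 0.5 doublings/h)`). The absolute
  floor exists because the MAD of a noise-free exponential window is
  exactly 0. All constants are configurable; none are printed in the
  reference description.
* **Invalidation** checks presence, growth, constitutive-reporter level and
  estimated responsiveness each interval; a rule failing for 3 consecutive
  intervals invalidates the cell permanently (absorbing), and post-hoc
  analysis truncates its record to 150 min before the violation.
* **Runaway blocking** removes a cell from the pCL population statistic
  (never from its own stimulus stream) when its measurement exceeds
  `median + 5·MAD` of the valid population, with an absolute cap when the
  MAD degenerates to 0. The exact platform rule is not public; this is a
  robust stand-in.

## Experiment loop

`run_experiment` executes measure → QC → estimate → plan → stimulate per
6-min interval; the measurement precedes the stimulus decision, and the
decided stimulus acts on the *following* interval. All randomness flows
from one seed through separate streams (dynamics, measurement, lags), so
logs replay byte-identically. The experiment loop synthesizes a constant
constitutive-reporter channel (10 a.u. plus measurement noise) purely so the
reporter QC rule has an input; virtual cells have no second reporter state.

Analytics: raw one-sided periodograms of mean-subtracted trajectories
(Parseval-exact; Welch averaging deliberately not used, for transparency),
averaged across cells with s.e.m.; expression peaks from a 5-point
edge-aware moving average, 20%-of-range prominence and quadratic sub-sample
refinement; phase lags from the cross-correlation maximum wrapped to
(−½, ½] periods; and windowed error summaries including the
relative-perturbation statistic (per-cell post-window mean over group
pre-window mean). The OL/iCL spectral crossover is located on 5-bin
smoothed averaged spectra — single periodogram bins are noisy even after
averaging over ~15 cells.

## Problem sizes

Defaults used by the test suite and the reproduction script: ensembles of
10⁴ replicates for simulator/moment cross-checks; 15–20 cells per
controller group; 12–30-h experiments; 20 seeded replicates for the
controller-taxonomy ordering; 3 replicate experiments averaged for the
spectral-crossover estimate; 10 seeds per coupling morphology. A 100-cell,
40-h individual-closed-loop experiment runs in well under 5 min on one CPU
core thanks to vectorization across cells and candidate light sequences.

## Known limitations

* No reporter maturation, transcription/translation delays, or mRNA layer;
  consequences discussed above.
* No spatial effects (channel geometry, diffusion, shading) and no real
  image segmentation — the renderer produces idealized detection regions.
* Controllers never re-estimate static kinetic parameters online; the
  nominal model is fixed, which is precisely what makes the perturbation
  experiments informative.
* The chemical-Langevin noise model is quantitative only at ≳100 molecules;
  the exact discrete oracle covers the low-count regime in tests.
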