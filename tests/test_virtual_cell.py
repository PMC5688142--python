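"""Virtual-cell model: closed forms, determinism, ensembles, perturbations."""

import math

import numpy as np
import pytest

from optoloop import (CellParams, CellState, FilterState, PerturbationEvent,
                      PopulationSpec, init_population, measure,
                      propagate_moments, render_detection_region, ssa_oracle,
                      step_cell, step_population)
from optoloop.quantify import extract_fluorescence
from optoloop.virtual_cell import PopulationState


class TestInitPopulation:
    def test_zero_scale_gives_identical_cells(self):
        spec = PopulationSpec(n_cells=8, ebar_scale=0.0, seed=1)
        cells = init_population(spec)
        ebars = {p.E_bar for p, _ in cells}
        assert ebars == {spec.params.E_bar}

    def test_same_seed_reproduces_population(self):
        spec = PopulationSpec.from_mean_cv(50, mean=1.0, cv=0.3, seed=9)
        a = init_population(spec)
        b = init_population(spec)
        for (pa, sa), (pb, sb) in zip(a, b):
            assert pa == pb and sa == sb

    def test_lognormal_cv_matches_request(self):
        # closed-form log-normal moments: sample CV within 3 s.e. of 0.3
        n, cv = 10_000, 0.3
        spec = PopulationSpec.from_mean_cv(n, mean=1.0, cv=cv, seed=4)
        ebars = np.array([p.E_bar for p, _ in init_population(spec)])
        sample_cv = ebars.std(ddof=1) / ebars.mean()
        # delta-method s.e. of the CV of a log-normal sample
        se = cv * math.sqrt((0.5 + cv ** 2) / n)
        assert abs(sample_cv - cv) < 3 * se

    def test_initial_state_at_dark_steady_state(self, params):
        cells = init_population(PopulationSpec(n_cells=3, seed=0))
        for p, s in cells:
            assert s.H == 0.0
            assert s.F == pytest.approx(params.f0 / params.gamma)
            assert s.E == pytest.approx(p.E_bar)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_cells=0)
        with pytest.raises(ValueError):
            PopulationSpec(n_cells=3, ebar_scale=-0.1)


class TestStepCell:
    def test_noiseless_decay_matches_closed_form(self, rng):
        p = CellParams(sigma_E=0.0, omega=0.0, sigma_m=0.0)
        st = CellState(H=0.0, E=p.E_bar, F=12.0)
        out = step_cell(st, p, 0, 6.0, rng)
        fss = p.f0 / p.gamma
        expect = fss + (12.0 - fss) * math.exp(-p.gamma * 6.0)
        assert out.F == pytest.approx(expect, rel=1e-9)

    def test_activation_follows_exponential(self, params, rng):
        st = CellState(H=0.0, E=params.E_bar, F=0.0)
        out = step_cell(st, params, 1, 9.0, rng)
        assert out.H == pytest.approx(1.0 - math.exp(-params.k_H * 9.0), rel=1e-9)

    def test_rejects_bad_inputs(self, params, dark_state, rng):
        with pytest.raises(ValueError):
            step_cell(dark_state, params, 2, 6.0, rng)
        with pytest.raises(ValueError):
            step_cell(dark_state, params, 1, -1.0, rng)

    def test_halving_substep_changes_moments_below_1pct(self, params):
        n = 3000
        means = {}
        for dt_sub in (0.1, 0.05):
            rng = np.random.default_rng(5)
            pop = PopulationState([(params, CellState(E=params.E_bar,
                                                      F=params.f0 / params.gamma))
                                   for _ in range(n)])
            for u in (1, 1, 0, 1):
                step_population(pop, params, np.full(n, float(u)), 6.0, rng,
                                dt_sub=dt_sub)
            means[dt_sub] = (pop.F.mean(), pop.F.var(ddof=1))
        m1, v1 = means[0.1]
        m2, v2 = means[0.05]
        assert abs(m1 - m2) / m2 < 0.01
        assert abs(v1 - v2) / v2 < 0.05   # variance needs more MC wiggle room

    def test_division_sawtooth_has_unit_log2_drops(self, params):
        rng = np.random.default_rng(3)
        st = CellState(E=params.E_bar, F=1.0, length=params.L0)
        lengths = []
        for _ in range(400):
            st = step_cell(st, params, 0, 6.0, rng)
            lengths.append(st.length)
        drops = np.diff(np.log2(lengths))
        div_drops = drops[drops < -0.5]
        assert div_drops.size > 5
        # sampled drop = exact halving (-1) plus one interval of regrowth,
        # jittered by the noisy division threshold
        expected = -1.0 + 6.0 * params.gamma / math.log(2)
        assert np.allclose(div_drops, expected, atol=0.15)
        # length never exceeds threshold after a step by more than one substep
        assert max(lengths) < 2 * params.L0 * (1 + 4 * params.div_noise)


class TestMeasure:
    def test_noiseless_measurement_is_exact(self, rng):
        p = CellParams(sigma_m=0.0)
        st = CellState(F=7.5, E=1.0)
        assert measure(st, p, rng) == 7.5

    def test_truncated_at_zero(self, rng):
        p = CellParams(sigma_m=5.0)
        st = CellState(F=0.0, E=1.0)
        assert all(measure(st, p, rng) >= 0.0 for _ in range(200))

    def test_dead_cell_rejected(self, params, rng):
        st = CellState(F=1.0, E=1.0, alive=False)
        with pytest.raises(ValueError):
            measure(st, params, rng)

    def test_noise_sd_calibrated(self, rng):
        p = CellParams(sigma_m=1.0)
        st = CellState(F=15.0, E=1.0)
        ys = np.array([measure(st, p, rng) for _ in range(20_000)])
        se = 1.0 / math.sqrt(2 * (ys.size - 1))
        assert abs(ys.std(ddof=1) - 1.0) < 3 * se


class TestPerturbation:
    def test_identity_before_switch(self, params):
        ev = PerturbationEvent(t_switch=600.0)
        assert ol_apply(params, ev, 300.0) == params

    def test_growth_step_is_exact_factor(self, params):
        # growth slows by exactly the configured ~30%
        ev = PerturbationEvent(t_switch=600.0, gamma_factor=0.7)
        out = ol_apply(params, ev, 5000.0)
        assert out.gamma == pytest.approx(0.7 * params.gamma)

    def test_responsiveness_ramp_starts_after_delay(self, params):
        # expression stays at baseline through the ~300-min stable period
        ev = PerturbationEvent(t_switch=600.0, resp_delay=300.0,
                               resp_factor=1.5)
        at_delay = ol_apply(params, ev, 900.0)
        assert at_delay.E_bar == pytest.approx(params.E_bar)
        late = ol_apply(params, ev, 600.0 + 300.0 + 10 * ev.resp_tau)
        assert late.E_bar == pytest.approx(1.5 * params.E_bar, rel=1e-3)

    def test_idempotent_per_time_query(self, params):
        ev = PerturbationEvent(t_switch=100.0)
        a = ol_apply(params, ev, 700.0)
        b = ol_apply(params, ev, 700.0)
        assert a == b


def ol_apply(params, ev, t):
    from optoloop import apply_perturbation
    return apply_perturbation(params, ev, t, lag=0.0)


class TestSSAOracle:
    def test_pure_death_closed_form(self):
        # all-red input with zero leak: H stays 0, so production is zero
        p = CellParams(f0=0.0, sigma_E=0.0, omega=0.5)
        F0 = 50.0
        n0 = round(F0 / p.omega)
        t, m, v = ssa_oracle(p, np.zeros(5), n_reps=20_000, seed=2, F0=F0)
        for k in (1, 3, 5):
            surv = math.exp(-p.gamma * t[k])
            em = n0 * surv * p.omega
            ev = n0 * surv * (1 - surv) * p.omega ** 2
            se_m = math.sqrt(ev / 20_000)
            assert abs(m[k] - em) < 3 * se_m
            assert abs(v[k] - ev) < 4 * ev * math.sqrt(2 / 20_000)

    def test_stationary_mean_is_production_over_gamma(self):
        p = CellParams(sigma_E=0.0, omega=0.2)
        # hold green long enough to equilibrate
        t, m, v = ssa_oracle(p, np.ones(40), n_reps=5000, seed=3)
        target = (p.f0 + p.k_F * p.E_bar) / p.gamma
        assert m[-1] == pytest.approx(target, rel=0.02)

    def test_small_ensemble_flagged(self, params):
        with pytest.raises(ValueError):
            ssa_oracle(params, np.ones(3), n_reps=10, seed=0)

    def test_agrees_with_langevin_ensemble(self):
        # cross-simulator check at >= 100 molecules
        p = CellParams(omega=0.05)
        rng = np.random.default_rng(21)
        sched = np.array([1, 1, 0, 1, 0, 0, 1, 1], float)
        n = 6000
        t, m_ssa, v_ssa = ssa_oracle(p, sched, n_reps=n, seed=22)
        pop = PopulationState([(p, CellState(E=p.E_bar, F=p.f0 / p.gamma))
                               for _ in range(n)])
        for k, u in enumerate(sched):
            step_population(pop, p, np.full(n, u), 6.0, rng)
            se = math.sqrt((v_ssa[k + 1] + pop.F.var(ddof=1)) / n)
            assert abs(m_ssa[k + 1] - pop.F.mean()) < 3.5 * se


class TestMomentClosure:
    def test_ensemble_matches_moment_odes(self, params):
        """Langevin ensemble mean/variance vs the moment equations, over a
        random piecewise-constant stimulus schedule."""
        rng = np.random.default_rng(31)
        sched = rng.integers(0, 2, 12).astype(float)
        n = 10_000
        pop = PopulationState([(params, CellState(E=params.E_bar,
                                                  F=params.f0 / params.gamma))
                               for _ in range(n)])
        pop.E = np.abs(params.E_bar
                       + params.sigma_E * rng.standard_normal(n))
        fs = FilterState(mean=[params.E_bar, params.f0 / params.gamma],
                         cov=np.diag([params.sigma_E ** 2, 0.0]))
        for u in sched:
            step_population(pop, params, np.full(n, u), 6.0, rng)
            fs = propagate_moments(fs, int(u), 6.0, params)
            mF, vF = pop.F.mean(), pop.F.var(ddof=1)
            assert abs(mF - fs.mean[1]) < 3.5 * math.sqrt(vF / n)
            assert abs(vF - fs.cov[1, 1]) < 3.5 * vF * math.sqrt(2 / (n - 1))

    def test_stationary_full_induction_mean(self, params):
        # long-run mean F under constant green -> (f0 + k_F E_bar)/gamma
        rng = np.random.default_rng(41)
        n = 4000
        pop = PopulationState([(params, CellState(E=params.E_bar,
                                                  F=params.f0 / params.gamma))
                               for _ in range(n)])
        pop.E = np.abs(params.E_bar + params.sigma_E * rng.standard_normal(n))
        for _ in range(40):
            step_population(pop, params, np.ones(n), 6.0, rng)
        target = (params.f0 + params.k_F * params.E_bar) / params.gamma
        assert pop.F.mean() == pytest.approx(target, rel=0.02)


class TestRenderDetectionRegion:
    def test_box_has_3200_pixels(self, rng):
        img, _ = render_detection_region(CellState(F=15.0, E=1.0), rng=rng)
        assert img.size == 3200 and img.shape == (80, 40)

    def test_constant_field_roundtrip(self):
        img = np.full((80, 40), 4.2)
        assert extract_fluorescence(img) == 4.2

    def test_readout_calibrated_to_truth(self, rng):
        vals = [extract_fluorescence(render_detection_region(
            CellState(F=15.0, E=1.0), rng=rng)[0]) for _ in range(200)]
        assert abs(np.mean(vals) - 15.0) / 15.0 < 0.02

    def test_degenerate_geometry_rejected(self, rng):
        with pytest.raises(ValueError):
            render_detection_region(CellState(F=1.0, E=1.0), shape=(2, 2),
                                    rng=rng)
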