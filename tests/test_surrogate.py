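"""Fokker-Planck surrogate: drift/diffusion forms, companion ODEs, the
reference solver, empirical p.d.f. construction, and the physics-informed
fit."""

import numpy as np
import pytest
from dataclasses import replace

from gliomarl.schedules import make_schedule
from gliomarl.surrogate import (FPSolver, HybridState, PinnSpec, Surrogate,
                                SurrogateParams, build_training_pdf,
                                euler_maruyama_ensemble, fp_diffusion,
                                fp_drift, gaussian_p0, hybrid_ode_step,
                                hybrid_trajectory, r_eff, solve_fp_reference,
                                surrogate_predict, train_pinn)


class TestDriftDiffusion:
    def test_extinction_is_a_fixed_point(self, surrogate_params):
        assert fp_drift(0.0, 0.0, surrogate_params, c_m1=0.4) == 0.0

    def test_pure_death_at_capacity(self, surrogate_params):
        p = surrogate_params
        mu = fp_drift(1.0, 0.0, p, c_m1=0.4)
        expected = -p.k2 * p.d_tc * (1 + p.k8 * p.d_tcm1 * 0.4)
        assert np.isclose(mu, expected)

    def test_drift_matches_symbolic_expression(self):
        """Sweep against an independent sympy evaluation of the printed
        drift and diffusion forms."""
        sympy = pytest.importorskip("sympy")
        k1, k2, k8, r, d, dm1, cm1, c, sig = sympy.symbols(
            "k1 k2 k8 r d dm1 cm1 c sig", positive=True)
        mu_expr = k1 * r * c * (1 - c) - k2 * d * (1 + k8 * dm1 * cm1) * c
        nu_expr = k2 * d * k8 * dm1 * cm1 * c * sig
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = dict(k1=rng.uniform(0.5, 2), k2=rng.uniform(0.5, 2),
                        k8=rng.uniform(0.5, 8), r=rng.uniform(0.05, 0.5),
                        d=rng.uniform(0.001, 0.05), dm1=rng.uniform(0.5, 5),
                        cm1=rng.uniform(0, 1), c=rng.uniform(0, 1),
                        sig=rng.uniform(0, 0.5))
            p = SurrogateParams(k1=vals["k1"], k2=vals["k2"], k8=vals["k8"],
                                r_tc=vals["r"], d_tc=vals["d"],
                                d_tcm1=vals["dm1"], sigma=vals["sig"])
            mu_ref = float(mu_expr.subs({k1: vals["k1"], k2: vals["k2"],
                                         k8: vals["k8"], r: vals["r"],
                                         d: vals["d"], dm1: vals["dm1"],
                                         cm1: vals["cm1"], c: vals["c"]}))
            nu_ref = float(nu_expr.subs({k2: vals["k2"], k8: vals["k8"],
                                         d: vals["d"], dm1: vals["dm1"],
                                         cm1: vals["cm1"], c: vals["c"],
                                         sig: vals["sig"]}))
            assert np.isclose(fp_drift(vals["c"], 0, p, vals["cm1"]), mu_ref)
            assert np.isclose(fp_diffusion(vals["c"], 0, p, vals["cm1"]),
                              abs(nu_ref))

    def test_zero_noise_or_zero_m1_kills_diffusion(self, surrogate_params):
        p0 = replace(surrogate_params, sigma=0.0)
        assert fp_diffusion(0.5, 0, p0, c_m1=0.4) == 0.0
        assert fp_diffusion(0.5, 0, surrogate_params, c_m1=0.0) == 0.0


class TestHybridODEs:
    def test_zero_dose_zero_initial_stays_zero(self, surrogate_params):
        h = HybridState(c_m1=surrogate_params.m1_0)
        for _ in range(100):
            h = hybrid_ode_step(h, surrogate_params, 0.0, 0.0, 0.1)
        assert h.d_csf1ri == 0.0
        assert h.exposure == 0.0

    def test_constant_dose_converges_to_linear_ode_equilibrium(self,
                                                               surrogate_params):
        """d(drug)/dt = k (dose - drug): the closed-form fixed point is the
        dose itself, approached exponentially at rate k."""
        p = surrogate_params
        sched = make_schedule("continuous", 100, drug="CSF1R_I", dose=0.7)
        t = np.linspace(0, 60, 61)
        hyb = hybrid_trajectory(p, sched, t)
        assert abs(hyb["d_csf1ri"][-1] - 0.7) < 1e-3
        # half-way point matches exp relaxation
        analytic = 0.7 * (1 - np.exp(-p.k_drug * t))
        assert np.max(np.abs(hyb["d_csf1ri"] - analytic)) < 0.02

    def test_m1_rises_under_drug_and_reverts_with_resistance(self,
                                                             surrogate_params):
        sched = make_schedule("continuous", 300, drug="CSF1R_I", dose=1.0)
        t = np.linspace(0, 200, 201)
        hyb = hybrid_trajectory(surrogate_params, sched, t)
        m1 = hyb["c_m1"]
        assert m1.max() > 2 * surrogate_params.m1_0
        assert m1[-1] < 0.8 * m1.max()      # acquired resistance reverts M1

    def test_igf1ri_blocks_resistant_growth(self, surrogate_params):
        h = HybridState(exposure=200.0, c_m1=0.2)
        h_blocked = HybridState(exposure=200.0, c_m1=0.2, d_igf1ri=1.0)
        assert r_eff(surrogate_params, h_blocked) < r_eff(surrogate_params, h)


class TestReferenceSolver:
    def test_probability_bookkeeping_exact(self, surrogate_params):
        solver = FPSolver(surrogate_params, nc=72)
        sched = make_schedule("continuous", 200, drug="CSF1R_I", dose=1.0)
        grid = solver.run(gaussian_p0(solver.c), sched, np.linspace(0, 100, 51))
        assert grid.check_normalization(1e-6)
        assert np.all(np.diff(grid.absorbed) >= -1e-12)
        assert np.all(np.diff(grid.cured) >= -1e-12)

    def test_zero_noise_transport_follows_logistic_characteristics(self):
        """With nu = 0 the density rides the characteristics of the scalar
        ODE dc/dt = mu(c); the mode matches the ODE solution closely."""
        p = SurrogateParams(sigma=0.0, d_tc=0.0)   # pure logistic drift
        solver = FPSolver(p, nc=360, dt=0.02)
        P0 = gaussian_p0(solver.c, mean=0.2, sd=0.02)
        t_end = 5.0
        grid = solver.run(P0, make_schedule("none", 50),
                          np.array([0.0, t_end]))
        mode = solver.c[np.argmax(grid.P[-1])]
        # logistic solution c(t) = c0 e^{rt} / (1 + c0 (e^{rt} - 1))
        r = p.k1 * p.r_tc
        c0 = 0.2
        expected = c0 * np.exp(r * t_end) / (1 + c0 * (np.exp(r * t_end) - 1))
        assert abs(mode - expected) / expected < 0.01

    def test_constant_coefficients_diffuse_like_brownian_motion(self):
        """With mu = 0 and constant nu the variance grows as nu*t before
        boundary contact (override hooks isolate the kernel)."""
        nu0 = 2e-4
        p = SurrogateParams()
        solver = FPSolver(p, nc=200, dt=0.05,
                          drift=lambda c, t, pp, cm1, r=None: np.zeros_like(
                              np.asarray(c, dtype=float)),
                          diffusion=lambda c, t, pp, cm1: np.full_like(
                              np.asarray(c, dtype=float), nu0))
        P0 = gaussian_p0(solver.c, mean=0.45, sd=0.02)
        t_end = 20.0
        grid = solver.run(P0, make_schedule("none", 50), np.array([0, t_end]))
        P = grid.P[-1]
        m = np.sum(P * solver.c) * solver.dc
        var = np.sum(P * (solver.c - m) ** 2) * solver.dc
        assert np.isclose(var, 0.02 ** 2 + nu0 * t_end, rtol=0.05)

    def test_em_ensemble_matches_fp_solution(self, surrogate_params):
        """Total-variation distance between the Euler-Maruyama ensemble and
        the Fokker-Planck solution (live + dead + cured) is below 0.05."""
        sched = make_schedule("continuous", 200, drug="CSF1R_I", dose=1.0)
        solver = FPSolver(surrogate_params, nc=90)
        t_eval = 40.0
        grid = solver.run(gaussian_p0(solver.c), sched, np.array([0, t_eval]))
        n_paths = 10000
        paths, death = euler_maruyama_ensemble(
            surrogate_params, sched, np.array([0.0, t_eval]), n_paths,
            seed=1, dt=0.02)
        alive = np.isfinite(paths[:, 1])
        hist, _ = np.histogram(paths[alive, 1], bins=solver.c_faces)
        em_pdf = hist / (n_paths * solver.dc)
        em_dead = (death <= t_eval).mean()
        em_cured = 1 - alive.mean() - em_dead
        tv = 0.5 * np.sum(np.abs(em_pdf - grid.P[1])) * solver.dc \
            + 0.5 * abs(em_dead - grid.absorbed[1]) \
            + 0.5 * abs(em_cured - grid.cured[1])
        assert tv < 0.05


class TestEmpiricalPdf:
    def test_identical_individuals_concentrate_in_one_spike(self):
        X = np.full((10, 5), 0.4)
        pdf = build_training_pdf(X, np.arange(5.0))
        peak = pdf.c[np.argmax(pdf.P[2])]
        assert abs(peak - 0.4) < 0.02
        assert pdf.check_normalization(1e-6)

    def test_normalization_includes_dead_mass(self):
        X = np.vstack([np.linspace(0.5, 0.95, 8)] * 6)   # all eventually cross
        pdf = build_training_pdf(X, np.arange(8.0))
        assert pdf.check_normalization(1e-6)
        assert pdf.absorbed[-1] == 1.0

    def test_recovers_known_gaussian_population(self, rng):
        X = rng.normal(0.45, 0.06, size=(400, 3)).clip(0.06, 0.85)
        pdf = build_training_pdf(X, np.arange(3.0))
        m = np.sum(pdf.P[1] * pdf.c) * pdf.dc
        sd = np.sqrt(np.sum(pdf.P[1] * (pdf.c - m) ** 2) * pdf.dc)
        assert abs(m - 0.45) < 0.01
        assert abs(sd - 0.06) < 0.015


@pytest.fixture(scope="module")
def quick_fit(surrogate_params):
    sched = make_schedule("continuous", 196, drug="CSF1R_I", dose=1.0)
    solver = FPSolver(surrogate_params, nc=72)
    t = np.linspace(0, 196, 99)
    ref = solver.run(gaussian_p0(solver.c), sched, t)
    spec = PinnSpec(n_iter=150, n_lbfgs=200, n_data=1200, n_colloc=1200,
                    lr=3e-3, seed=0)
    sur = train_pinn(ref, sched, surrogate_params, spec)
    return ref, sur, t


class TestPinnFit:
    def test_data_loss_decreases(self, quick_fit):
        _, sur, _ = quick_fit
        assert sur.losses[-1][0] < 0.05 * sur.losses[0][0]

    def test_physics_weight_zero_reduces_to_regression(self, surrogate_params):
        sched = make_schedule("none", 196)
        solver = FPSolver(surrogate_params, nc=48)
        ref = solver.run(gaussian_p0(solver.c), sched, np.linspace(0, 50, 26))
        spec = PinnSpec(n_iter=100, n_lbfgs=50, n_data=600, n_colloc=200,
                        physics_weight=0.0, seed=1)
        sur = train_pinn(ref, sched, surrogate_params, spec, train_sigma=False)
        assert np.all(sur.losses[:, 1] >= 0)
        assert sur.losses[-1][0] < sur.losses[0][0]

    def test_sigma_recovery_within_twenty_percent(self, surrogate_params):
        """Simulation-based identifiability: refitting on data generated at
        a known noise amplitude recovers it within 20%."""
        true_sigma = 0.2
        p = replace(surrogate_params, sigma=true_sigma)
        sched = make_schedule("continuous", 196, drug="CSF1R_I", dose=1.0)
        solver = FPSolver(p, nc=72)
        ref = solver.run(gaussian_p0(solver.c), sched, np.linspace(0, 196, 99))
        spec = PinnSpec(n_iter=100, n_lbfgs=100, n_data=800, n_colloc=800,
                        seed=0)
        sur = train_pinn(ref, sched, p, spec)
        assert abs(sur.sigma_fitted - true_sigma) / true_sigma < 0.2

    def test_training_is_seed_deterministic(self, surrogate_params):
        sched = make_schedule("none", 50)
        solver = FPSolver(surrogate_params, nc=48)
        ref = solver.run(gaussian_p0(solver.c), sched, np.linspace(0, 50, 26))
        spec = PinnSpec(n_iter=40, n_lbfgs=0, n_data=400, n_colloc=300, seed=3)
        a = train_pinn(ref, sched, surrogate_params, spec)
        b = train_pinn(ref, sched, surrogate_params, spec)
        assert np.array_equal(a.losses, b.losses)


class TestPrediction:
    def test_initial_slice_and_full_survival(self, surrogate_params):
        sur = Surrogate(params=surrogate_params)
        sched = make_schedule("switch", 98)
        grid, surv = surrogate_predict(sur, sched, np.linspace(0, 98, 15))
        assert surv[0] == 100.0
        # initial p.d.f. is the configured Gaussian
        assert abs(grid.c[np.argmax(grid.P[0])] - 0.58) < 0.02

    def test_survival_curve_nonincreasing(self, surrogate_params):
        sur = Surrogate(params=surrogate_params)
        for kind in ("none", "switch", "preset:optimal_rl"):
            sched = make_schedule(kind, 196)
            _, surv = surrogate_predict(sur, sched, np.linspace(0, 196, 29))
            assert np.all(np.diff(surv) <= 1e-9)
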