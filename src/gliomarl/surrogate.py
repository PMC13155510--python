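"""Fokker-Planck surrogate of population tumor-cell-density dynamics.

The agent-based cohort is reduced to a scalar SDE for the normalized TC
density C(t):

    dC = mu(t, C) dt + sqrt(nu(t, C)) dW

    mu(t, C) = k1 r_eff(t) C (1 - C) - k2 d_TC (1 + k8 d_TCM1 C_M1(t)) C
    nu(t, C) = k2 d_TC k8 d_TCM1 C_M1(t) C sigma

with the M1-density mean C_M1(t), the mean drug concentrations, and the
acquired-resistance state driven by a small companion ODE system (the
"hybrid" part).  The Fokker-Planck equation for the population p.d.f.
P(t, c),

    dP/dt = -d/dc [mu P] + 1/2 d^2/dc^2 [nu P],

is solved on [0, Thr] with a reflecting boundary at 0 and an absorbing
boundary at the death threshold Thr = 0.896; the absorbed mass is the
cumulative death fraction, so percent survival is 100 * (1 - absorbed).
The printed diffusion coefficient carries a sign that depends on the noise
direction; the solver uses its magnitude, as a diffusion coefficient must
be nonnegative.

A physics-informed trainer fits a dense network u(t, c; theta) to empirical
(or reference) p.d.f. surfaces under the PDE residual constraint, with the
noise amplitude sigma* as a trainable physical parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.linalg import solve_banded

from ._mlp import MLP, Adam
from .analysis import THR
from .schedules import TreatmentSchedule

__all__ = [
    "SurrogateParams",
    "PdfGrid",
    "PinnSpec",
    "HybridState",
    "fp_drift",
    "fp_diffusion",
    "hybrid_ode_step",
    "hybrid_trajectory",
    "FPSolver",
    "solve_fp_reference",
    "gaussian_p0",
    "euler_maruyama_ensemble",
    "build_training_pdf",
    "Surrogate",
    "train_pinn",
    "surrogate_predict",
]


@dataclass
class SurrogateParams:
    """Reduced-model parameters (time unit: days).

    ``k1, k2, k8`` are the adjustment factors of the reduction; the products
    ``k1*r_tc`` (net growth) and ``k2*d_tc*(1 + k8*d_tcm1*C_M1)`` (net
    death) are what the dynamics see.  Defaults are calibrated so that the
    reduced model reproduces the cohort-level outcomes of the agent-based
    simulator: untreated tumors cross the death threshold within ~3 weeks,
    continuous CSF1R inhibition cures a minority and fails by acquired
    resistance in the rest, and the inhibitor combination keeps the
    population alive.
    """

    k1: float = 1.0
    k2: float = 1.0
    k8: float = 8.0
    r_tc: float = 0.4            # effective logistic growth rate, 1/day
    d_tc: float = 0.005          # basal death rate, 1/day
    d_tcm1: float = 5.0          # M1-mediated kill coefficient
    sigma: float = 0.08          # noise amplitude sigma_TC
    # hybrid ODEs ----------------------------------------------------------
    k_drug: float = 1.0          # drug equilibration rate, 1/day
    p12: float = 0.26            # M1->M2 polarization rate at tumor CSF1, 1/day
    p21: float = 0.048           # M2->M1 basal repolarization rate, 1/day
    km12d: float = 1.1           # drug responsiveness of polarization
    k_res: float = 6.0e-4        # resistance accumulation rate, 1/(day*conc)
    x_half: float = 25.0         # exposure half-saturation of AKT activation
    g_res: float = 8.0           # max growth amplification by resistant AKT
    k_igf1ri: float = 30.0       # IGF1R_I potency against resistant AKT
    g_base: float = 0.15         # baseline growth reduction by IGF1R_I
    g_m1: float = 12.0           # growth suppression by M1 crowding at the rim
    m1_0: float = 0.156          # naive steady-state M1 density

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k8", "r_tc", "d_tc", "d_tcm1", "sigma",
                     "k_drug", "p12", "p21", "km12d", "k_res", "x_half",
                     "g_res", "k_igf1ri", "g_base", "g_m1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class HybridState:
    """Mean-field companion state: drugs, exposure, M1 density."""

    d_csf1ri: float = 0.0
    d_igf1ri: float = 0.0
    exposure: float = 0.0        # cumulative CSF1R_I exposure (conc*days)
    c_m1: float = 0.156

    def copy(self) -> "HybridState":
        return HybridState(self.d_csf1ri, self.d_igf1ri, self.exposure, self.c_m1)


def r_eff(params: SurrogateParams, h: HybridState) -> float:
    """Effective growth rate of the reduced model.

    Three mean-field influences mirror the agent-based mechanisms:
    resistance (AKT activated by cumulative CSF1R_I exposure, blocked by
    IGF1R_I) amplifies growth; IGF1R_I mildly suppresses baseline growth;
    excess M1 crowding at the tumor rim suppresses the refill of
    phagocytosed sites.
    """
    akt = h.exposure / (h.exposure + params.x_half) if params.x_half > 0 else 1.0
    akt /= (1.0 + params.k_igf1ri * h.d_igf1ri)
    base = 1.0 / (1.0 + params.g_base * h.d_igf1ri)
    crowd = np.exp(-params.g_m1 * max(0.0, h.c_m1 - params.m1_0))
    return params.r_tc * base * crowd * (1.0 + params.g_res * akt)


def fp_drift(c, t, params: SurrogateParams, c_m1, r_eff_t=None):
    """Drift mu(t, c) = k1 r C (1-C) - k2 d_TC (1 + k8 d_TCM1 C_M1) C."""
    c = np.asarray(c, dtype=float)
    r = params.r_tc if r_eff_t is None else r_eff_t
    growth = params.k1 * r * c * (1.0 - c)
    death = params.k2 * params.d_tc * (1.0 + params.k8 * params.d_tcm1 * c_m1) * c
    return growth - death


def fp_diffusion(c, t, params: SurrogateParams, c_m1):
    """Diffusion coefficient magnitude |nu| = k2 d_TC k8 d_TCM1 C_M1 C sigma."""
    c = np.asarray(c, dtype=float)
    return np.abs(params.k2 * params.d_tc * params.k8 * params.d_tcm1
                  * c_m1 * c * params.sigma)


def hybrid_ode_step(h: HybridState, params: SurrogateParams,
                    dose_csf1ri: float, dose_igf1ri: float,
                    dt: float) -> HybridState:
    """One explicit step of the companion mean-field ODEs.

    Drugs relax to the administered dose at rate k_drug; cumulative
    CSF1R_I exposure drives both M1 reversion and AKT-mediated growth
    amplification.
    """
    p = params
    h = h.copy()
    h.d_csf1ri += dt * p.k_drug * (dose_csf1ri - h.d_csf1ri)
    h.d_igf1ri += dt * p.k_drug * (dose_igf1ri - h.d_igf1ri)
    h.exposure += dt * h.d_csf1ri
    u = h.d_csf1ri
    gain = p.p21 * (1.0 + p.km12d * u)
    loss = p.p12 / (1.0 + p.km12d * u) + p.k_res * h.exposure
    h.c_m1 += dt * (gain * (1.0 - h.c_m1) - loss * h.c_m1)
    h.c_m1 = min(max(h.c_m1, 0.0), 1.0)
    return h


def hybrid_trajectory(params: SurrogateParams, schedule: TreatmentSchedule,
                      t_grid: np.ndarray, h0: HybridState | None = None):
    """Integrate the companion ODEs over ``t_grid`` (days).

    Returns dict of arrays: d_csf1ri, d_igf1ri, exposure, c_m1, r_eff.
    """
    h = HybridState(c_m1=params.m1_0) if h0 is None else h0.copy()
    out = {k: [] for k in ("d_csf1ri", "d_igf1ri", "exposure", "c_m1", "r_eff")}
    dt_max = 0.1                 # days; keeps the explicit step stable
    for i, t in enumerate(t_grid):
        out["d_csf1ri"].append(h.d_csf1ri)
        out["d_igf1ri"].append(h.d_igf1ri)
        out["exposure"].append(h.exposure)
        out["c_m1"].append(h.c_m1)
        out["r_eff"].append(r_eff(params, h))
        if i + 1 < len(t_grid):
            span = t_grid[i + 1] - t
            n_sub = max(1, int(np.ceil(span / dt_max)))
            dt = span / n_sub
            for j in range(n_sub):
                tt = t + j * dt
                h = hybrid_ode_step(h, params,
                                    schedule.dose("CSF1R_I", tt),
                                    schedule.dose("IGF1R_I", tt), dt)
    return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class PdfGrid:
    """P(t, c) on a [0, T] x [c_lo, Thr] mesh plus the boundary masses.

    ``absorbed`` is the cumulative death probability (mass that crossed the
    threshold Thr); ``cured`` the cumulative eradication probability (mass
    that reached the lower extinction boundary).  Percent survival is
    100 * (1 - absorbed): cured individuals stay alive.
    """

    t: np.ndarray                # (nt,) days
    c: np.ndarray                # (nc,) cell centers
    P: np.ndarray                # (nt, nc) density w.r.t. c
    absorbed: np.ndarray         # (nt,) cumulative death probability
    cured: np.ndarray | None = None   # (nt,) cumulative eradication probability

    def __post_init__(self) -> None:
        if self.cured is None:
            self.cured = np.zeros_like(self.absorbed)

    @property
    def dc(self) -> float:
        return float(self.c[1] - self.c[0])

    def live_mass(self) -> np.ndarray:
        return self.P.sum(axis=1) * self.dc

    def survival_percent(self) -> np.ndarray:
        return 100.0 * (1.0 - self.absorbed)

    def check_normalization(self, atol: float = 1e-6) -> bool:
        total = self.live_mass() + self.absorbed + self.cured
        return bool(np.all(np.abs(total - 1.0) < atol))


class FPSolver:
    """Conservative Chang-Cooper finite-volume solver on [c_lo, Thr].

    Implicit Euler in time (banded solve).  Both boundaries absorb: the
    outflux through the upper face (c = Thr, the death threshold) is the
    cumulative death mass, and the outflux through the lower face (c = c_lo,
    tumor eradication) is the cumulative cured mass.  Absorbing the lower
    boundary keeps cured tumors cured; without it, any population mass near
    zero would eventually regrow once resistance raises the growth rate.
    """

    def __init__(self, params: SurrogateParams, nc: int = 90,
                 c_max: float = THR, c_lo: float = 0.05, dt: float = 0.25,
                 drift=None, diffusion=None):
        self.params = params
        self.drift = drift if drift is not None else fp_drift
        self.diffusion = diffusion if diffusion is not None else fp_diffusion
        self.nc = nc
        self.c_max = c_max
        self.c_lo = c_lo
        self.dt = dt
        self.dc = (c_max - c_lo) / nc
        self.c = c_lo + (np.arange(nc) + 0.5) * self.dc    # cell centers
        self.c_faces = c_lo + np.arange(nc + 1) * self.dc

    @staticmethod
    def _cc_delta(B):
        """Chang-Cooper weighting delta(B) = 1/B - 1/(expm1(B))."""
        B = np.asarray(B, dtype=float)
        out = np.empty_like(B)
        small = np.abs(B) < 1e-10
        out[small] = 0.5
        Bb = B[~small]
        out[~small] = 1.0 / Bb - 1.0 / np.expm1(Bb)
        return out

    def step_matrix(self, c_m1: float, r_eff_t: float):
        """Implicit-Euler banded matrix rows and the absorbing-face fluxes."""
        p = self.params
        cf = self.c_faces
        dc = self.dc
        mu_f = self.drift(cf, 0.0, p, c_m1, r_eff_t)
        D_f = 0.5 * self.diffusion(cf, 0.0, p, c_m1)
        # F = mu P - d/dc (D P) = (mu - D') P - D dP/dc
        Dprime = np.gradient(0.5 * self.diffusion(self.c, 0.0, p, c_m1), self.c)
        adv_f = mu_f - np.interp(cf, self.c, Dprime)

        lower = np.zeros(self.nc)
        diag = np.zeros(self.nc)
        upper = np.zeros(self.nc)
        a = adv_f[1:self.nc]
        D = D_f[1:self.nc]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            d = np.where(D > 1e-14, self._cc_delta(a * dc / np.maximum(D, 1e-300)),
                         np.where(a >= 0, 0.0, 1.0))
        wL = a * (1.0 - d) + D / dc
        wR = a * d - D / dc
        diag[:-1] += wL / dc
        upper[:-1] += wR / dc
        diag[1:] -= wR / dc
        lower[1:] -= wL / dc
        # absorbing right boundary (death): ghost P = 0, upwind outflux
        w_dead = max(adv_f[self.nc], 0.0) + D_f[self.nc] / dc
        diag[self.nc - 1] += w_dead / dc
        # absorbing left boundary (cure): outflux for leftward transport
        w_cured = max(-adv_f[0], 0.0) + D_f[0] / dc
        diag[0] += w_cured / dc
        return lower, diag, upper, w_dead, w_cured

    def run(self, P0: np.ndarray, schedule: TreatmentSchedule,
            t_grid: np.ndarray, h0: HybridState | None = None) -> PdfGrid:
        """Solve forward over ``t_grid`` (days), recording each slice."""
        P = np.asarray(P0, dtype=float).copy()
        mass0 = P.sum() * self.dc
        if mass0 > 1.0 + 1e-6:
            raise ValueError("P0 must carry at most unit mass on the mesh")
        out_P = [P.copy()]
        absorbed, cured = [0.0], [0.0]
        dead = cure = 0.0
        for i in range(len(t_grid) - 1):
            span = t_grid[i + 1] - t_grid[i]
            n_sub = max(1, int(np.ceil(span / self.dt)))
            dt = span / n_sub
            # companion ODEs on the sub-step grid of this span
            sub_t = t_grid[i] + dt * np.arange(n_sub + 1)
            hyb = hybrid_trajectory(self.params, schedule, sub_t, h0=h0)
            h0 = HybridState(hyb["d_csf1ri"][-1], hyb["d_igf1ri"][-1],
                             hyb["exposure"][-1], hyb["c_m1"][-1])
            for k in range(n_sub):
                c_m1 = 0.5 * (hyb["c_m1"][k] + hyb["c_m1"][k + 1])
                r_t = 0.5 * (hyb["r_eff"][k] + hyb["r_eff"][k + 1])
                lower, diag, upper, w_dead, w_cured = self.step_matrix(c_m1, r_t)
                ab = np.zeros((3, self.nc))
                ab[0, 1:] = dt * upper[:-1]
                ab[1, :] = 1.0 + dt * diag
                ab[2, :-1] = dt * lower[1:]
                P_new = solve_banded((1, 1), ab, P)
                dead += dt * w_dead * P_new[-1]
                cure += dt * w_cured * P_new[0]
                P = np.clip(P_new, 0.0, None)
            out_P.append(P.copy())
            absorbed.append(dead)
            cured.append(cure)
        return PdfGrid(t=np.asarray(t_grid, dtype=float), c=self.c.copy(),
                       P=np.vstack(out_P), absorbed=np.asarray(absorbed),
                       cured=np.asarray(cured))


def gaussian_p0(c_grid: np.ndarray, mean: float = 0.58, sd: float = 0.03):
    """Normalized initial p.d.f. on the mesh (truncated Gaussian)."""
    P0 = np.exp(-0.5 * ((c_grid - mean) / sd) ** 2)
    dc = c_grid[1] - c_grid[0]
    return P0 / (P0.sum() * dc)


def solve_fp_reference(params: SurrogateParams, P0: np.ndarray,
                       schedule: TreatmentSchedule, t_grid: np.ndarray,
                       nc: int = 90, dt: float = 0.25,
                       c_lo: float = 0.05) -> PdfGrid:
    """Reference finite-volume solution of the Fokker-Planck equation."""
    solver = FPSolver(params, nc=nc, dt=dt, c_lo=c_lo)
    return solver.run(P0, schedule, np.asarray(t_grid, dtype=float))


def euler_maruyama_ensemble(params: SurrogateParams,
                            schedule: TreatmentSchedule,
                            t_grid: np.ndarray, n_paths: int, seed: int,
                            c0_mean: float = 0.58, c0_sd: float = 0.03,
                            dt: float = 0.05):
    """Euler-Maruyama paths of the SDE whose Fokker-Planck form the
    reference solver integrates (noise amplitude sqrt(|nu|)).

    Returns (tc_matrix (n_paths, nt) with NaN after absorption,
    death_time array with inf for survivors).
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    c_lo = 0.05
    c = np.clip(rng.normal(c0_mean, c0_sd, size=n_paths), c_lo + 1e-3, THR - 1e-3)
    alive = np.ones(n_paths, dtype=bool)     # alive and not yet cured
    cured = np.zeros(n_paths, dtype=bool)
    death = np.full(n_paths, np.inf)
    hyb = hybrid_trajectory(params, schedule,
                            np.arange(0.0, t_grid[-1] + dt, dt))
    out = np.full((len(t_grid), n_paths), np.nan)
    out[0] = c
    k_rec = 1
    t = 0.0
    i_h = 0
    while k_rec < len(t_grid):
        c_m1 = hyb["c_m1"][min(i_h, len(hyb["c_m1"]) - 1)]
        r_t = hyb["r_eff"][min(i_h, len(hyb["r_eff"]) - 1)]
        mu = fp_drift(c, t, params, c_m1, r_t)
        nu = fp_diffusion(c, t, params, c_m1)
        dW = rng.normal(0.0, np.sqrt(dt), size=n_paths)
        c = np.where(alive, c + mu * dt + np.sqrt(nu) * dW, c)
        hit = alive & (c >= THR)
        death[hit] = t + dt
        alive &= ~hit
        ext = alive & (c <= c_lo)           # eradicated: absorb as cured
        cured |= ext
        alive &= ~ext
        t += dt
        i_h += 1
        if t >= t_grid[k_rec] - 1e-9:
            out[k_rec, alive] = c[alive]
            k_rec += 1
    return out.T, death


def build_training_pdf(tc_density: np.ndarray, times: np.ndarray,
                       nc: int = 90, c_max: float = THR,
                       bandwidth: float | None = None,
                       thr: float = THR) -> PdfGrid:
    """Empirical population p.d.f. from cohort TC-density series.

    Per time slice: individuals that have already crossed ``thr`` count
    toward the absorbed (dead) mass; the live ones enter a
    reflection-corrected Gaussian kernel estimate on [0, c_max].  Live plus
    dead mass is exactly 1 at every slice.
    """
    X = np.atleast_2d(np.asarray(tc_density, dtype=float))
    N, nt = X.shape
    if N < 2:
        raise ValueError("need at least two individuals")
    c_lo0 = 0.05
    dc = (c_max - c_lo0) / nc
    c_grid = c_lo0 + (np.arange(nc) + 0.5) * dc
    dead = np.zeros(nt)
    cured = np.zeros(nt)
    P = np.zeros((nt, nc))
    crossed = np.zeros(N, dtype=bool)
    extinct = np.zeros(N, dtype=bool)
    c_lo = 0.02
    for j in range(nt):
        crossed |= (X[:, j] >= thr) & ~extinct
        extinct |= (X[:, j] <= c_lo) & ~crossed
        dead[j] = crossed.mean()
        cured[j] = extinct.mean()
        live = X[~crossed & ~extinct, j]
        if live.size == 0:
            continue
        if bandwidth is None:
            sd = np.std(live)
            h = 1.06 * max(sd, 1e-3) * live.size ** (-1 / 5)   # Silverman
        else:
            h = bandwidth
        # reflection-corrected Gaussian KDE on [0, c_max]
        z = (c_grid[:, None] - live[None, :]) / h
        zr0 = (c_grid[:, None] + live[None, :]) / h
        zr1 = (2 * c_max - c_grid[:, None] - live[None, :]) / h
        k = (np.exp(-0.5 * z**2) + np.exp(-0.5 * zr0**2)
             + np.exp(-0.5 * zr1**2)) / (h * np.sqrt(2 * np.pi))
        dens = k.mean(axis=1)
        total = dens.sum() * dc
        if total > 0:
            dens *= (1.0 - dead[j] - cured[j]) / total
        P[j] = dens
    return PdfGrid(t=np.asarray(times, dtype=float), c=c_grid, P=P,
                   absorbed=dead, cured=cured)


# --------------------------------------------------------------------------
# physics-informed training
# --------------------------------------------------------------------------

@dataclass
class PinnSpec:
    """Architecture and training schedule of the p.d.f. approximator."""

    hidden: tuple = (48, 48)
    fourier_k: int = 6           # Fourier input features per coordinate
    n_data: int = 4000           # prior (data) points sampled from the slices
    n_colloc: int = 6000         # collocation points in [0,T]x[0,c_max]
    changepoint_oversample: float = 10.0   # density boost near dose switches
    changepoint_band: float = 1.0          # days around each changepoint
    physics_weight: float = 1.0
    lr: float = 2e-3
    n_iter: int = 800            # first-order (Adam) warm-up iterations
    n_lbfgs: int = 600           # quasi-Newton refinement iterations
    seed: int = 0
    fd_step: tuple = (0.25, 0.01)          # (dt, dc) residual stencil steps


def _fourier_features(X: np.ndarray, k: int) -> np.ndarray:
    """[x, sin(pi j x), cos(pi j x)] embedding; sharpens small-net fits."""
    if k <= 0:
        return X
    feats = [X]
    for j in range(1, k + 1):
        feats.append(np.sin(np.pi * j * X))
        feats.append(np.cos(np.pi * j * X))
    return np.concatenate(feats, axis=1)


@dataclass
class Surrogate:
    """Trained surrogate: fitted parameters plus the p.d.f. approximator.

    Prediction for arbitrary schedules integrates the Fokker-Planck model
    with the fitted noise amplitude; the network is the smooth approximation
    of the training solution used for fidelity checks.
    """

    params: SurrogateParams
    net: MLP | None = None
    t_scale: float = 200.0
    losses: np.ndarray | None = None
    sigma_fitted: float | None = None
    fourier_k: int = 6

    def predict(self, schedule: TreatmentSchedule, t_grid,
                nc: int = 90) -> PdfGrid:
        return solve_fp_reference(self.params, gaussian_p0(
            FPSolver(self.params, nc=nc).c), schedule,
            np.asarray(t_grid, dtype=float), nc=nc)

    def net_eval(self, t, c):
        """Evaluate the network approximator u(t, c)."""
        if self.net is None:
            raise ValueError("no trained network")
        t = np.asarray(t, dtype=float).ravel()
        c = np.asarray(c, dtype=float).ravel()
        X = np.column_stack([t / self.t_scale, c])
        return self.net(_fourier_features(X, self.fourier_k))[:, 0]


def _residual_batch(net: MLP, pts: np.ndarray, params: SurrogateParams,
                    hyb_interp, sigma: float, t_scale: float,
                    fd: tuple, fourier_k: int = 0):
    """PDE residual at collocation points via finite-difference stencils.

    Returns (residual f, stencil inputs X (5n, 2), coefficients a (5n,),
    dres_dsigma) where f_j = sum_k a_jk u(X_jk) and the five stencil points
    per collocation point are (t+ht, c), (t-ht, c), (t, c+hc), (t, c-hc),
    (t, c).
    """
    ht, hc = fd
    t, c = pts[:, 0], pts[:, 1]
    n = len(pts)
    c_m1 = hyb_interp["c_m1"](t)
    r_t = hyb_interp["r_eff"](t)

    def mu(cc):
        return fp_drift(cc, t, params, c_m1, r_t)

    def nu_unit(cc):
        # diffusion magnitude per unit sigma
        p1 = replace(params, sigma=1.0)
        return fp_diffusion(cc, t, p1, c_m1)

    X = np.concatenate([
        np.column_stack([t + ht, c]),
        np.column_stack([t - ht, c]),
        np.column_stack([t, c + hc]),
        np.column_stack([t, c - hc]),
        np.column_stack([t, c]),
    ])
    Xs = X.copy()
    Xs[:, 0] /= t_scale
    u_full, caches = net.forward(_fourier_features(Xs, fourier_k), cache=True)
    u = u_full[:, 0].reshape(5, n)
    # coefficients of f = u_t + (mu u)_c - 1/2 (nu u)_cc
    a = np.empty((5, n))
    a[0] = 1.0 / (2 * ht)
    a[1] = -1.0 / (2 * ht)
    a[2] = mu(c + hc) / (2 * hc) - 0.5 * sigma * nu_unit(c + hc) / hc**2
    a[3] = -mu(c - hc) / (2 * hc) - 0.5 * sigma * nu_unit(c - hc) / hc**2
    a[4] = sigma * nu_unit(c) / hc**2
    f = (a * u).sum(axis=0)
    # d f / d sigma (holding u fixed)
    ds = np.empty((5, n))
    ds[0] = ds[1] = 0.0
    ds[2] = -0.5 * nu_unit(c + hc) / hc**2
    ds[3] = -0.5 * nu_unit(c - hc) / hc**2
    ds[4] = nu_unit(c) / hc**2
    df_dsigma = (ds * u).sum(axis=0)
    return f, caches, a, df_dsigma


def _interp1(x, y):
    return lambda q: np.interp(q, x, y)


def _sigma_least_squares(pdf: PdfGrid, params: SurrogateParams, hyb_i,
                         fd: tuple, rng, n_pts: int = 4000):
    """Closed-form noise-amplitude fit from the p.d.f. surface.

    Writes the residual as A + sigma*B at stencil points of the (bilinearly
    interpolated) surface and solves min_sigma ||A + sigma B||^2.
    """
    from scipy.interpolate import RegularGridInterpolator
    ht, hc = fd
    t, c = pdf.t, pdf.c
    if len(t) < 5:
        return None
    # stencil steps must span at least one mesh cell of the (bilinear)
    # surface, otherwise the second difference vanishes inside a cell
    ht = max(ht, float(t[1] - t[0]))
    hc = max(hc, 2.0 * float(c[1] - c[0]))
    interp = RegularGridInterpolator((t, c), pdf.P, bounds_error=False,
                                     fill_value=None)
    tt = rng.uniform(t[0] + 2 * ht, t[-1] - 2 * ht, n_pts)
    cc = rng.uniform(c[0] + 2 * hc, c[-1] - 2 * hc, n_pts)
    u = lambda a, b: interp(np.column_stack([a, b]))
    cm1 = hyb_i["c_m1"](tt)
    rf = hyb_i["r_eff"](tt)
    mu = lambda x: fp_drift(x, tt, params, cm1, rf)
    p1 = replace(params, sigma=1.0)
    nu1 = lambda x: fp_diffusion(x, tt, p1, cm1)
    A = (u(tt + ht, cc) - u(tt - ht, cc)) / (2 * ht) \
        + (mu(cc + hc) * u(tt, cc + hc) - mu(cc - hc) * u(tt, cc - hc)) / (2 * hc)
    B = -0.5 * (nu1(cc + hc) * u(tt, cc + hc) - 2 * nu1(cc) * u(tt, cc)
                + nu1(cc - hc) * u(tt, cc - hc)) / hc**2
    denom = np.sum(B * B)
    if denom <= 0:
        return None
    return float(-np.sum(A * B) / denom)


def train_pinn(pdfs, schedules, params: SurrogateParams, spec: PinnSpec,
               train_sigma: bool = True) -> Surrogate:
    """Fit the p.d.f. approximator to one or more (PdfGrid, schedule) pairs.

    Loss = mean squared data misfit over sampled slice points + physics
    weight times the mean squared Fokker-Planck residual over collocation
    points (oversampled near dose changepoints, where accuracy is hardest).
    The noise amplitude sigma* is fitted alongside the network weights when
    ``train_sigma`` is set.  Training is deterministic for a fixed spec.
    """
    if isinstance(pdfs, PdfGrid):
        pdfs = [pdfs]
        schedules = [schedules]
    rng = np.random.default_rng(spec.seed)
    t_scale = max(float(p.t[-1]) for p in pdfs)
    d_in = 2 * (1 + 2 * spec.fourier_k)
    net = MLP([d_in, *spec.hidden, 1], seed=spec.seed)

    # --- data points sampled uniformly from the slice grids
    Xd_list, yd_list = [], []
    for p in pdfs:
        tt, cc = np.meshgrid(p.t, p.c, indexing="ij")
        Xd_list.append(np.column_stack([tt.ravel(), cc.ravel()]))
        yd_list.append(p.P.ravel())
    Xd_all = np.vstack(Xd_list)
    yd_all = np.concatenate(yd_list)
    take = rng.choice(len(Xd_all), size=min(spec.n_data, len(Xd_all)),
                      replace=False)
    Xd = Xd_all[take]
    yd = yd_all[take]
    Xd_s = Xd.copy()
    Xd_s[:, 0] /= t_scale
    Xd_s = _fourier_features(Xd_s, spec.fourier_k)

    # --- collocation points, oversampled near the schedules' changepoints
    n_c = spec.n_colloc
    pts = np.column_stack([rng.uniform(spec.fd_step[0],
                                       t_scale - spec.fd_step[0], n_c),
                           rng.uniform(spec.fd_step[1],
                                       THR - spec.fd_step[1], n_c)])
    cps = np.unique(np.concatenate([s.all_changepoints() for s in schedules]))
    cps = cps[(cps > 0) & (cps < t_scale)]
    if cps.size:
        n_extra = min(int(n_c * spec.changepoint_oversample / 100.0 * len(cps)),
                      n_c // 2)
        t_extra = (rng.choice(cps, n_extra)
                   + rng.uniform(-spec.changepoint_band,
                                 spec.changepoint_band, n_extra))
        t_extra = np.clip(t_extra, spec.fd_step[0], t_scale - spec.fd_step[0])
        extra = np.column_stack([t_extra,
                                 rng.uniform(spec.fd_step[1],
                                             THR - spec.fd_step[1], n_extra)])
        pts = np.vstack([pts, extra])

    hyb = hybrid_trajectory(params, schedules[0],
                            np.linspace(0, t_scale, 801))
    hyb_i = {k: _interp1(np.linspace(0, t_scale, 801), v)
             for k, v in hyb.items()}

    sigma = params.sigma
    log_sigma = np.log(max(sigma, 1e-6))
    losses = []
    n5 = len(pts)
    w = spec.physics_weight

    def loss_and_grads(ls):
        sig = float(np.exp(ls))
        yhat, caches_d = net.forward(Xd_s, cache=True)
        err_d = yhat[:, 0] - yd
        loss_d = np.mean(err_d**2)
        g_d = net.backward(caches_d, (2.0 / len(yd)) * err_d[:, None])
        f, caches_p, a, df_ds = _residual_batch(net, pts, params, hyb_i, sig,
                                                t_scale, spec.fd_step,
                                                spec.fourier_k)
        loss_p = np.mean(f**2)
        dLdy = (2.0 * w / n5) * (np.tile(f, 5) * a.ravel())[:, None]
        g_p = net.backward(caches_p, dLdy)
        grads = [gd + gp for gd, gp in zip(g_d, g_p)]
        g_sigma = (2.0 * w / n5) * np.sum(f * df_ds) * sig if train_sigma else 0.0
        return loss_d, loss_p, grads, g_sigma

    # stage 1: Adam warm-up
    opt = Adam(net.params() + [np.array([log_sigma])], lr=spec.lr)
    for it in range(spec.n_iter):
        loss_d, loss_p, grads, g_sigma = loss_and_grads(log_sigma)
        new = opt.step(net.params() + [np.array([log_sigma])],
                       grads + [np.array([g_sigma])])
        net.set_params(new[:-1])
        log_sigma = float(new[-1][0])
        losses.append((loss_d, loss_p))
        if not np.isfinite(loss_d + loss_p):
            break

    # stage 2: quasi-Newton refinement over (theta, log sigma)
    if spec.n_lbfgs > 0:
        from scipy.optimize import minimize
        shapes = [p_.shape for p_ in net.params()]
        sizes = [p_.size for p_ in net.params()]

        def pack(plist, ls):
            return np.concatenate([p_.ravel() for p_ in plist] + [[ls]])

        def unpack(x):
            out, k = [], 0
            for sh, sz in zip(shapes, sizes):
                out.append(x[k:k + sz].reshape(sh))
                k += sz
            return out, float(x[-1])

        def objective(x):
            plist, ls = unpack(x)
            net.set_params(plist)
            loss_d, loss_p, grads, g_sigma = loss_and_grads(ls)
            losses.append((loss_d, loss_p))
            return loss_d + loss_p, pack(grads, g_sigma)

        x0 = pack(net.params(), log_sigma)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=spec.n_lbfgs))
        plist, log_sigma = unpack(res.x)
        net.set_params(plist)

    sigma = float(np.exp(log_sigma))
    if train_sigma:
        # final refinement: for fixed u the Fokker-Planck residual is affine
        # in sigma, so the optimal noise amplitude has a closed form.  The
        # stencils are evaluated on the training surface itself (bilinear in
        # the slice grid) rather than on the network, whose smooth fitting
        # error would otherwise attenuate the estimate.
        sigma_ls = _sigma_least_squares(pdfs[0], params, hyb_i, spec.fd_step,
                                        rng)
        if sigma_ls is not None and sigma_ls > 0:
            sigma = sigma_ls
    fitted = replace(params, sigma=sigma)
    return Surrogate(params=fitted, net=net, t_scale=t_scale,
                     losses=np.asarray(losses), sigma_fitted=sigma,
                     fourier_k=spec.fourier_k)


def surrogate_predict(surrogate: Surrogate, schedule: TreatmentSchedule,
                      t_grid) -> tuple[PdfGrid, np.ndarray]:
    """Predict the p.d.f. evolution and percent-survival curve.

    Survival is the cumulative live probability: 100 times the mass that
    has not yet been absorbed at the death threshold.
    """
    grid = surrogate.predict(schedule, t_grid)
    return grid, grid.survival_percent()
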