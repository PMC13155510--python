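"""Simulation engine: single runs, heterogeneous cohorts, initial-tumor
generation and density-map initialisation.

A run couples the three scales once per time step: reaction-diffusion of the
five fields (CSF1, EGF, IGF1 and the two inhibitors), the per-tumor-cell
signaling network, and the agent phases (quiescence reversal, division,
polarization, phagocytosis, migration, recruitment, aging/death).

Cohort runs emulate intertumor heterogeneity by sampling three parameters
(alpha_ERK, alpha_C, alpha_I) from Normal(basal, 0.1*basal) truncated at
zero, all individuals sharing one frozen initial tumor state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .agents import (AgentGrid, CellParams, age_and_die, attempt_division,
                     migrate, phagocytose, polarize, recruit_and_differentiate,
                     update_quiescence)
from .kinds import (DC, EMPTY, FIELD_NAMES, M0, M1, M2, TC_ACTIVE,
                    TC_QUIESCENT, TAM_KINDS, TC_KINDS, VESSEL)
from .lattice import (Field, LatticeConfig, VascularMap, diffuse_react_step,
                      drug_influx_step, init_vasculature)
from .schedules import TreatmentSchedule
from .signaling import SignalingParams, SignalingState, proliferation_modifier, signaling_step

__all__ = [
    "FieldParams",
    "EngineParams",
    "CohortSpec",
    "TMEState",
    "SimulationResult",
    "CohortResult",
    "CalibrationError",
    "grow_initial_tme",
    "run_single",
    "run_cohort",
    "init_from_density_maps",
]

_REF_SPACING = 15.0  # um; diffusion coefficients are quoted at this spacing


class CalibrationError(RuntimeError):
    """Raised when the burn-in fails to reach the standardized density."""


@dataclass
class FieldParams:
    """Reaction-diffusion rate constants (lattice-units^2/h and 1/h).

    Normalization: cytokine secretion/decay are equal, so a site embedded in
    a dense secreting mass equilibrates at concentration ~1 (CSF1 ~ 1 at the
    tumor core).  Drug influx/decay are set so a sustained full dose yields
    an O(1) concentration in the tissue.
    """

    D_cytokine: float = 2.0
    decay_cytokine: float = 0.02
    s_csf1: float = 0.02         # secretion by TCs
    s_egf: float = 0.02          # secretion by M2
    s_igf1: float = 0.15         # max exposure-induced secretion by M2
    igf1_half: float = 0.0025    # half-saturation of alpha_I * exposure for induction
    q_consume: float = 0.002
    D_drug: float = 6.0
    decay_drug: float = 0.02
    influx: float = 0.5          # per-vascular-site drug influx weight


@dataclass
class EngineParams:
    """All tunables of one simulation, grouped by scale."""

    lattice: LatticeConfig = dc_field(default_factory=LatticeConfig)
    cells: CellParams = dc_field(default_factory=CellParams)
    signaling: SignalingParams = dc_field(default_factory=SignalingParams)
    fields: FieldParams = dc_field(default_factory=FieldParams)
    vasc_p0: float = 0.25        # vascular occupation probability at the edge
    vasc_band: float = 0.15      # normalized width of the vascularized rim
    initial_density: float = 0.58
    burnin_cap_days: float = 120.0
    tc_capacity_frac: float = 0.9    # N_TC^max as a fraction of lattice sites

    @classmethod
    def scaled(cls, **overrides) -> "EngineParams":
        """Reduced profile (50x50 grid, 1 h step) for desk-scale studies."""
        p = cls(lattice=LatticeConfig(nx=50, ny=50, dt=1.0), **overrides)
        return p

    @property
    def n_tc_max(self) -> int:
        return int(round(self.tc_capacity_frac * self.lattice.n_sites))

    @property
    def tam_capacity(self) -> int:
        return int(round(self.cells.tam_capacity_frac * self.lattice.n_sites))


@dataclass
class CohortSpec:
    """Population heterogeneity: alpha_ERK, alpha_C, alpha_I sampled from
    Normal(basal, variance = 0.1 * basal), truncated at 0."""

    N: int = 100
    variance_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")

    def sample(self, params: "EngineParams", rng: np.random.Generator) -> pd.DataFrame:
        basal = {
            "alpha_ERK": params.signaling.alpha_ERK,
            "alpha_C": params.cells.alpha_C,
            "alpha_I": params.cells.alpha_I,
        }
        cols = {}
        for name, mu in basal.items():
            sd = np.sqrt(self.variance_scale * mu)
            x = rng.normal(mu, sd, size=self.N)
            while np.any(x <= 0):      # truncate at zero by resampling
                bad = x <= 0
                x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            cols[name] = x
        return pd.DataFrame(cols)


@dataclass
class TMEState:
    """Full simulator state at one instant: agents + fields + vasculature."""

    grid: AgentGrid
    fields: dict
    vasc: VascularMap
    t_hours: float = 0.0

    def copy(self) -> "TMEState":
        g = self.grid.copy()
        flds = {k: Field(f.name, f.values.copy(), f.D, f.decay,
                         dict(f.secretion), dict(f.consumption))
                for k, f in self.fields.items()}
        return TMEState(g, flds, VascularMap(self.vasc.mask.copy(),
                                             self.vasc.influx_weight.copy()),
                        self.t_hours)

    def tc_density(self, n_tc_max: int) -> float:
        return self.grid.count(*TC_KINDS) / n_tc_max


@dataclass
class SimulationResult:
    times_days: np.ndarray
    tc_density: np.ndarray
    m1_density: np.ndarray       # normalized to TAM carrying capacity
    m2_density: np.ndarray
    dc_density: np.ndarray
    drug_mean: dict              # per drug, spatially averaged concentration
    events: pd.DataFrame
    seed: int
    final_state: TMEState | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t_days": self.times_days, "tc": self.tc_density,
            "m1": self.m1_density, "m2": self.m2_density,
            "dc": self.dc_density,
        })
        for drug, series in self.drug_mean.items():
            df[drug.lower()] = series
        return df


@dataclass
class CohortResult:
    times_days: np.ndarray
    tc_density: np.ndarray       # (N, T)
    sampled: pd.DataFrame
    seeds: list
    events: list

    @property
    def N(self) -> int:
        return self.tc_density.shape[0]


def _build_fields(params: EngineParams) -> dict:
    fp = params.fields
    ny, nx = params.lattice.ny, params.lattice.nx
    scale = (params.lattice.site_spacing / _REF_SPACING) ** 2
    z = lambda: np.zeros((ny, nx))
    mk = lambda name, D, decay, sec, con: Field(
        name, z(), D / scale, decay, sec, con)
    return {
        "CSF1": mk("CSF1", fp.D_cytokine, fp.decay_cytokine,
                   {TC_ACTIVE: fp.s_csf1, TC_QUIESCENT: fp.s_csf1},
                   {M1: fp.q_consume, M2: fp.q_consume}),
        "EGF": mk("EGF", fp.D_cytokine, fp.decay_cytokine,
                  {M2: fp.s_egf},
                  {TC_ACTIVE: fp.q_consume, TC_QUIESCENT: fp.q_consume}),
        "IGF1": mk("IGF1", fp.D_cytokine, fp.decay_cytokine, {},
                   {TC_ACTIVE: fp.q_consume, TC_QUIESCENT: fp.q_consume}),
        "CSF1R_I": mk("CSF1R_I", fp.D_drug, fp.decay_drug, {},
                      {M0: fp.q_consume, M1: fp.q_consume, M2: fp.q_consume}),
        "IGF1R_I": mk("IGF1R_I", fp.D_drug, fp.decay_drug, {},
                      {TC_ACTIVE: fp.q_consume, TC_QUIESCENT: fp.q_consume}),
    }


def _igf1_source(grid: AgentGrid, fp: FieldParams, cells: CellParams) -> np.ndarray:
    """IGF1 secretion by M2, induced saturably by cumulative CSF1R_I exposure.

    The induction is scaled by the individual's drug responsiveness alpha_I,
    so both arms of acquired resistance (M1 reversion and IGF1 secretion)
    share one axis of intertumor heterogeneity.
    """
    x = cells.alpha_I * cells.k_resist * grid.exposure / fp.igf1_half
    src = fp.s_igf1 * x / (1.0 + x)
    src[grid.kind != M2] = 0.0
    return src


def _step(state: TMEState, params: EngineParams, schedule: TreatmentSchedule | None,
          capacity: int) -> None:
    """Advance the coupled system by one lattice time step (in place)."""
    lat, cells, fp = params.lattice, params.cells, params.fields
    dt = lat.dt
    grid = state.grid
    t_days = state.t_hours / 24.0

    # 1. drugs: vascular influx then reaction-diffusion of all fields
    for drug in ("CSF1R_I", "IGF1R_I"):
        dose = schedule.dose(drug, t_days) if schedule is not None else 0.0
        drug_influx_step(state.fields[drug], state.vasc, float(dose), dt)
    for name, f in state.fields.items():
        extra = _igf1_source(grid, fp, cells) if name == "IGF1" else None
        diffuse_react_step(f, grid.kind, dt, extra_source=extra)

    # 2. intracellular signaling of TCs
    sig = SignalingState(grid.egfr, grid.igf1r, grid.erk, grid.akt)
    signaling_step(sig, state.fields["EGF"].values,
                   state.fields["IGF1"].values, params.signaling, dt,
                   igf1ri_local=state.fields["IGF1R_I"].values)
    is_tc = np.isin(grid.kind, TC_KINDS)
    for name, arr in (("egfr", sig.egfr), ("igf1r", sig.igf1r),
                      ("erk", sig.erk), ("akt", sig.akt)):
        arr[~is_tc] = 0.0
        setattr(grid, name, arr)
    mult = proliferation_modifier(sig, params.signaling)

    # 3. agent phases
    csf1 = state.fields["CSF1"].values
    csf1ri = state.fields["CSF1R_I"].values
    update_quiescence(grid, cells)
    attempt_division(grid, mult, cells, dt)
    polarize(grid, csf1, csf1ri, cells, dt)
    phagocytose(grid, cells, dt)
    migrate(grid, csf1, cells, dt)
    recruit_and_differentiate(grid, state.vasc, csf1, cells, dt,
                              capacity=capacity)
    age_and_die(grid, cells, dt, csf1ri=csf1ri)

    state.t_hours += dt


def _seed_tumor(grid: AgentGrid, params: EngineParams) -> None:
    """Place the initial stem TCs at the lattice center."""
    cells = params.cells
    cy, cx = grid.ny // 2, grid.nx // 2
    spots = [(cy, cx), (cy, cx + 1), (cy + 1, cx), (cy + 1, cx + 1)]
    for (y, x) in spots[: cells.n_stem]:
        flat = y * grid.nx + x
        grid.place(np.array([flat]), TC_ACTIVE,
                   lifespan=cells.tc_lifespan * cells.stem_lifespan_mult,
                   cycle_len=cells.div * cells.stem_cycle_mult)


def new_state(params: EngineParams, seed: int) -> TMEState:
    """Empty TME with vasculature; no tumor yet."""
    lat = params.lattice
    ss = np.random.SeedSequence(seed)
    s_vasc, s_agents = ss.spawn(2)
    p0, band = params.vasc_p0, params.vasc_band
    profile = lambda d: p0 * np.clip(1.0 - d / band, 0.0, 1.0)
    vasc = init_vasculature(lat, profile, seed=s_vasc.generate_state(1)[0] % (2**31),
                            influx_weight=params.fields.influx)
    rng = np.random.default_rng(s_agents)
    grid = AgentGrid(lat.ny, lat.nx, rng)
    grid.kind[vasc.mask] = VESSEL
    return TMEState(grid, _build_fields(params), vasc)


def grow_initial_tme(params: EngineParams, seed: int) -> TMEState:
    """Drug-free burn-in from the initial stem cells until the tumor first
    reaches the standardized density (default 0.58); the returned state is
    the shared initial condition of all treatment experiments."""
    state = new_state(params, seed)
    _seed_tumor(state.grid, params)
    cap_steps = int(params.burnin_cap_days * 24.0 / params.lattice.dt)
    target = params.initial_density
    capacity = params.tam_capacity
    for _ in range(cap_steps):
        _step(state, params, None, capacity)
        if state.tc_density(params.n_tc_max) >= target:
            return state
    raise CalibrationError(
        f"burn-in did not reach density {target} within "
        f"{params.burnin_cap_days} days "
        f"(reached {state.tc_density(params.n_tc_max):.3f})")


def run_single(tme0: TMEState, schedule: TreatmentSchedule | None,
               params: EngineParams, horizon_days: float, seed: int,
               keep_final_state: bool = False,
               record_every: int = 1) -> SimulationResult:
    """Advance a copy of ``tme0`` under a treatment schedule.

    Fully reproducible: the run RNG stream is derived from ``seed`` alone.
    """
    if horizon_days > 200.0:
        raise ValueError("horizon capped at 200 days")
    state = tme0.copy()
    state.t_hours = 0.0
    state.grid.rng = np.random.default_rng(seed)
    lat = params.lattice
    n_steps = int(round(horizon_days * 24.0 / lat.dt))
    capacity = params.tam_capacity
    cap = params.tam_capacity
    n_max = params.n_tc_max

    rec_t, rec = [], {k: [] for k in ("tc", "m1", "m2", "dc")}
    drug_mean = {d: [] for d in ("CSF1R_I", "IGF1R_I")}
    ev_rows = []

    def record() -> None:
        rec_t.append(state.t_hours / 24.0)
        kgrid = state.grid.kind
        rec["tc"].append(np.isin(kgrid, TC_KINDS).sum() / n_max)
        rec["m1"].append((kgrid == M1).sum() / cap)
        rec["m2"].append((kgrid == M2).sum() / cap)
        rec["dc"].append((kgrid == DC).sum() / n_max)
        for d in drug_mean:
            drug_mean[d].append(float(state.fields[d].values.mean()))

    record()
    for k in range(n_steps):
        state.grid.reset_events()
        _step(state, params, schedule, capacity)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            record()
            ev_rows.append(dict(t_days=state.t_hours / 24.0,
                                **state.grid.events))

    return SimulationResult(
        times_days=np.asarray(rec_t),
        tc_density=np.asarray(rec["tc"]),
        m1_density=np.asarray(rec["m1"]),
        m2_density=np.asarray(rec["m2"]),
        dc_density=np.asarray(rec["dc"]),
        drug_mean={d: np.asarray(v) for d, v in drug_mean.items()},
        events=pd.DataFrame(ev_rows),
        seed=seed,
        final_state=state if keep_final_state else None,
    )


def run_cohort(tme0: TMEState, schedule: TreatmentSchedule | None,
               spec: CohortSpec, params: EngineParams, horizon_days: float,
               seed: int, record_every: int = 1) -> CohortResult:
    """N independent runs from the shared initial state with per-individual
    sampled (alpha_ERK, alpha_C, alpha_I) and independent RNG streams."""
    ss = np.random.SeedSequence(seed)
    s_sample, *s_runs = ss.spawn(spec.N + 1)
    sampled = spec.sample(params, np.random.default_rng(s_sample))
    series, seeds, events = [], [], []
    times = None
    for i in range(spec.N):
        p_i = copy.deepcopy(params)
        p_i.signaling = replace(params.signaling,
                                alpha_ERK=float(sampled.loc[i, "alpha_ERK"]),
                                s_ref=params.signaling.s_ref)
        p_i.cells = replace(params.cells,
                            alpha_C=float(sampled.loc[i, "alpha_C"]),
                            alpha_I=float(sampled.loc[i, "alpha_I"]))
        run_seed = int(s_runs[i].generate_state(1)[0] % (2**31))
        res = run_single(tme0, schedule, p_i, horizon_days, run_seed,
                         record_every=record_every)
        series.append(res.tc_density)
        seeds.append(run_seed)
        events.append(res.events)
        times = res.times_days
    return CohortResult(times_days=times, tc_density=np.vstack(series),
                        sampled=sampled, seeds=seeds, events=events)


def init_from_density_maps(tc_map, m1_map, m2_map, params: EngineParams,
                           seed: int) -> TMEState:
    """Initialize the TME from per-site cell-type proportion maps (the
    spatial-transcriptomics-style entry point, 60 um spots).

    Each site is annotated with the arg-max type among {TC, M1, M2, empty}
    where the empty proportion is 1 minus the sum of the other three.
    Fields are relaxed to quasi-steady state for the frozen cell layout.
    """
    maps = [np.asarray(m, dtype=float) for m in (tc_map, m1_map, m2_map)]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("density maps must share one grid shape")
    for m in maps:
        if np.any((m < 0) | (m > 1)):
            raise ValueError("proportions must lie in [0, 1]")
    ny, nx = shape
    if (ny, nx) != (params.lattice.ny, params.lattice.nx):
        raise ValueError("maps must match the configured lattice shape")

    state = new_state(params, seed)
    grid = state.grid
    rng = grid.rng
    cells = params.cells
    empty = np.clip(1.0 - sum(maps), 0.0, None)
    stacked = np.stack([empty] + maps)     # order: empty, TC, M1, M2
    winner = stacked.argmax(axis=0)
    winner[grid.kind == VESSEL] = 0        # vessels stay vessels

    kind_of = {1: TC_ACTIVE, 2: M1, 3: M2}
    for w, kind in kind_of.items():
        idx = np.flatnonzero(winner.ravel() == w)
        if idx.size == 0:
            continue
        if kind == TC_ACTIVE:
            grid.place(idx, kind, lifespan=cells.tc_lifespan,
                       cycle_len=cells.div)
            grid.age.ravel()[idx] = rng.uniform(0, cells.tc_lifespan / 2, idx.size)
            grid.cycle_phase.ravel()[idx] = rng.uniform(0, cells.div, idx.size)
        else:
            grid.place(idx, kind, lifespan=cells.tam_lifespan)
            grid.age.ravel()[idx] = rng.uniform(0, cells.tam_lifespan / 2, idx.size)

    # relax fields to quasi-steady state with the cell layout frozen
    for _ in range(400):
        for name, f in state.fields.items():
            if name in ("CSF1R_I", "IGF1R_I"):
                continue
            diffuse_react_step(f, grid.kind, params.lattice.dt)
    return state
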