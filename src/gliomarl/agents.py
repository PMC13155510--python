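"""Cellular scale: on-lattice agent rules for tumor cells, macrophages and
dead cells.

Tumor cells (TCs) divide into empty Moore neighbors, become quiescent when
fully enclosed (age frozen), and revert when space frees up.  Macrophages
(TAMs) are recruited at the vasculature as M0, mature into M1/M2, polarize
between the phenotypes under the control of local CSF1 and the CSF1R
inhibitor, chemotax up CSF1 gradients, and (M1 only) phagocytose adjacent
tumor or dead cells.  Cells that outlive their lifespan become dead cells
(DCs) cleared at a slow constant rate.

The scheduler is phase-synchronous: within each phase all eligible agents
act at once and site conflicts are resolved by a uniformly random winner.
Basal per-step probabilities are defined at the reference step ``dt_ref``
(0.5 h) and rescaled as ``1 - (1-p)**(dt/dt_ref)`` when the engine runs at a
different step, so that ``p = 1`` stays certain and ``p = 0`` impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .kinds import (EMPTY, TC_ACTIVE, TC_QUIESCENT, M0, M1, M2, DC, VESSEL,
                    TAM_KINDS, TC_KINDS)

__all__ = [
    "CellParams",
    "AgentGrid",
    "attempt_division",
    "update_quiescence",
    "polarize",
    "phagocytose",
    "migrate",
    "recruit_and_differentiate",
    "age_and_die",
]

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class CellParams:
    """Agent-rule parameters.

    Probabilities are per step at ``dt_ref`` unless stated otherwise; ``pTC``
    is per completed cell cycle.  Defaults are calibrated so that a
    treatment-naive run starting from the standard initial tumor (density
    0.58) reaches density ~0.9 by day 20 with the macrophage pool ~85% M2 /
    ~15% M1, and so that full-dose CSF1R inhibition transiently raises the
    M1 fraction to ~0.4 before acquired resistance reverses it.
    """

    dt_ref: float = 0.5            # h; reference step for per-step probabilities
    # --- tumor cells
    pTC: float = 0.5               # basal division probability per cycle
    div: float = 24.0              # cell-cycle length, h
    tc_lifespan: float = 480.0     # h
    p_tc_move: float = 0.01        # unbiased migration prob per step
    n_stem: int = 4
    stem_lifespan_mult: float = 2.0
    stem_cycle_mult: float = 0.5
    quiescence: bool = True        # False -> nonquiescent model variant
    # --- macrophages
    tam_capacity_frac: float = 0.08   # carrying capacity as fraction of sites
    prec: float = 0.006            # basal recruitment prob per vascular site/step
    k_rec_csf1: float = 0.05        # CSF1 half-saturation of recruitment boost
    m0_maturation: float = 24.0    # h
    p_m0_to_m1: float = 0.3        # differentiation split at maturation
    tam_lifespan: float = 2400.0    # h
    DM: float = 0.35                # TAM migration prob per step
    beta_chemo: float = 30.0       # CSF1 chemotaxis weight (softmax gain)
    kM12: float = 0.006            # max M1->M2 Hill prob per step
    K_csf1: float = 0.1            # CSF1 half-saturation of M1->M2 switching
    alpha_C: float = 1.0           # adjustment coefficient of the CSF1 Hill term
    KM12d: float = 0.7            # TAM responsiveness to CSF1R_I
    alpha_I: float = 1.0           # CSF1R_I-responsiveness scale (resistance axis)
    k_resist: float = 2.6e-7       # M1->M2 reversion prob per unit drug exposure
    pM21: float = 0.001           # basal M2->M1 prob per step
    pha: float = 0.16             # M1 phagocytosis prob per step
    # --- dead cells
    dc_removal: float = 0.002      # clearance prob per step

    def __post_init__(self) -> None:
        for name in ("pTC", "prec", "p_m0_to_m1", "DM", "kM12", "pM21",
                     "pha", "dc_removal", "p_tc_move"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("div", "tc_lifespan", "tam_lifespan", "m0_maturation",
                     "K_csf1", "alpha_C", "KM12d", "alpha_I", "k_resist",
                     "beta_chemo", "k_rec_csf1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def per_step(self, p, dt: float):
        """Rescale a per-step probability from dt_ref to dt."""
        if dt == self.dt_ref:
            return p
        return 1.0 - (1.0 - np.minimum(p, 1.0)) ** (dt / self.dt_ref)


def _neighbor_table(ny: int, nx: int, offsets) -> np.ndarray:
    """(n_sites, k) flat neighbor indices; -1 marks out-of-bounds."""
    iy, ix = np.mgrid[0:ny, 0:nx]
    tables = []
    for dy, dx in offsets:
        ty, tx = iy + dy, ix + dx
        ok = (ty >= 0) & (ty < ny) & (tx >= 0) & (tx < nx)
        flat = np.where(ok, ty * nx + tx, -1)
        tables.append(flat.ravel())
    return np.stack(tables, axis=1)


# per-site cell attributes carried along on moves / cleared on removal
_ATTRS = ("age", "lifespan", "cycle_len", "cycle_phase", "exposure",
          "mature", "egfr", "igf1r", "erk", "akt")


class AgentGrid:
    """Lattice occupancy plus per-cell attribute planes and the run RNG."""

    def __init__(self, ny: int, nx: int, rng: np.random.Generator):
        self.ny, self.nx = ny, nx
        self.kind = np.zeros((ny, nx), dtype=np.int8)
        for a in _ATTRS:
            setattr(self, a, np.zeros((ny, nx), dtype=float))
        self.rng = rng
        self.moore = _neighbor_table(ny, nx, _MOORE)
        self.vn = _neighbor_table(ny, nx, _VON_NEUMANN)
        self.events: dict[str, int] = {}
        self.reset_events()

    # -- bookkeeping -------------------------------------------------------
    def reset_events(self) -> None:
        self.events = dict(division=0, reverted=0, m1_to_m2=0, m2_to_m1=0,
                           phago_tc=0, phago_dc=0, death_tc=0, death_tam=0,
                           dc_removed=0, recruited=0, m1_steps=0)

    def count(self, *kinds) -> int:
        return int(np.isin(self.kind, kinds).sum())

    def tam_count(self) -> int:
        return self.count(*TAM_KINDS)

    def copy(self) -> "AgentGrid":
        g = AgentGrid.__new__(AgentGrid)
        g.ny, g.nx = self.ny, self.nx
        g.kind = self.kind.copy()
        for a in _ATTRS:
            setattr(g, a, getattr(self, a).copy())
        g.rng = self.rng
        g.moore, g.vn = self.moore, self.vn
        g.events = dict(self.events)
        return g

    # -- low-level site ops ------------------------------------------------
    def clear_sites(self, flat_idx: np.ndarray) -> None:
        self.kind.ravel()[flat_idx] = EMPTY
        for a in _ATTRS:
            getattr(self, a).ravel()[flat_idx] = 0.0

    def move_cells(self, src: np.ndarray, dst: np.ndarray) -> None:
        kf = self.kind.ravel()
        kf[dst] = kf[src]
        kf[src] = EMPTY
        for a in _ATTRS:
            af = getattr(self, a).ravel()
            af[dst] = af[src]
            af[src] = 0.0

    def place(self, flat_idx, kind: int, **attrs) -> None:
        self.kind.ravel()[flat_idx] = kind
        for a in _ATTRS:
            getattr(self, a).ravel()[flat_idx] = attrs.get(a, 0.0)


def _sample_candidates(rng, cand, valid, weights=None):
    """Pick one valid candidate per row (uniform or weighted); -1 if none."""
    if weights is None:
        w = valid.astype(float)
    else:
        w = np.where(valid, weights, 0.0)
    tot = w.sum(axis=1)
    ok = tot > 0
    cw = np.cumsum(w, axis=1)
    r = rng.random(cand.shape[0]) * np.maximum(tot, 1e-300)
    pick = (cw > r[:, None]).argmax(axis=1)
    return np.where(ok, cand[np.arange(cand.shape[0]), pick], -1)


def _resolve_conflicts(rng, dst):
    """Winner mask: one uniformly random claimant per contested site."""
    n = dst.shape[0]
    win = np.zeros(n, dtype=bool)
    perm = rng.permutation(n)
    _, first = np.unique(dst[perm], return_index=True)
    win[perm[first]] = True
    win &= dst >= 0
    return win


def _empty_neighbors(grid: AgentGrid, idx: np.ndarray, table: np.ndarray):
    cand = table[idx]
    safe = np.where(cand < 0, 0, cand)
    valid = (cand >= 0) & (grid.kind.ravel()[safe] == EMPTY)
    return cand, valid


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def attempt_division(grid: AgentGrid, mult, params: CellParams, dt: float | None = None):
    """Division attempts for all active TCs with a completed cell cycle.

    With probability ``min(1, pTC * mult)`` a daughter is placed on a
    uniformly chosen empty Moore neighbor; stem-lineage daughters have their
    lifespan halved and cycle doubled until regular values are reached.
    Fully enclosed cells become quiescent (or, in the nonquiescent variant,
    simply restart their cycle).  Returns the number of divisions.
    """
    rng = grid.rng
    kf = grid.kind.ravel()
    ready = (kf == TC_ACTIVE) & (grid.cycle_phase.ravel() >= grid.cycle_len.ravel() - 1e-9)
    idx = np.flatnonzero(ready)
    if idx.size == 0:
        return 0
    cand, valid = _empty_neighbors(grid, idx, grid.moore)
    has_space = valid.any(axis=1)

    blocked = idx[~has_space]
    if params.quiescence:
        kf[blocked] = TC_QUIESCENT          # cycle_phase retained: divide on revert
    else:
        grid.cycle_phase.ravel()[blocked] = 0.0

    free = has_space
    mflat = np.broadcast_to(np.asarray(mult, dtype=float).ravel(),
                            grid.kind.size) if np.ndim(mult) else None
    m = mflat[idx[free]] if mflat is not None else float(mult)
    p = np.minimum(1.0, params.pTC * m)
    success = rng.random(int(free.sum())) < p
    grid.cycle_phase.ravel()[idx[free]] = 0.0

    src = idx[free][success]
    if src.size == 0:
        return 0
    tgt = _sample_candidates(rng, cand[free][success], valid[free][success])
    win = _resolve_conflicts(rng, tgt)
    src, dst = src[win], tgt[win]
    if src.size == 0:
        return 0
    # stem lineage: halve lifespan / double cycle until regular values
    d_life = np.maximum(grid.lifespan.ravel()[src] / 2.0, params.tc_lifespan)
    d_cyc = np.minimum(grid.cycle_len.ravel()[src] * 2.0, params.div)
    grid.kind.ravel()[dst] = TC_ACTIVE
    grid.lifespan.ravel()[dst] = d_life
    grid.cycle_len.ravel()[dst] = d_cyc
    grid.age.ravel()[dst] = 0.0
    grid.cycle_phase.ravel()[dst] = 0.0
    for a in ("egfr", "igf1r", "erk", "akt"):   # daughters inherit signaling
        af = getattr(grid, a).ravel()
        af[dst] = af[src]
    grid.events["division"] += int(src.size)
    return int(src.size)


def update_quiescence(grid: AgentGrid, params: CellParams) -> int:
    """Revert quiescent TCs that regained an empty Moore neighbor.

    Reverted cells keep their completed cycle phase, so the division phase of
    the same scheduler step immediately attempts a division for them.
    Returns the number of reverted cells.
    """
    if not params.quiescence:
        return 0
    kf = grid.kind.ravel()
    idx = np.flatnonzero(kf == TC_QUIESCENT)
    if idx.size == 0:
        return 0
    _, valid = _empty_neighbors(grid, idx, grid.moore)
    revert = idx[valid.any(axis=1)]
    kf[revert] = TC_ACTIVE
    grid.events["reverted"] += int(revert.size)
    return int(revert.size)


def polarize(grid: AgentGrid, csf1: np.ndarray, csf1ri: np.ndarray,
             params: CellParams, dt: float) -> None:
    """Stochastic M1<->M2 phenotype switching.

    M1->M2 per step: ``kM12 * c/(K/alpha_C + c) / (1 + KM12d*u) +
    alpha_I * exposure`` -- CSF1-driven polarization, inhibited by the CSF1R
    inhibitor ``u``, plus an acquired-resistance term growing with cumulative
    local drug exposure.  M2->M1: ``pM21 * (1 + KM12d*u)``.
    """
    rng = grid.rng
    kf = grid.kind.ravel()
    c = np.asarray(csf1, dtype=float).ravel()
    u = np.asarray(csf1ri, dtype=float).ravel()

    m1 = np.flatnonzero(kf == M1)
    if m1.size:
        hill = params.kM12 * c[m1] / (params.K_csf1 / max(params.alpha_C, 1e-12) + c[m1])
        p12 = hill / (1.0 + params.KM12d * u[m1]) \
            + params.alpha_I * params.k_resist * grid.exposure.ravel()[m1]
        p12 = params.per_step(np.clip(p12, 0.0, 1.0), dt)
        flip = m1[rng.random(m1.size) < p12]
        kf[flip] = M2
        grid.events["m1_to_m2"] += int(flip.size)

    m2 = np.flatnonzero(kf == M2)
    if m2.size:
        p21 = np.clip(params.pM21 * (1.0 + params.KM12d * u[m2]), 0.0, 1.0)
        p21 = params.per_step(p21, dt)
        flip = m2[rng.random(m2.size) < p21]
        kf[flip] = M1
        grid.events["m2_to_m1"] += int(flip.size)


def phagocytose(grid: AgentGrid, params: CellParams, dt: float) -> int:
    """M1 macrophages engulf an adjacent TC (preferred) or DC and move into
    the vacated site.  Returns the number of phagocytosis events."""
    rng = grid.rng
    kf = grid.kind.ravel()
    m1 = np.flatnonzero(kf == M1)
    grid.events["m1_steps"] += int(m1.size)
    if m1.size == 0:
        return 0
    fire = m1[rng.random(m1.size) < params.per_step(params.pha, dt)]
    if fire.size == 0:
        return 0
    cand = grid.vn[fire]
    safe = np.where(cand < 0, 0, cand)
    ck = kf[safe]
    is_tc = (cand >= 0) & ((ck == TC_ACTIVE) | (ck == TC_QUIESCENT))
    is_dc = (cand >= 0) & (ck == DC)
    use_tc = is_tc.any(axis=1)
    valid = np.where(use_tc[:, None], is_tc, is_dc)
    tgt = _sample_candidates(rng, cand, valid)
    win = _resolve_conflicts(rng, tgt)
    src, dst = fire[win], tgt[win]
    if src.size == 0:
        return 0
    victim_tc = np.isin(kf[dst], TC_KINDS)
    grid.events["phago_tc"] += int(victim_tc.sum())
    grid.events["phago_dc"] += int((~victim_tc).sum())
    grid.clear_sites(dst)
    grid.move_cells(src, dst)
    return int(src.size)


def migrate(grid: AgentGrid, csf1: np.ndarray, params: CellParams, dt: float) -> None:
    """Random-walk / chemotactic relocation into empty Von Neumann neighbors.

    TAMs move with probability DM per step, choosing among empty neighbors
    with weights ``exp(beta_chemo * CSF1)`` (softmax over candidates, i.e.
    biased up-gradient); active TCs move unbiased with probability
    ``p_tc_move``.
    """
    rng = grid.rng
    kf = grid.kind.ravel()
    c = np.asarray(csf1, dtype=float).ravel()

    for kinds, prob, biased in ((TAM_KINDS, params.DM, True),
                                ((TC_ACTIVE,), params.p_tc_move, False)):
        idx = np.flatnonzero(np.isin(kf, kinds))
        if idx.size == 0:
            continue
        movers = idx[rng.random(idx.size) < params.per_step(prob, dt)]
        if movers.size == 0:
            continue
        cand, valid = _empty_neighbors(grid, movers, grid.vn)
        if biased:
            safe = np.where(cand < 0, 0, cand)
            z = params.beta_chemo * c[safe]
            z -= z.max(axis=1, keepdims=True)
            w = np.exp(z)
        else:
            w = None
        tgt = _sample_candidates(rng, cand, valid, w)
        win = _resolve_conflicts(rng, tgt)
        src, dst = movers[win], tgt[win]
        if src.size:
            grid.move_cells(src, dst)


def recruit_and_differentiate(grid: AgentGrid, vasc, csf1: np.ndarray,
                              params: CellParams, dt: float,
                              capacity: int | None = None) -> int:
    """Vasculature-driven M0 recruitment (CSF1-boosted, capacity-capped) and
    maturation of M0 into M1/M2.  Returns the number of recruits."""
    rng = grid.rng
    kf = grid.kind.ravel()
    c = np.asarray(csf1, dtype=float).ravel()
    if capacity is None:
        capacity = int(round(params.tam_capacity_frac * grid.kind.size))

    # maturation first: M0 -> M1/M2 after the delay
    m0 = np.flatnonzero(kf == M0)
    if m0.size:
        mat = grid.mature.ravel()
        mat[m0] -= dt
        done = m0[mat[m0] <= 0.0]
        if done.size:
            to_m1 = rng.random(done.size) < params.p_m0_to_m1
            kf[done[to_m1]] = M1
            kf[done[~to_m1]] = M2

    room = capacity - grid.tam_count()
    if room <= 0:
        return 0
    vmask = vasc.mask if hasattr(vasc, "mask") else np.asarray(vasc, dtype=bool)
    vidx = np.flatnonzero(vmask.ravel())
    if vidx.size == 0:
        return 0
    boost = 0.01 + 0.99 * c[vidx] / (params.k_rec_csf1 + c[vidx] + 1e-300)
    p = params.per_step(np.clip(params.prec * boost, 0.0, 1.0), dt)
    fire = vidx[rng.random(vidx.size) < p]
    if fire.size == 0:
        return 0
    cand, valid = _empty_neighbors(grid, fire, grid.vn)
    tgt = _sample_candidates(rng, cand, valid)
    win = _resolve_conflicts(rng, tgt)
    dst = tgt[win]
    if dst.size > room:
        dst = rng.permutation(dst)[:room]
    if dst.size == 0:
        return 0
    grid.place(dst, M0, lifespan=params.tam_lifespan,
               mature=params.m0_maturation)
    grid.events["recruited"] += int(dst.size)
    return int(dst.size)


def age_and_die(grid: AgentGrid, params: CellParams, dt: float,
                csf1ri: np.ndarray | None = None) -> None:
    """Aging, cycle progression, lifespan death (-> DC) and DC clearance.

    Quiescent TCs do not age.  TAM sites additionally accumulate cumulative
    CSF1R_I exposure (the substrate of acquired resistance).
    """
    rng = grid.rng
    kf = grid.kind.ravel()
    age = grid.age.ravel()

    active = kf == TC_ACTIVE
    tams = (kf == M0) | (kf == M1) | (kf == M2)
    ages_now = active | tams
    age[ages_now] += dt
    grid.cycle_phase.ravel()[active] += dt

    if csf1ri is not None:
        u = np.asarray(csf1ri, dtype=float).ravel()
        ef = grid.exposure.ravel()
        ef[tams] += u[tams] * dt

    dying = np.flatnonzero(ages_now & (age >= grid.lifespan.ravel()))
    if dying.size:
        grid.events["death_tc"] += int(np.isin(kf[dying], TC_KINDS).sum())
        grid.events["death_tam"] += int(np.isin(kf[dying], TAM_KINDS).sum())
        grid.clear_sites(dying)
        grid.kind.ravel()[dying] = DC

    dcs = np.flatnonzero(kf == DC)
    if dcs.size:
        gone = dcs[rng.random(dcs.size) < params.per_step(params.dc_removal, dt)]
        if gone.size:
            grid.clear_sites(gone)
            grid.events["dc_removed"] += int(gone.size)
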