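"""Molecular scale: per-tumor-cell receptor/kinase network.

Each tumor cell carries four dimensionless activities in [0, 1]:

* ``egfr`` / ``igf1r`` -- receptor activation, driven saturably by the local
  EGF / IGF1 concentration and suppressed by negative feedback from ERK;
* ``erk`` / ``akt`` -- downstream kinase activities driven by the respective
  receptor and relaxing at first order.

The ODE system for one cell (ligands ``E``, ``I``; IGF1R-inhibitor ``u``):

    dR_E/dt = a_E E/(K_E+E) (1-R_E) - (d_E + f ERK) R_E
    dR_I/dt = a_I I/(K_I+I) / (1 + k_u u) (1-R_I) - (d_I + f ERK) R_I
    dERK/dt = k_erk R_E - delta_erk ERK
    dAKT/dt = k_akt R_I - delta_akt AKT

With ``k_erk <= delta_erk`` and ``k_akt <= delta_akt`` the hypercube
[0,1]^4 is forward-invariant.  ERK feedback stabilizes EGFR at an
intermediate level; without IGF1 both IGF1R and AKT stay near zero, and IGF1
secreted by reprogrammed M2 macrophages raises AKT -- the resistance axis the
IGF1R inhibitor targets.

All state arrays are vectorized over cells; integration is explicit Euler at
the lattice time step with internal sub-stepping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalingState",
    "SignalingParams",
    "signaling_step",
    "steady_state",
    "proliferation_modifier",
]


@dataclass
class SignalingState:
    """Vectorized signaling state; each attribute is an array over cells."""

    egfr: np.ndarray
    igf1r: np.ndarray
    erk: np.ndarray
    akt: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SignalingState":
        return cls(*(np.zeros(n) for _ in range(4)))

    def copy(self) -> "SignalingState":
        return SignalingState(self.egfr.copy(), self.igf1r.copy(),
                              self.erk.copy(), self.akt.copy())


@dataclass
class SignalingParams:
    # receptor kinetics (1/h)
    a_E: float = 2.0
    K_E: float = 0.75
    d_E: float = 0.2
    a_I: float = 2.0
    K_I: float = 0.75
    d_I: float = 0.2
    feedback: float = 1.0        # ERK negative feedback on both receptors
    # kinase kinetics (1/h); gain k/delta <= 1 keeps activities in [0, 1]
    k_erk: float = 0.5
    delta_erk: float = 0.5
    k_akt: float = 0.5
    delta_akt: float = 0.5
    basal: float = 0.15          # basal EGFR activation drive (1/h)
    basal_igf1r: float = 0.08    # basal IGF1R activation drive (1/h), drug-blockable
    k_igf1ri: float = 8.0        # IGF1R_I potency on IGF1R activation
    # proliferation coupling
    alpha_ERK: float = 1.0
    alpha_AKT: float = 1.0
    mult_min: float = 0.12       # basal floor of the proliferation multiplier
    mult_max: float = 2.0
    hill_n: float = 3.0          # steepness of the proliferation response
    s_ref: float | None = None   # drive at which the multiplier equals 1
    egf_ref: float = 0.06        # realized naive EGF at the tumor rim (calibration point)
    n_substeps: int = 4

    def __post_init__(self) -> None:
        for name in ("a_E", "K_E", "d_E", "a_I", "K_I", "d_I", "feedback",
                     "k_erk", "delta_erk", "k_akt", "delta_akt", "basal",
                     "k_igf1ri", "alpha_ERK", "alpha_AKT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mult_min < 1 < self.mult_max:
            raise ValueError("need mult_min < 1 < mult_max")
        if self.s_ref is None:
            # calibrate the reference drive at the treatment-naive operating
            # point: rim-level EGF, no IGF1, no inhibitor
            ss = steady_state(self, egf=self.egf_ref, igf1=0.0, igf1ri=0.0)
            self.s_ref = float(self.alpha_ERK * ss["erk"] + self.alpha_AKT * ss["akt"])


def _activation(a: float, K: float, L, basal: float):
    return a * L / (K + L) + basal


def signaling_step(
    state: SignalingState,
    egf_local,
    igf1_local,
    params: SignalingParams,
    dt: float,
    igf1ri_local=0.0,
) -> SignalingState:
    """Advance the signaling network one lattice time step (in place)."""
    egf = np.asarray(egf_local, dtype=float)
    igf1 = np.asarray(igf1_local, dtype=float)
    u = np.asarray(igf1ri_local, dtype=float)
    if np.any(egf < 0) or np.any(igf1 < 0):
        raise ValueError("ligand concentrations must be >= 0")
    p = params
    sub = dt / p.n_substeps
    A_E = _activation(p.a_E, p.K_E, egf, p.basal)
    A_I = _activation(p.a_I, p.K_I, igf1, p.basal_igf1r) / (1.0 + p.k_igf1ri * u)
    for _ in range(p.n_substeps):
        fb = p.feedback * state.erk
        d_egfr = A_E * (1.0 - state.egfr) - (p.d_E + fb) * state.egfr
        d_igf1r = A_I * (1.0 - state.igf1r) - (p.d_I + fb) * state.igf1r
        d_erk = p.k_erk * state.egfr - p.delta_erk * state.erk
        d_akt = p.k_akt * state.igf1r - p.delta_akt * state.akt
        state.egfr = np.clip(state.egfr + sub * d_egfr, 0.0, 1.0)
        state.igf1r = np.clip(state.igf1r + sub * d_igf1r, 0.0, 1.0)
        state.erk = np.clip(state.erk + sub * d_erk, 0.0, 1.0)
        state.akt = np.clip(state.akt + sub * d_akt, 0.0, 1.0)
    return state


def steady_state(params: SignalingParams, egf: float, igf1: float,
                 igf1ri: float = 0.0) -> dict:
    """Closed-form fixed point of the network at constant inputs.

    With gain g = k/delta, ERK solves the quadratic
    f ERK^2 + (A+d) ERK - g A = 0 from ERK = g A/(A + d + f ERK).
    """
    p = params
    out = {}
    for (A, d, g, r_key, k_key) in (
        (_activation(p.a_E, p.K_E, egf, p.basal), p.d_E,
         p.k_erk / p.delta_erk, "egfr", "erk"),
        (_activation(p.a_I, p.K_I, igf1, p.basal_igf1r) / (1.0 + p.k_igf1ri * igf1ri),
         p.d_I, p.k_akt / p.delta_akt, "igf1r", "akt"),
    ):
        f = p.feedback
        if f > 0 and A > 0:
            kin = (-(A + d) + np.sqrt((A + d) ** 2 + 4.0 * f * g * A)) / (2.0 * f)
        elif A > 0:
            kin = g * A / (A + d)
        else:
            kin = 0.0
        rec = kin / g if g > 0 else (A / (A + d) if A > 0 else 0.0)
        out[r_key] = float(rec)
        out[k_key] = float(kin)
    # receptors share the ERK feedback: recompute IGF1R against the EGF-set ERK
    if p.feedback > 0:
        A_I = _activation(p.a_I, p.K_I, igf1, p.basal_igf1r) / (1.0 + p.k_igf1ri * igf1ri)
        denom = A_I + p.d_I + p.feedback * out["erk"]
        out["igf1r"] = float(A_I / denom) if denom > 0 else 0.0
        out["akt"] = float(p.k_akt / p.delta_akt * out["igf1r"])
    return out


def proliferation_modifier(state: SignalingState, params: SignalingParams):
    """Saturating, increasing proliferation multiplier in [mult_min, mult_max].

    m(s) = m_min + (m_max - m_min) s^n/(s^n + K_s^n) with the half-saturation
    K_s chosen so that m equals exactly 1 at the treatment-naive reference
    drive s_ref; the basal proliferation probability pTC is then realized
    unchanged in an untreated tumor.  The Hill exponent n sets how sharply
    proliferation responds to growth-factor withdrawal.
    """
    p = params
    s = p.alpha_ERK * np.asarray(state.erk) + p.alpha_AKT * np.asarray(state.akt)
    u = (s / p.s_ref) ** p.hill_n
    r = (1.0 - p.mult_min) / (p.mult_max - p.mult_min)
    if not 0 < r < 1:
        raise ValueError("mult_max too small to normalize at s_ref")
    c = r / (1.0 - r)
    return p.mult_min + (p.mult_max - p.mult_min) * c * u / (c * u + 1.0)
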