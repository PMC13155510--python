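"""Microenvironment scale: lattice geometry, vasculature, and reaction-diffusion
dynamics of cytokines (CSF1, EGF, IGF1) and drugs (CSF1R_I, IGF1R_I).

All concentrations are normalized and kept on a regular ``ny x nx`` grid with
grid spacing ``h = 1`` lattice unit (physically ``site_spacing`` micrometres).
Diffusion-reaction dynamics use an explicit forward-time central-space scheme
with zero-flux (Neumann) boundaries; the step sub-cycles automatically whenever
the stability bound ``D*dt/h**2 <= 1/4`` would be violated.

Time is measured in hours throughout the agent-based layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "LatticeConfig",
    "Field",
    "VascularMap",
    "init_vasculature",
    "laplacian",
    "diffuse_react_step",
    "drug_influx_step",
]


@dataclass
class LatticeConfig:
    """Geometry and integration step of the simulated tissue section.

    The default 100x100 grid at 15 um spacing spans a 1.5 mm x 1.5 mm section;
    spatial-transcriptomics-style initialisation uses 60 um spots instead.
    """

    nx: int = 100
    ny: int = 100
    site_spacing: float = 15.0   # micrometres per lattice site
    dt: float = 0.5              # hours
    t_max_days: float = 100.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.site_spacing <= 0:
            raise ValueError("site_spacing must be positive")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny


@dataclass
class Field:
    """One diffusible species on the lattice.

    ``secretion`` and ``consumption`` are per-hour rates keyed by cell-kind
    code; consumption is first order in the local concentration.
    """

    name: str
    values: np.ndarray
    D: float = 1.0               # lattice-units^2 / hour
    decay: float = 0.01          # 1/hour
    secretion: dict = dc_field(default_factory=dict)
    consumption: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.name}: non-finite values")
        if np.any(self.values < 0):
            raise ValueError(f"field {self.name}: negative values")


@dataclass
class VascularMap:
    """Immobile vascular sites with per-site drug-influx weights."""

    mask: np.ndarray             # bool (ny, nx)
    influx_weight: np.ndarray    # float (ny, nx), zero off-mask

    @property
    def n_sites(self) -> int:
        return int(self.mask.sum())


def _boundary_distance(ny: int, nx: int) -> np.ndarray:
    """Chebyshev-style distance from the nearest boundary, normalized to [0, 1]
    (0 on the boundary, 1 at the domain center)."""
    iy = np.arange(ny)[:, None]
    ix = np.arange(nx)[None, :]
    d = np.minimum(np.minimum(iy, ny - 1 - iy), np.minimum(ix, nx - 1 - ix))
    dmax = max((min(nx, ny) - 1) // 2, 1)
    return np.minimum(d / dmax, 1.0)


def init_vasculature(
    config: LatticeConfig,
    density_profile,
    seed: int,
    influx_weight: float = 1.0,
) -> VascularMap:
    """Randomly place vascular sites with density decreasing from the boundary
    toward the center.

    ``density_profile(d)`` maps the normalized distance-from-boundary
    ``d in [0, 1]`` to a per-site occupation probability; it must be
    nonnegative and nonincreasing in ``d`` (denser at the edges).
    """
    d = _boundary_distance(config.ny, config.nx)
    prob = np.asarray(density_profile(d), dtype=float)
    if prob.shape != d.shape:
        prob = np.broadcast_to(prob, d.shape).astype(float)
    if np.any(prob < 0):
        raise ValueError("density_profile must be nonnegative")
    if np.any(prob > 1):
        raise ValueError("density_profile must be a probability (<= 1)")
    # check monotonicity on the radial axis
    dd = np.linspace(0, 1, 64)
    pp = np.asarray(density_profile(dd), dtype=float)
    if np.any(np.diff(pp) > 1e-12):
        raise ValueError("density_profile must be nonincreasing from boundary inward")
    rng = np.random.default_rng(seed)
    mask = rng.random(d.shape) < prob
    weight = np.where(mask, float(influx_weight), 0.0)
    return VascularMap(mask=mask, influx_weight=weight)


def laplacian(values: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with zero-flux (Neumann) boundaries, h = 1."""
    p = np.pad(values, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * values)


def diffuse_react_step(field: Field, kind_grid: np.ndarray, dt: float,
                       extra_source: np.ndarray | None = None) -> Field:
    """Advance one reaction-diffusion step (in place) and return the field.

    dc/dt = D lap(c) + sum_k s_k 1[kind=k] + extra_source
            - sum_k q_k 1[kind=k] c - decay c

    ``extra_source`` covers spatially varying secretion (e.g. IGF1 release by
    M2 macrophages scaled by their cumulative drug exposure).  Sub-cycles
    internally so each explicit sub-step satisfies D*dt' <= 1/4.
    """
    field.validate()
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_sub = 1
    if field.D > 0:
        n_sub = max(1, int(np.ceil(field.D * dt / 0.25)))
    sub_dt = dt / n_sub

    source = np.zeros_like(field.values)
    if extra_source is not None:
        source += extra_source
    sink_rate = np.zeros_like(field.values)
    for kind, rate in field.secretion.items():
        if rate:
            source[kind_grid == kind] += rate
    for kind, rate in field.consumption.items():
        if rate:
            sink_rate[kind_grid == kind] += rate

    c = field.values
    for _ in range(n_sub):
        c = c + sub_dt * (field.D * laplacian(c) + source - sink_rate * c - field.decay * c)
        np.clip(c, 0.0, None, out=c)
    field.values = c
    return field


def drug_influx_step(field: Field, vasc: VascularMap, dose: float, dt: float) -> Field:
    """Add drug at vascular sites: values += dose * influx_weight * dt.

    ``dose`` is the normalized administered dose in [0, 1]; applied before the
    diffusion step of the same time step.
    """
    if not (0.0 <= dose <= 1.0):
        raise ValueError("dose must be in [0, 1]")
    if dose > 0:
        field.values = field.values + dose * vasc.influx_weight * dt
    return field
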