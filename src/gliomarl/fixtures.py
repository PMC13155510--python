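"""Synthetic fixtures: density maps emulating spatial-transcriptomics-derived
tumor microenvironments, and toy survival cohorts with known event-time laws.

The density-map generator produces per-site proportions for tumor cells
(central Gaussian mass), M1 and M2 macrophages (peripheral halo, mostly M2)
suitable for :func:`gliomarl.engine.init_from_density_maps`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "generate_density_maps", "generate_toy_cohort"]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic tumor/macrophage proportion maps."""

    ny: int = 50
    nx: int = 50
    core_radius: float = 0.35     # tumor-core radius, fraction of half-width
    halo_width: float = 0.12      # macrophage-halo width, fraction of half-width
    m1_fraction: float = 0.15     # M1 share of the macrophage halo
    noise: float = 0.05           # multiplicative lognormal-ish jitter

    def __post_init__(self) -> None:
        if not (0 < self.core_radius < 1 and 0 < self.halo_width < 1):
            raise ValueError("core_radius and halo_width must be in (0, 1)")
        if not 0 <= self.m1_fraction <= 1:
            raise ValueError("m1_fraction must be in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def generate_density_maps(spec: FixtureSpec, seed: int):
    """Deterministic synthetic (tc_map, m1_map, m2_map) proportion maps.

    The tumor is a central Gaussian disc; macrophages form a ring just
    outside the core with the configured M1/M2 split.  With ``noise = 0``
    the maps are radially symmetric.
    """
    rng = np.random.default_rng(seed)
    ny, nx = spec.ny, spec.nx
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    half = min(cy, cx)
    r = np.hypot(yy - cy, xx - cx) / half

    tc = np.exp(-0.5 * (r / spec.core_radius) ** 4)       # flat core, steep edge
    ring = np.exp(-0.5 * ((r - spec.core_radius - spec.halo_width / 2)
                          / spec.halo_width) ** 2)
    tam = 0.9 * ring
    if spec.noise > 0:
        tc = tc * np.exp(spec.noise * rng.standard_normal(tc.shape))
        tam = tam * np.exp(spec.noise * rng.standard_normal(tam.shape))
    tc = np.clip(tc, 0.0, 1.0)
    tam = np.clip(tam, 0.0, 1.0 - tc)                     # proportions sum <= 1
    m1 = spec.m1_fraction * tam
    m2 = (1.0 - spec.m1_fraction) * tam
    return tc, m1, m2


def generate_toy_cohort(n: int, rate_per_day: float, horizon_days: float,
                        seed: int) -> pd.DataFrame:
    """Exponential event times at ``rate_per_day``, censored at the horizon.

    Returns a tidy frame with columns (time, event); the survival function
    of the underlying law is exp(-rate * t), which a Kaplan-Meier fit
    should recover within sampling error.
    """
    if n < 1 or rate_per_day <= 0 or horizon_days <= 0:
        raise ValueError("need n >= 1, positive rate and horizon")
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate_per_day, size=n)
    event = t <= horizon_days
    t = np.minimum(t, horizon_days)
    return pd.DataFrame({"time": t, "event": event})
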