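"""Outcome analysis: survival statistics, sensitivity indices and spatial
point-pattern statistics.

Survival conventions: an individual "dies" (or relapses) at the first time
its normalized tumor-cell density reaches the threshold ``THR = 0.896``;
individuals still below the threshold at the horizon are right-censored.
Percent survival is the plain fraction-alive curve ``(1 - d(t)/N) * 100``;
the Kaplan-Meier product-limit estimator handles interval censoring and the
two coincide in the absence of censoring before t.

The log-rank statistic uses the variance form V = sum_j d_j^2 / n_j *
(N - n_j)/(N - 1); a ``textbook`` flag selects the classical hypergeometric
variance for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

THR = 0.896   # death / recurrence threshold on normalized TC density

__all__ = [
    "THR",
    "SurvivalRecord",
    "survival_time",
    "records_from_cohort",
    "km_estimator",
    "percent_survival",
    "logrank_p",
    "significance_stars",
    "sensitivity_index",
    "annd",
    "nni",
    "phagocytosis_rate",
    "moran_index",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's survival (or recurrence) time.

    ``event`` is True for an observed death/recurrence; False means the
    individual was censored at ``time`` (alive at the horizon).
    """

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


def survival_time(tc_density, times, thr: float = THR):
    """First time the density series reaches ``thr``; None if censored.

    Densities are normalized to the nominal carrying capacity and may
    slightly exceed 1 when the realized occupancy outgrows it; negative
    values are rejected.  The time of the first sample >= thr is returned
    (linear scan semantics on the sampled grid).
    """
    c = np.asarray(tc_density, dtype=float)
    t = np.asarray(times, dtype=float)
    if c.size == 0:
        raise ValueError("empty density series")
    if np.any(c < 0) or np.any(c > 1.5):
        raise ValueError("densities must be nonnegative and near [0, 1]")
    hit = np.flatnonzero(c >= thr)
    if hit.size == 0:
        return None
    return float(t[hit[0]])


def records_from_cohort(cohort, thr: float = THR, horizon: float | None = None):
    """Survival records for every individual of a cohort result."""
    horizon = float(cohort.times_days[-1]) if horizon is None else horizon
    out = []
    for row in np.atleast_2d(cohort.tc_density):
        td = survival_time(row, cohort.times_days, thr)
        if td is None or td > horizon:
            out.append(SurvivalRecord(time=horizon, event=False))
        else:
            out.append(SurvivalRecord(time=td, event=True))
    return out


def _event_table(records):
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if np.any(times <= 0):
        raise ValueError("nonpositive survival time")
    uniq = np.unique(times[events])
    n_at_risk, n_events = [], []
    for t in uniq:
        n_at_risk.append(int(np.sum(times >= t)))
        n_events.append(int(np.sum(events & (times == t))))
    return uniq, np.array(n_at_risk), np.array(n_events)


def km_estimator(records):
    """Kaplan-Meier product-limit estimator.

    Returns (event_times, S_hat) with S right-continuous, nonincreasing and
    S(0) = 1; the arrays cover the distinct event times.
    """
    if not records:
        raise ValueError("need at least one record")
    t, n, d = _event_table(records)
    if t.size == 0:
        return np.array([0.0]), np.array([1.0])
    surv = np.cumprod(1.0 - d / n)
    return np.concatenate([[0.0], t]), np.concatenate([[1.0], surv])


def km_at(records, query_times):
    """Evaluate the KM curve at arbitrary times."""
    t, s = km_estimator(records)
    idx = np.clip(np.searchsorted(t, np.asarray(query_times, float),
                                  side="right") - 1, 0, len(s) - 1)
    return s[idx]


def percent_survival(records, N: int | None = None, query_times=None):
    """Percent-survival curve S_p(t) = (1 - d(t)/N) * 100.

    ``d(t)`` counts observed deaths up to and including t.  With no
    censoring before t this equals 100 * KM(t).
    """
    N = len(records) if N is None else N
    times = np.array([r.time for r in records if r.event], dtype=float)
    if query_times is None:
        query_times = np.unique(np.concatenate([[0.0], times]))
    q = np.asarray(query_times, dtype=float)
    d = (times[None, :] <= q[:, None]).sum(axis=1)
    if np.any(d > N):
        raise ValueError("more deaths than individuals")
    return q, (1.0 - d / N) * 100.0


def logrank_p(group_a, group_b, textbook: bool = False):
    """Two-sample log-rank test, p = 2*(1 - Phi(|Z|)).

    Z = (O - E)/sqrt(V) where O and E are observed and expected deaths in
    group A accumulated over the pooled event times.  The default variance
    is V = sum_j d_j^2/n_j * (N - n_j)/(N - 1) with n_j the group-A risk set
    and N the pooled risk set at event time j; ``textbook=True`` uses the
    classical hypergeometric form instead.

    Returns (p_value, Z); degenerate tables (zero variance) report p = 1.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta = np.array([r.time for r in group_a]); ea = np.array([r.event for r in group_a])
    tb = np.array([r.time for r in group_b]); eb = np.array([r.event for r in group_b])
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in all_t:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        n = na + nb
        if n < 2:
            continue
        da = np.sum(ea & (ta == t))
        db = np.sum(eb & (tb == t))
        d = da + db
        O += da
        E += d * na / n
        if textbook:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        else:
            V += d**2 / na * ((n - na) / (n - 1)) if na > 0 else 0.0
    if V <= 0:
        return 1.0, 0.0
    Z = (O - E) / np.sqrt(V)
    p = 2.0 * (1.0 - norm.cdf(abs(Z)))
    return float(p), float(Z)


def significance_stars(p: float) -> str:
    """Log-rank significance convention: *** p<0.01, ** p<0.05, * p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def sensitivity_index(baseline_records, perturbed_records,
                      rel_change: float = 0.1):
    """Normalized mean-survival-time elasticity of a parameter perturbation.

    index = (mean Td perturbed - mean Td baseline) /
            (mean Td baseline * rel_change)

    Positive values indicate that the perturbation extends survival.
    Censored individuals contribute their censoring time (a conservative
    lower bound on Td).  Returns (index, logrank p).
    """
    tb = np.array([r.time for r in baseline_records], dtype=float)
    tp = np.array([r.time for r in perturbed_records], dtype=float)
    if tb.size != tp.size:
        import warnings
        warnings.warn("unmatched cohort sizes in sensitivity comparison")
    idx = (tp.mean() - tb.mean()) / (tb.mean() * rel_change)
    p, _ = logrank_p(baseline_records, perturbed_records)
    return float(idx), p


# --------------------------------------------------------------------------
# spatial statistics
# --------------------------------------------------------------------------

def annd(source_pts, target_pts):
    """Average nearest-neighbor distance from each source to the target set,
    in lattice units.  Undefined (None) for an empty target set."""
    src = np.atleast_2d(np.asarray(source_pts, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_pts, dtype=float))
    if tgt.size == 0:
        return None
    if src.size == 0:
        raise ValueError("no source points")
    d, _ = cKDTree(tgt).query(src, k=1)
    return float(np.mean(d))


def nni(points, area: float):
    """Nearest-neighbor index: observed mean NN distance over the value
    expected under complete spatial randomness, 0.5/sqrt(n/area).

    < 1 indicates clustering, ~1 spatial randomness.  Undefined for n < 2.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        return None
    if area <= 0:
        raise ValueError("area must be positive")
    d, _ = cKDTree(pts).query(pts, k=2)
    observed = float(np.mean(d[:, 1]))
    expected = 0.5 / np.sqrt(n / area)
    return observed / expected


def phagocytosis_rate(events: pd.DataFrame, t_start: float, t_end: float):
    """Percent of M1 step-opportunities in the window that ended in a
    tumor-cell phagocytosis: 100 * phago_tc / m1_steps."""
    w = events[(events["t_days"] >= t_start) & (events["t_days"] <= t_end)]
    opp = w["m1_steps"].sum()
    if opp == 0:
        return None
    return 100.0 * w["phago_tc"].sum() / opp


def moran_index(indicator: np.ndarray):
    """Moran's I of a binary/continuous lattice field with queen adjacency.

    Undefined (None) for a constant field.  The CSR null expectation is
    -1/(n-1).
    """
    x = np.asarray(indicator, dtype=float)
    z = x - x.mean()
    if np.allclose(z, 0):
        return None
    num = 0.0
    W = 0.0
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dy, dx in shifts:
        zs = np.roll(np.roll(z, dy, axis=0), dx, axis=1)
        valid = np.ones_like(z, dtype=bool)
        if dy == 1:
            valid[0, :] = False
        elif dy == -1:
            valid[-1, :] = False
        if dx == 1:
            valid[:, 0] = False
        elif dx == -1:
            valid[:, -1] = False
        num += np.sum(z * zs * valid)
        W += valid.sum()
    n = z.size
    return float((n / W) * num / np.sum(z**2))
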