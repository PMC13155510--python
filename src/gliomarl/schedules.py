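"""Treatment schedules: per-drug piecewise-constant normalized dose d(t).

Time is in days here (the clinical scale); the engine converts to hours.
Doses are normalized to [0, 1].  Schedules serialize to/from tidy CSV with
columns (t_start, t_end, drug, dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DRUGS = ("CSF1R_I", "IGF1R_I")

__all__ = ["DRUGS", "TreatmentSchedule", "make_schedule"]


@dataclass
class TreatmentSchedule:
    """Piecewise-constant dose functions for the two drugs.

    ``changepoints[drug]`` is a nondecreasing array of times (days) starting
    at 0 and ``doses[drug]`` the dose holding from each changepoint to the
    next.
    """

    horizon_days: float
    changepoints: dict = field(default_factory=dict)
    doses: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug in DRUGS:
            t = np.asarray(self.changepoints.get(drug, [0.0]), dtype=float)
            d = np.asarray(self.doses.get(drug, [0.0]), dtype=float)
            if t[0] != 0.0:
                t = np.concatenate([[0.0], t])
                d = np.concatenate([[0.0], d])
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{drug}: changepoints must be nondecreasing")
            if t.shape != d.shape:
                raise ValueError(f"{drug}: changepoints and doses differ in length")
            if np.any((d < 0) | (d > 1)):
                raise ValueError(f"{drug}: doses must lie in [0, 1]")
            self.changepoints[drug] = t
            self.doses[drug] = d

    def dose(self, drug: str, t_days):
        """Dose of ``drug`` at time(s) ``t_days`` (right-continuous)."""
        t = np.asarray(t_days, dtype=float)
        cp = self.changepoints[drug]
        i = np.clip(np.searchsorted(cp, t, side="right") - 1, 0, len(cp) - 1)
        out = self.doses[drug][i]
        return float(out) if np.isscalar(t_days) else out

    def total_dose(self, drug: str | None = None) -> float:
        """Integral of dose over the horizon (dose-days)."""
        if drug is None:
            return sum(self.total_dose(d) for d in DRUGS)
        cp = np.concatenate([self.changepoints[drug], [self.horizon_days]])
        return float(np.sum(self.doses[drug] * np.diff(cp)))

    def all_changepoints(self) -> np.ndarray:
        return np.unique(np.concatenate([self.changepoints[d] for d in DRUGS]))

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for drug in DRUGS:
            cp = np.concatenate([self.changepoints[drug], [self.horizon_days]])
            for t0, t1, d in zip(cp[:-1], cp[1:], self.doses[drug]):
                rows.append(dict(t_start=t0, t_end=t1, drug=drug, dose=d))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TreatmentSchedule":
        horizon = float(df["t_end"].max())
        cps, doses = {}, {}
        for drug, sub in df.groupby("drug"):
            sub = sub.sort_values("t_start")
            cps[drug] = sub["t_start"].to_numpy(dtype=float)
            doses[drug] = sub["dose"].to_numpy(dtype=float)
        return cls(horizon_days=horizon, changepoints=cps, doses=doses)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "TreatmentSchedule":
        return cls.from_frame(pd.read_csv(path))


def _single(drug: str, segments, horizon: float) -> tuple[dict, dict]:
    """segments: list of (t_start, dose); holds each dose until the next."""
    t = np.array([s[0] for s in segments], dtype=float)
    d = np.array([s[1] for s in segments], dtype=float)
    cps = {dr: np.array([0.0]) for dr in DRUGS}
    doses = {dr: np.array([0.0]) for dr in DRUGS}
    cps[drug], doses[drug] = t, d
    return cps, doses


def _merge(a: TreatmentSchedule, b: TreatmentSchedule,
           horizon: float) -> TreatmentSchedule:
    cps, doses = {}, {}
    for drug in DRUGS:
        grid = np.unique(np.concatenate(
            [a.changepoints[drug], b.changepoints[drug]]))
        cps[drug] = grid
        doses[drug] = np.clip(a.dose(drug, grid) + b.dose(drug, grid), 0, 1)
    return TreatmentSchedule(horizon_days=horizon, changepoints=cps, doses=doses)


def make_schedule(kind: str, horizon_days: float = 200.0, **kw) -> TreatmentSchedule:
    """Build a schedule of one of the archetypes used in treatment studies.

    kinds: ``continuous``, ``cyclic``, ``cut``, ``switch``, ``add``, ``none``
    and presets ``preset:csf1ri_only``, ``preset:igf1ri_only``,
    ``preset:combo``, ``preset:optimal_rl``.
    """
    H = float(horizon_days)
    if kind.startswith("preset:"):
        name = kind.split(":", 1)[1]
        if name == "csf1ri_only":
            # continuous CSF1R_I at 0.7 (dose-matched to the optimized schedule)
            return make_schedule("continuous", H, drug="CSF1R_I", dose=0.7)
        if name == "igf1ri_only":
            # no drug for 4 weeks, then continuous IGF1R_I at 1.0
            cps, doses = _single("IGF1R_I", [(0.0, 0.0), (28.0, 1.0)], H)
            return TreatmentSchedule(H, cps, doses)
        if name == "combo":
            return _merge(make_schedule("preset:csf1ri_only", H),
                          make_schedule("preset:igf1ri_only", H), H)
        if name == "optimal_rl":
            # continuous CSF1R_I ending after week 20; IGF1R_I from week 5 on
            cps = {"CSF1R_I": np.array([0.0, 140.0]),
                   "IGF1R_I": np.array([0.0, 35.0])}
            doses = {"CSF1R_I": np.array([1.0, 0.0]),
                     "IGF1R_I": np.array([0.0, 1.0])}
            return TreatmentSchedule(H, cps, doses)
        raise ValueError(f"unknown preset {name!r}")

    if kind == "none":
        return TreatmentSchedule(H)
    if kind == "continuous":
        drug = kw.get("drug", "CSF1R_I")
        dose = float(kw.get("dose", 1.0))
        start = float(kw.get(
            "t_start", 0.0))
        segs = [(0.0, 0.0), (start, dose)] if start > 0 else [(0.0, dose)]
        cps, doses = _single(drug, segs, H)
        return TreatmentSchedule(H, cps, doses)
    if kind == "cut":
        drug = kw.get("drug", "CSF1R_I")
        dose = float(kw.get("dose", 1.0))
        stop = float(kw["t_stop"])
        cps, doses = _single(drug, [(0.0, dose), (stop, 0.0)], H)
        return TreatmentSchedule(H, cps, doses)
    if kind == "cyclic":
        drug = kw.get("drug", "CSF1R_I")
        dose = float(kw.get("dose", 1.0))
        on, off = float(kw["on_days"]), float(kw["off_days"])
        segs, t = [], 0.0
        while t < H:
            segs.append((t, dose))
            segs.append((min(t + on, H), 0.0))
            t += on + off
        cps, doses = _single(drug, segs, H)
        return TreatmentSchedule(H, cps, doses)
    if kind == "switch":
        # continuous CSF1R_I for 4 weeks, then switch to continuous IGF1R_I
        t_sw = float(kw.get("t_switch", 28.0))
        cps = {"CSF1R_I": np.array([0.0, t_sw]),
               "IGF1R_I": np.array([0.0, t_sw])}
        doses = {"CSF1R_I": np.array([float(kw.get("dose_csf1ri", 1.0)), 0.0]),
                 "IGF1R_I": np.array([0.0, float(kw.get("dose_igf1ri", 1.0))])}
        return TreatmentSchedule(H, cps, doses)
    if kind == "add":
        # overlapped combination: continuous CSF1R_I plus IGF1R_I added later
        t_add = float(kw.get("t_add", 28.0))
        a = make_schedule("continuous", H, drug="CSF1R_I",
                          dose=kw.get("dose_csf1ri", 1.0))
        b = make_schedule("continuous", H, drug="IGF1R_I",
                          dose=kw.get("dose_igf1ri", 1.0), t_start=t_add)
        return _merge(a, b, H)
    raise ValueError(f"unknown schedule kind {kind!r}")
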