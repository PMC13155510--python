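"""Surrogate-driven actor-critic optimisation of weekly combination
schedules.

The environment rolls the Fokker-Planck surrogate forward one decision
interval at a time.  The state is the full time series of (percent
survival, change in percent survival) pairs observed so far; an LSTM
feature extractor summarises it into a 4-dimensional feature vector feeding
a 4-way softmax actor (binary on/off dose per drug) and a scalar critic.
Episodes start with a fixed 4-week continuous CSF1R_I lead-in and end at
week 28.

Training follows the asynchronous advantage actor-critic scheme: workers
roll episodes against their own environment copies and apply
entropy-regularised policy-gradient and value updates to the shared global
parameters (Hogwild-style, via threads).  A single worker gives a fully
deterministic run for a fixed seed.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field as dc_field

import numpy as np

from .schedules import TreatmentSchedule, DRUGS
from .surrogate import FPSolver, HybridState, Surrogate, gaussian_p0

__all__ = [
    "ACTIONS",
    "RewardParams",
    "PolicySpec",
    "EnvState",
    "TreatmentEnv",
    "LSTMPolicy",
    "train_a3c",
    "extract_schedule",
    "interval_sweep",
]

# 4 discrete actions: (CSF1R_I on/off, IGF1R_I on/off)
ACTIONS = ((0, 0), (1, 0), (0, 1), (1, 1))

TOTAL_WEEKS = 28
LEADIN_WEEKS = 4


@dataclass
class RewardParams:
    """Reward shaping: survival gain minus dose penalty plus terminal bonus.

    r_t = w_survival * dS_t - w_dose * (d_csf1ri + d_igf1ri) * interval
          + 1[terminal] * w_terminal * S_T/100
    with S in percent and doses in {0, 1}.  The dose weight is tuned so that
    a week of a single drug costs about as much reward as a tenth of a
    percentage point of final population survival.
    """

    w_survival: float = 1.0
    w_dose: float = 0.1
    w_terminal: float = 10.0
    gamma: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        for name in ("w_survival", "w_dose", "w_terminal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PolicySpec:
    """Network and training-run hyperparameters."""

    lstm_hidden: int = 16
    feature_dim: int = 4
    entropy_weight: float = 0.01
    lr: float = 0.01
    value_weight: float = 0.5
    n_workers: int = 1
    n_epochs: int = 2000
    seed: int = 0


@dataclass
class EnvState:
    """Observed series of (survival percent, change in survival percent)."""

    survival: list = dc_field(default_factory=list)
    delta: list = dc_field(default_factory=list)
    week: int = 0

    def series(self) -> np.ndarray:
        """(n, 2) array scaled to O(1): survival/100 and delta/10."""
        s = np.asarray(self.survival, dtype=float) / 100.0
        d = np.asarray(self.delta, dtype=float) / 10.0
        return np.column_stack([s, d])


class TreatmentEnv:
    """Weekly-interval treatment environment on the surrogate model.

    The surrogate state (p.d.f. plus companion ODEs) advances exactly as
    under ``surrogate_predict`` for the equivalent schedule, so a fixed
    action sequence reproduces the schedule-level prediction.
    """

    def __init__(self, surrogate: Surrogate, interval_weeks: int = 4,
                 reward_params: RewardParams | None = None, nc: int = 64,
                 fp_dt: float = 0.5):
        if interval_weeks not in (1, 2, 3, 4):
            raise ValueError("interval_weeks must be 1..4")
        self.surrogate = surrogate
        self.interval = interval_weeks
        self.reward_params = reward_params or RewardParams()
        self.solver = FPSolver(surrogate.params, nc=nc, dt=fp_dt)
        self._leadin = None
        self._cache: dict = {}   # deterministic transition memo, by action prefix
        self.reset()

    # -- internals ---------------------------------------------------------
    def _advance(self, P, h, doses, days: float):
        sched = TreatmentSchedule(
            horizon_days=days,
            changepoints={d: np.array([0.0]) for d in DRUGS},
            doses={"CSF1R_I": np.array([float(doses[0])]),
                   "IGF1R_I": np.array([float(doses[1])])})
        grid = self.solver.run(P, sched, np.array([0.0, days]), h0=h)
        h_new = self._h_after(h, sched, days)
        return grid.P[-1], h_new, float(grid.absorbed[-1]), float(grid.cured[-1])

    def _h_after(self, h, sched, days):
        from .surrogate import hybrid_trajectory
        hyb = hybrid_trajectory(self.surrogate.params, sched,
                                np.array([0.0, days]), h0=h)
        return HybridState(hyb["d_csf1ri"][-1], hyb["d_igf1ri"][-1],
                           hyb["exposure"][-1], hyb["c_m1"][-1])

    # -- gym-style API ------------------------------------------------------
    def reset(self) -> EnvState:
        """Roll the fixed 4-week continuous CSF1R_I lead-in."""
        if self._leadin is None:
            P = gaussian_p0(self.solver.c)
            h = HybridState(c_m1=self.surrogate.params.m1_0)
            dead = cured = 0.0
            state = EnvState()
            surv_prev = 100.0
            for w in range(LEADIN_WEEKS):
                P, h, dead_inc, cured_inc = self._advance(P, h, (1, 0), 7.0)
                dead += dead_inc
                cured += cured_inc
                surv = 100.0 * (1.0 - dead)
                state.survival.append(surv)
                state.delta.append(surv - surv_prev)
                surv_prev = surv
                state.week = w + 1
            self._leadin = (P.copy(), h.copy(), dead, cured,
                            [list(state.survival), list(state.delta)])
        P, h, dead, cured, (sv, dl) = self._leadin
        self.P, self.h = P.copy(), h.copy()
        self.dead, self.cured = dead, cured
        self.state = EnvState(survival=list(sv), delta=list(dl),
                              week=LEADIN_WEEKS)
        self.done = False
        self.actions_taken: list[int] = []
        return self.state

    def step(self, action: int):
        """Apply one action for the next interval; returns
        (state, reward, done)."""
        if self.done:
            raise RuntimeError("episode finished; call reset()")
        doses = ACTIONS[action]
        weeks = min(self.interval, TOTAL_WEEKS - self.state.week)
        surv_before = 100.0 * (1.0 - self.dead)
        key = tuple(self.actions_taken) + (action,)
        hit = self._cache.get(key)
        if hit is None:
            P, h, dead_inc, cured_inc = self._advance(self.P, self.h, doses,
                                                      7.0 * weeks)
            self._cache[key] = (P, h, dead_inc, cured_inc)
        else:
            P, h, dead_inc, cured_inc = hit
        self.P, self.h = P, h
        self.dead += dead_inc
        self.cured += cured_inc
        surv = 100.0 * (1.0 - self.dead)
        self.state.survival.append(surv)
        self.state.delta.append(surv - surv_before)
        self.state.week += weeks
        self.actions_taken.append(action)
        rp = self.reward_params
        reward = rp.w_survival * (surv - surv_before) \
            - rp.w_dose * (doses[0] + doses[1]) * weeks
        self.done = self.state.week >= TOTAL_WEEKS
        if self.done:
            reward += rp.w_terminal * surv / 100.0
        return self.state, float(reward), self.done

    @property
    def n_decisions(self) -> int:
        return int(np.ceil((TOTAL_WEEKS - LEADIN_WEEKS) / self.interval))

    def schedule_from_actions(self, actions) -> TreatmentSchedule:
        """The piecewise-constant schedule equivalent to an action sequence
        (including the lead-in)."""
        cps = {d: [0.0] for d in DRUGS}
        doses = {"CSF1R_I": [1.0], "IGF1R_I": [0.0]}
        week = LEADIN_WEEKS
        for a in actions:
            weeks = min(self.interval, TOTAL_WEEKS - week)
            for drug, lvl in zip(DRUGS, ACTIONS[a]):
                cps[drug].append(week * 7.0)
                doses[drug].append(float(lvl))
            week += weeks
        return TreatmentSchedule(
            horizon_days=TOTAL_WEEKS * 7.0,
            changepoints={d: np.asarray(cps[d]) for d in DRUGS},
            doses={d: np.asarray(doses[d]) for d in DRUGS})


# --------------------------------------------------------------------------
# LSTM actor-critic
# --------------------------------------------------------------------------

def _softmax(z):
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class LSTMPolicy:
    """LSTM feature extractor + linear actor (softmax over 4 actions) and
    critic heads, with hand-written backpropagation through time."""

    def __init__(self, spec: PolicySpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        H, F = spec.lstm_hidden, spec.feature_dim
        d_in = 2
        s = 1.0 / np.sqrt(H + d_in)
        self.p = {
            "Wx": rng.uniform(-s, s, (d_in, 4 * H)),
            "Wh": rng.uniform(-s, s, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wf": rng.uniform(-s, s, (H, F)),
            "bf": np.zeros(F),
            "Wa": rng.uniform(-s, s, (F, len(ACTIONS))),
            "ba": np.zeros(len(ACTIONS)),
            "Wc": rng.uniform(-s, s, (F, 1)),
            "bc": np.zeros(1),
        }
        # forget-gate bias init at 1 for stable memory
        H_ = H
        self.p["b"][H_:2 * H_] = 1.0

    def param_names(self):
        return list(self.p)

    def forward(self, series: np.ndarray):
        """Full forward pass over a (n, 2) series.

        Returns (action probabilities, value, cache for backprop).
        """
        H = self.spec.lstm_hidden
        h = np.zeros(H)
        c = np.zeros(H)
        steps = []
        for x in series:
            z = x @ self.p["Wx"] + h @ self.p["Wh"] + self.p["b"]
            i = 1 / (1 + np.exp(-z[:H]))
            f = 1 / (1 + np.exp(-z[H:2 * H]))
            o = 1 / (1 + np.exp(-z[2 * H:3 * H]))
            g = np.tanh(z[3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append((x, h, c, i, f, o, g, c_new))
            h, c = h_new, c_new
        zf = h @ self.p["Wf"] + self.p["bf"]
        feat = np.tanh(zf)
        logits = feat @ self.p["Wa"] + self.p["ba"]
        probs = _softmax(logits)
        value = float((feat @ self.p["Wc"])[0] + self.p["bc"][0])
        cache = (steps, h, feat)
        return probs, value, cache

    def backward(self, cache, dlogits, dvalue):
        """Gradients for d(loss)/d(logits) and d(loss)/d(value)."""
        H = self.spec.lstm_hidden
        steps, h_last, feat = cache
        g = {k: np.zeros_like(v) for k, v in self.p.items()}
        dfeat = dlogits @ self.p["Wa"].T + dvalue * self.p["Wc"][:, 0]
        g["Wa"] += np.outer(feat, dlogits)
        g["ba"] += dlogits
        g["Wc"] += dvalue * feat[:, None]
        g["bc"] += np.array([dvalue])
        dzf = dfeat * (1 - feat**2)
        g["Wf"] += np.outer(h_last, dzf)
        g["bf"] += dzf
        dh = dzf @ self.p["Wf"].T
        dc = np.zeros(H)
        for (x, h_prev, c_prev, i, f, o, gg, c_new) in reversed(steps):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                do * o * (1 - o),
                dg * (1 - gg**2),
            ])
            g["Wx"] += np.outer(x, dz)
            g["Wh"] += np.outer(h_prev, dz)
            g["b"] += dz
            dh = dz @ self.p["Wh"].T
            dc = dc * f
        return g

    def act(self, series, rng: np.random.Generator, greedy: bool = False):
        probs, value, cache = self.forward(series)
        if greedy:
            a = int(np.argmax(probs))
        else:
            a = int(rng.choice(len(ACTIONS), p=probs))
        return a, probs, value, cache


def _episode_grads(policy: LSTMPolicy, env: TreatmentEnv,
                   reward_params: RewardParams, rng) -> tuple[dict, float]:
    """One rollout; returns summed gradients and the episode return."""
    spec = policy.spec
    state = env.reset()
    traj = []
    done = False
    while not done:
        series = state.series()
        a, probs, value, cache = policy.act(series, rng)
        state, r, done = env.step(a)
        traj.append((series, a, probs, value, cache, r))
    # n-step returns over the whole episode remainder
    G = 0.0
    grads = {k: np.zeros_like(v) for k, v in policy.p.items()}
    total = 0.0
    for (series, a, probs, value, cache, r) in reversed(traj):
        G = r + reward_params.gamma * G
        total += r
        adv = G - value
        # policy loss: -log pi(a) * adv - entropy_weight * H(pi)
        dlogits = probs.copy()
        dlogits[a] -= 1.0          # d(-log pi_a)/dlogits
        dlogits *= adv
        # entropy gradient: dH/dlogits = -p * (log p + H)
        ent = -np.sum(probs * np.log(probs + 1e-12))
        dlogits += spec.entropy_weight * probs * (np.log(probs + 1e-12) + ent)
        dvalue = spec.value_weight * 2.0 * (value - G)
        g = policy.backward(cache, dlogits, dvalue)
        for k in grads:
            grads[k] += g[k]
    return grads, total


def train_a3c(env_factory, spec: PolicySpec,
              reward_params: RewardParams | None = None,
              epochs: int | None = None, seed: int | None = None):
    """Asynchronous advantage actor-critic training.

    ``env_factory()`` builds an environment per worker.  Workers apply
    RMSprop-style updates to the shared parameters without locking; with
    one worker the run is deterministic for a fixed seed.  Returns
    (policy, per-epoch return history).
    """
    reward_params = reward_params or RewardParams()
    epochs = spec.n_epochs if epochs is None else epochs
    seed = spec.seed if seed is None else seed
    policy = LSTMPolicy(spec)
    ms = {k: np.zeros_like(v) for k, v in policy.p.items()}
    history = []
    hist_lock = threading.Lock()
    counter = {"n": 0}

    def worker(wid: int):
        env = env_factory()
        rng = np.random.default_rng(np.random.SeedSequence([seed, wid]))
        while True:
            with hist_lock:
                if counter["n"] >= epochs:
                    return
                counter["n"] += 1
            grads, ret = _episode_grads(policy, env, reward_params, rng)
            if not all(np.all(np.isfinite(g)) for g in grads.values()):
                continue               # skip the incident, keep training
            for k, gk in grads.items():
                np.clip(gk, -5.0, 5.0, out=gk)
                ms[k] = 0.99 * ms[k] + 0.01 * gk * gk
                policy.p[k] -= spec.lr * gk / (np.sqrt(ms[k]) + 1e-6)
            with hist_lock:
                history.append(ret)

    if spec.n_workers <= 1:
        worker(0)
    else:
        threads = [threading.Thread(target=worker, args=(w,))
                   for w in range(spec.n_workers)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
    return policy, np.asarray(history)


def extract_schedule(policy: LSTMPolicy, env: TreatmentEnv):
    """Greedy (arg-max) rollout of the trained policy.

    Returns (schedule, final percent survival, action list).
    """
    state = env.reset()
    rng = np.random.default_rng(0)
    done = False
    while not done:
        a, *_ = policy.act(state.series(), rng, greedy=True)
        state, _, done = env.step(a)
    sched = env.schedule_from_actions(env.actions_taken)
    return sched, state.survival[-1], list(env.actions_taken)


def interval_sweep(surrogate: Surrogate, spec: PolicySpec,
                   reward_params: RewardParams | None = None,
                   intervals=(1, 2, 3, 4), epochs: int | None = None):
    """Train one policy per decision interval and compare the optima.

    Returns a list of dicts with interval, final survival, total dose and
    the extracted schedule; longer intervals shorten the decision series.
    """
    rows = []
    for k in intervals:
        env_factory = lambda k=k: TreatmentEnv(surrogate, interval_weeks=k,
                                               reward_params=reward_params)
        policy, hist = train_a3c(env_factory, spec, reward_params,
                                 epochs=epochs)
        env = env_factory()
        sched, surv, actions = extract_schedule(policy, env)
        rows.append(dict(interval_weeks=k, final_survival=surv,
                         total_dose=sched.total_dose(),
                         n_decisions=env.n_decisions,
                         actions=actions, schedule=sched,
                         mean_return_tail=float(np.mean(hist[-100:]))
                         if len(hist) else np.nan))
    return rows
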