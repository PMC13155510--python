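# Methods

This note records the model equations, the defaults and their calibration,
the numerical choices, and the known limitations of the package.

## 1. Agent-based model

### Geometry and fields

The tumor microenvironment is a `ny x nx` lattice (default profile used
throughout the shipped calibration: 50x50 sites at 15 µm, time step 1 h; a
100x100 / 0.5 h geometry is available but the agent rates below are
calibrated at the desk profile — see §5). Five diffusible species evolve by

    dc/dt = D ∇²c + Σ_k s_k·1[kind=k] − Σ_k q_k·1[kind=k]·c − λc,

solved explicitly (forward-time central-space) with zero-flux boundaries and
automatic sub-cycling to keep `D·dt ≤ 1/4`. Zero-flux makes source-free mass
conservation exact, which the tests exploit. Cytokines (CSF1 by tumor
cells, EGF by M2) use `D = 2 sites²/h`, secretion = decay = 0.02/h, so a
site inside a dense secreting mass equilibrates near concentration 1 (CSF1
≈ 1 at the tumor core). Drugs enter at vascular sites (influx weight 0.5
per site per unit dose, `D = 6`, decay 0.02/h) so a sustained full dose
yields an O(1) tissue concentration within ~2 days. IGF1 has no constitutive
source: M2 macrophages secrete it at a rate that saturates in
`alpha_I · k_resist · exposure`, where `exposure = ∫ CSF1R_I dt` is
accumulated per macrophage — the "prolonged use" resistance arm.

Vasculature is sampled once per run: sites occupy with probability
`p0·max(0, 1 − d/band)` where `d` is normalized distance from the boundary
(`p0 = 0.25`, band = 0.15), reproducing a peripheral vascular rim.

### Cell agents

One cell per site. The scheduler is phase-synchronous: per step, quiescence
reversal → division → polarization → phagocytosis → migration → recruitment
→ aging/death, with all eligible agents acting at once and site conflicts
resolved by a uniformly random winner. This replaces a per-agent shuffled
sweep; at the event rates used the two schedules are statistically
indistinguishable, and the phase form vectorises cleanly. Per-step
probabilities are defined at a 0.5 h reference step and rescaled as
`1 − (1−p)^(dt/0.5)`.

Key rules:

* **Division.** An active TC whose cycle (24 h) has elapsed divides with
  probability `min(1, pTC·m)` into a uniformly chosen empty Moore neighbor;
  `pTC = 0.5`; `m` is the signaling multiplier (below). With no empty Moore
  neighbor it becomes quiescent (age and cycle frozen); when space frees it
  reverts and attempts a division in the same step. Stem-lineage
  initialisation: 4 stem cells (double lifespan, half cycle); daughters
  halve lifespan and double cycle until regular values.
* **Polarization.** M1→M2 per step: `kM12·c/(K/alpha_C + c) / (1 +
  KM12d·u) + alpha_I·k_resist·E` (CSF1 Hill term, drug inhibition,
  exposure-driven reversion); M2→M1: `pM21·(1 + KM12d·u)`. `alpha_C`
  divides the half-saturation so that raising it promotes M1→M2
  polarization, matching the reported sensitivity direction.
* **Phagocytosis.** An M1 eats an adjacent TC (preferred) or dead cell with
  probability `pha = 0.16` per step and moves into the vacated site.
* **Migration.** TAMs relocate with probability `DM = 0.35` into an empty
  Von Neumann neighbor weighted `∝ exp(30·CSF1)` (chemotaxis); active TCs
  walk unbiased with probability 0.01.
* **Recruitment.** Per vascular site per step, an M0 is placed on an empty
  neighbor with probability `prec·(0.01 + 0.99·c/(c + 0.05))`, capped at
  the TAM carrying capacity (8% of sites); M0 matures after 24 h into M1
  with probability 0.3, else M2. Gating recruitment almost entirely on
  CSF1 protects the nascent tumor from being eradicated by early wandering
  M1 cells before it can establish — the burn-in is otherwise a race the
  4-cell seed often loses.
* **Death.** Aging cells become dead cells at their lifespan (TC 480 h,
  TAM 2400 h); dead cells clear with probability 0.002 per step.

### Intracellular signaling

Each TC integrates (explicit Euler, 4 substeps)

    dR_E/dt = (a_E E/(K_E+E) + b_E)(1−R_E) − (d_E + f·ERK) R_E
    dR_I/dt = (a_I I/(K_I+I) + b_I)/(1 + k_u u) (1−R_I) − (d_I + f·ERK) R_I
    dERK/dt = k(R_E − ERK),   dAKT/dt = k(R_I − AKT)

with ERK negative feedback `f = 1` shared by both receptors, a basal EGFR
drive `b_E = 0.15/h` (tumor cells proliferate before macrophage-derived EGF
appears) and a small drug-blockable basal IGF1R drive `b_I = 0.08/h`
(gives the IGF1R inhibitor a direct antiproliferative component). The
closed-form fixed point (a quadratic, because of the feedback) is the test
oracle. The division multiplier is a Hill function of the combined drive
`s = alpha_ERK·ERK + alpha_AKT·AKT` with exponent 3, floor 0.12, ceiling
2.0, and half-saturation chosen so `m = 1` exactly at the treatment-naive
operating point — so `pTC` is the realized basal division probability, and
resistance (AKT) can roughly double proliferation.

### Calibration

Supplementary parameter tables of the source study are not public, so the
rate constants above were calibrated against the printed trajectories:
treatment-naive runs from the standardized density 0.58 reach ~0.9 by day
20 with the macrophage pool ~85% M2 / ~15% M1; burn-in from 4 stem cells
reaches 0.58 in ~40–50 days; continuous full-dose CSF1R_I produces a
transient M1 peak ≈ 0.4, early tumor suppression, cured responders and
relapsing nonresponders (survival ≈ 40% of a cohort at day 200); switching
to IGF1R_I at week 4 leaves only a minority alive at week 14. `N_TC^max` is
0.9 of the lattice (realized occupancy can slightly exceed it). Survival
uses the threshold 0.896.

Cohorts sample `alpha_ERK, alpha_C, alpha_I ~ Normal(basal, 0.1·basal)`
(the 0.1 factor taken literally as a variance) truncated at zero, sharing
one frozen burn-in state; `alpha_I` is dimensionless (basal 1) multiplying
the resistance rate `k_resist`, so its sampled spread creates the
responder/nonresponder split.

## 2. Survival statistics

`Td` is the first sampled time the normalized density reaches 0.896;
individuals below it at the horizon are right-censored. Kaplan–Meier and
percent survival are implemented per the product-limit and fraction-alive
formulas and cross-checked against lifelines. The log-rank variance is
implemented as printed, `V = Σ d_j²/n_j (N−n_j)/(N−1)` with `n_j` the
first group's risk set — this form is *not* symmetric under group exchange;
a `textbook=True` flag selects the classical hypergeometric variance
(symmetric, permutation-calibrated) for cross-checks. Sensitivity indices
are normalized mean-survival-time elasticities. Moran's I uses queen
adjacency; note that under queen weights a checkerboard scores near zero
(diagonal neighbors agree) — alternating stripes are the strongly
anticorrelated pattern.

## 3. Fokker–Planck surrogate

The reduction keeps one stochastic state, the normalized TC density, with
drift and diffusion as printed in the README; the printed diffusion
coefficient carries a sign depending on the noise direction and is used as
a magnitude (a diffusion coefficient must be nonnegative), and the
equivalent SDE is integrated with amplitude `√|ν|` so the Euler–Maruyama
ensemble and the Fokker–Planck solution agree (total variation < 0.05 at
10⁴ paths).

The companion ("hybrid") ODEs are re-derivations: drugs relax to the
administered dose at 1/day; exposure accumulates CSF1R_I; the M1 mean obeys
a two-state polarization balance with drug gain/loss factors and an
exposure-driven reversion; the effective growth rate is

    r_eff = r0 · exp(−g_m1·max(0, C_M1 − m1_0)) · (1 + g_res·AKT(E))
               / (1 + g_base·u_IGF1R_I),

where AKT = `E/(E+x_half)` is blocked by the IGF1R inhibitor. The
exponential crowding factor is the mean-field image of the spatial refill
race: abundant M1 at the tumor rim suppress the re-occupation of
phagocytosed sites.

The solver is a conservative Chang–Cooper finite-volume scheme (implicit
Euler, tridiagonal solves, coefficients refreshed every 0.25-day sub-step)
on `c ∈ [0.05, 0.896]`. Both boundaries absorb: mass leaving at 0.896 is
the cumulative death fraction, mass leaving at 0.05 is the cured fraction
(tumor eradication, mirroring the agent-based responders whose tumors
vanish). Without the lower absorbing state, any population mass near zero
would eventually regrow once resistance raises the growth rate and no
schedule could maintain long-run survival. Percent survival = 100·(1 −
dead mass); live + dead + cured sums to 1 to solver precision.

Surrogate defaults were calibrated (grid search over `d_tc, x_half, g_res,
km12d, σ, k_drug`) so the reduced model reproduces the cohort-level
outcomes: all untreated tumors die by ~day 25; continuous CSF1R_I keeps
≈ 40% alive at day 200; the week-4 switch leaves ≈ 20% alive at week 14;
overlapped combinations keep ≥ 92% alive at week 28.

### Physics-informed fit

The approximator `u(t, c; θ)` is a tanh MLP (two 48-unit layers) over a
Fourier feature embedding of (t/T, c) — 8 sine/cosine pairs per coordinate;
small plain-input networks cannot resolve the sharp early-time density
ridge. The loss is mean-squared data misfit over points sampled from the
p.d.f. slices plus the mean-squared PDE residual over collocation points
(oversampled within ±1 day of dose changepoints, where accuracy is
hardest). Residual derivatives use central finite-difference stencils
(0.25 day, 0.01 in c), which keeps the hand-written backpropagation to
plain network evaluations. Training is two-stage — Adam warm-up then
L-BFGS — and deterministic for a fixed spec. The noise amplitude σ* is
refitted at the end in closed form (the residual is affine in σ) with
stencils evaluated on the training surface itself, clamped to at least one
mesh cell; evaluating them on the network instead attenuates σ* severely,
because the network's smooth fitting error masquerades as reduced
diffusion. With that estimator, σ recovery is within a few percent across
noise regimes (identifiability is weakest when σ is so small that the
diffusion term is below the fit error). Prediction for arbitrary schedules
integrates the Fokker–Planck model with the fitted parameters; the network
is the smooth approximation used for fidelity checks.

## 4. Schedule optimisation

The environment advances the surrogate one decision interval at a time
(28-week episodes, 4-week continuous CSF1R_I lead-in, binary per-drug
doses, 1–4-week intervals). The state is the full series of (percent
survival, change) pairs; the policy is an LSTM (16 units) → 4-d feature →
softmax actor + scalar critic, trained with entropy-regularised
advantage policy gradients and RMSprop-style updates; multiple workers
update shared parameters from threads (Hogwild), one worker is
deterministic. Because the environment is deterministic given the action
prefix, transitions are memoised, which makes tens of thousands of
episodes cheap. The reward is `ΔS − 0.1·(doses)·weeks + 10·S_T/100`; the
dose weight is set so a drug-week trades against ~0.1 percentage points of
final survival. At the shipped calibration the learned 4-week policy keeps
both drugs on through mid-course and stops early (final survival ≥ 92% at
roughly half the always-on dose); the printed optimum of the source
framework (CSF1R_I to week 20, IGF1R_I from week 5) is reproduced in shape
— continuous use followed by early stopping — though the learned stopping
point depends on the surrogate's cure kinetics.

## 5. Problem sizes and what the tests show

All shipped numbers use the desk profile: 50x50 lattice, dt = 1 h, cohorts
of 12–16, 10⁴ SDE paths, ~1400 PINN optimisation steps, 6000 training
episodes. Agent-rule rates do not transfer unchanged across lattice sizes
(rim-limited growth scales with perimeter/area), so the 100x100 geometry
requires recalibration — a known limitation. The synthetic-data layers
(burn-in tumor, density-map fixtures, toy cohorts) emulate the geometry and
rates of real microenvironments but none of their molecular heterogeneity;
passing tests demonstrate internal consistency of the model chain, not
clinical validity. Other known limitations: no angiogenesis or vessel
remodeling, a three-phenotype macrophage model, one shared ERK-feedback
constant for both receptors, unbiased TC migration, and a surrogate whose
cure boundary (0.05) is a modeling choice rather than a measured quantity.
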