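# Methods

This note documents the models implemented in `dyadvigor`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations of the published parameter sets the
package ships.

## Solo reaching model

A wrist reach of amplitude `A` (radians, internal unit everywhere; degrees
only at I/O boundaries) is modelled with state `x = (q, q̇, τ)` and control
`u = τ̇` under

    I q̈ = τ − (D + ν) q̇,     I = 9.2e-3 Nm·s²,  D = 0.03 Nm·s,

with viscous load ν ∈ {0, 0.075, 0.15} Nm·s/rad.  The effort cost is
minimum-torque-change with a position-error term,

    E(u; T) = ∫₀ᵀ w_q (q_e − q)² + β u² dt,
    w_q = 15.5 / A,   β = 0.95,

with both boundary states fully pinned at rest (`τ = 0` holds either posture
since only velocity is damped).  Movement duration is valued by the
saturating time cost

    G(t) = p₁ (1 − [1 + (t/p₃)^{p₂}]^{−p₄}),

and the free-final-time problem minimizes `G(T) + E(u; T)`.

### Why no NLP solver

Every fixed-horizon problem above (and the coupled one below) has linear
dynamics and convex quadratic cost, so trapezoidal direct transcription
yields an equality-constrained QP whose KKT system is one sparse symmetric
factorization (`dyadvigor._collocation`).  This is an *exact* solve — no
iteration, no convergence tolerance — and it returns the discrete costates,
from which the Hamiltonian `H = L + p'f` is assembled.  On these problems
the recovered `H` is constant along the trajectory to machine precision and
equals the horizon sensitivity `dE*/dT` (both are asserted by tests).  Node
counts scale with the horizon (≈300 nodes/s, clamped to [120, 1500]) so the
time step stays near 3 ms.

### Free final time

`V(T) = G(T) + E*(T)` is minimized by an outer search on `T ∈ [0.01, 10]` s:
a 48-point log-spaced grid, then a finer linear grid over the near-optimal
region, bounded scalar refinement of every local minimum, and — because
`V(T)` can be multimodal when `G` saturates (long-duration basins where
time is "nearly free" sit within a fraction of a percent of the optimum) —
the **smallest duration among local minima within 1% relative cost of the
best** is returned, with a `multimodal` flag.  The 1% tolerance reflects
that basins this close are physically indistinguishable given the model's
own approximations, while the long-duration basins are artifacts of the
saturating tail.  A dense 1 ms grid scan is the test oracle; agreement is
within 2 ms.

### Cost-of-time identification

At a free-time optimum the transversality condition gives
`G'(T*) = −H(T*)`.  Identification therefore solves the fixed-time problem
at each observed duration `T(A_k)` of an amplitude–duration law, collects
`−H_k`, and fits `g(t; p) = dG/dt` through the five points by multi-start
nonlinear least squares (20 seeded starts; `p₄ ∈ [10⁻⁶, 10]`, optionally
pinned).  Unweighted residuals are the default: they reproduce published
identifications; a magnitude-relative weighting is available for Hamiltonian
sets spanning orders of magnitude.  The identified `G` closes its loop —
forward free-time solves reproduce the input law — to within ≈5% per target
for the average group and ≈0.5% for the fast group (see Limitations for the
slow group).

## Dyadic coordination models

Coupled dynamics for partners `f` and `s`:

    I q̈^f = τ^f − D q̇^f − κ(q^f − q^s) − ν q̇^f     (and symmetrically),

κ ∈ {0.5 (KL), 1.6 (KH)} Nm/rad; the interaction torque is
`τⁱ = κ(q^f − q^s)`.

**Co-activity.**  Each partner tracks their own minimum-jerk plan (duration
from their solo amplitude–duration law; the faster plan held at the target
once complete).  A finite-horizon time-varying LQR on
`(q^f, q̇^f, q^s, q̇^s)` with `Q = diag(100, 0.1, 100, 0.1)`, `R = I₂`
(backward Riccati recursion with affine feedforward, Euler-discretized at
1 kHz) produces the torques; the prediction reports the mean |τⁱ| over the
slow plan's duration.  The dyad's movement completes with the slow plan, so
the co-activity duration prediction equals the slow partner's — which makes
the co-activity and slow-leader duration errors identical by construction,
as observed empirically.

**Leader–follower and weighted adaptation.**  The fast-leader baseline is
the fast group's solo free-time duration under each load.  Slow-partner
durations (the slow-leader baseline and the interactive-adaptation μ_k)
come from the slow group's amplitude–duration law — the slow plan family is
*defined* by the empirical law — inflated by 1.15 (ν = 0.075) and 1.30
(ν = 0.15) on the forward model's stable branch.  Weighted adaptation is the
convex combination `α T_f + (1−α) T_s`, default α = 0.5.

**Interactive adaptation.**  The slow partner is a family of minimum-jerk
trajectories of random duration `ξ_k` with mean μ_k and deviation σ_k (no
further distributional assumption enters the cost; sampling oracles use a
truncated normal with support > 0.05 s).  Linearizing the slow velocity in
ξ about μ and dropping cross-covariance terms, the dyad minimizes the
deterministic-equivalent cost

    C(u, T) = E(u; T) + G_fast(T)
            + Q_τ κ² ∫₀ᵀ (q̇^f − q̇^s(μ))² + P_q̇ + (∂q̇^s/∂ξ|_μ)² σ² dt,

with `Q_τ = 3` across all 30 conditions and σ_k spread linearly over the
targets within [0.15, 0.25] s (no load), [0.2, 0.3] s (low load) and
[0.32, 0.4] s (high load).  The mean slow trajectory enters the fast-side
dynamics through the coupling, so the inner fixed-`T` problem is a
linear–quadratic tracking solve (same exact QP machinery; boundary torques
equal the steady torque holding the posture against the band); the
σ²-uncertainty integral and the optional process-noise covariance term
`P_q̇` are control-independent and enter the outer duration search only.
`P_q̇` defaults to zero (the upstream stochastic-control framework's noise
intensity is not published); it is exposed as
`InteractiveAdaptationConfig.process_noise`.  A 10⁴-sample Monte-Carlo
evaluation of the stochastic cost (sampling ξ, integrating the fast dynamics
against each sampled slow trajectory) agrees with the deterministic
equivalent within 5% at σ/μ = 0.1, consistent with the first-order
linearization.

## Synthetic-data generator

The generator emulates the session structure the analysis assumes: blocks of
100 trials (10 extensions + 10 flexions per target, seed-fixed pseudo-random
order), hold times of 2 ± 0.15 s (uniform half-width), Gaussian reaction
times (mean 225 ms), per-trial durations from each subject's affine law with
log-normal multiplicative jitter of configurable CV (default 0.05; positive
and right-skewed, as duration distributions are — the trial-level noise law
is a modelling choice, not a measured one), minimum-jerk kinematics sampled
at 300 Hz, additive Gaussian angle noise (default 2 mrad) and encoder
quantization at 2π/6400 rad (6400 counts per turn, switchable).  Dyadic
trials track per-hypothesis reference plans through the coupled dynamics
with the same LQR machinery and record τⁱ pointwise.  Loaded blocks inflate
durations by the fixed per-load factors above.

What it does **not** emulate: submovements and corrective dynamics near the
target, fatigue and learning across blocks, trial-by-trial adaptation of the
interaction force, EMG, or cursor/screen geometry.  Tests passing on this
generator therefore validate the *pipeline* (segmentation, fitting, scoring,
model solving), not the behavioural claims themselves.

One geometric fact matters downstream: the 5%-of-peak-speed segmentation
measures a fixed fraction c = 0.8811 of the nominal minimum-jerk duration
(the span between the analytic threshold crossings).  Recovery tests compare
against `c ×` the generating slope; vigor is a ratio of durations, so the
common factor cancels in every vigor-level result.

## Statistical components

Vigor scores use each condition family's own population mean durations as
reference (solo null field for the loaded solo blocks; the KL/KH means for
the loaded coupled blocks).  The variance decomposition is the one-way
sum-of-squares split `100 · SS_inter / (SS_inter + SS_intra)`; an all-equal
table reports 0% with a degeneracy flag rather than NaN.  The dyadic-vigor
model is a linear mixed model (maximum likelihood) with condition-specific
fixed effects for the fast and slow partners' solo vigors and a random
intercept per dyad — the minimal structure consistent with repeated
conditions per dyad; fits with and without a global intercept are both
available (`with_intercept`).  Bonferroni–Holm adjusts p-values across
conditions within each predictor by default (`holm_scope='all'` pools all
twelve).  Exactly collinear predictors short-circuit to a flagged
non-identifiable result.

## Known limitations

* **Published average/slow cost-of-time parameters do not close their
  loops.**  Refitting the sigmoid derivative (p₄ = 1) to this package's
  Hamiltonian points reproduces the published average parameters to three
  significant figures — the fixed-time solves agree — but the published fit
  misses the Hamiltonian tail at the two largest targets, where the
  position-error cost makes "arrive early and hold" optimal and `−H`
  collapses.  Free-time solves with the published average parameters
  therefore recover the average amplitude–duration law only to within
  ≈14% (slope); the published slow-group parameters are a degenerate fit
  (p₄ ≈ 10⁻⁵ at its bound) that does not interpolate its own identification
  data at all, and the slow loop does not close.  The fast group's
  parameters close to within ≈3%.  The corresponding acceptance tests are
  left failing rather than adjusted.
* **A5 sensitivity magnitude.**  With the deterministic-equivalent cost and
  `P_q̇ = 0`, scaling the fast cost of time by 1.3 shifts the predicted
  duration by ≈9 ms at the nearest and ≈17 ms at the farthest target; the
  published pair is 10 and 35 ms.  The unpublished process-noise covariance
  is the prime suspect for the farthest-target gap; the knob exists but its
  intensity is not identifiable from published material, so the default
  stays zero.
* The contraction of the identify → forward-solve loop is monotone but
  reaches the sub-1% regime on the second iteration, not the first (same
  tail physics).
* Problem sizes in tests (cohort sizes, seed counts, Monte-Carlo samples)
  are chosen so the full suite solves in a few minutes on one core while
  keeping every statistical bound several standard errors wide.
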