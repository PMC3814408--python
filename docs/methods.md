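# Methods

This note records the modeling choices, default parameters, numerical
details and known limitations of `bspctl`.  The README gives the
high-level model; here we document why each piece is the way it is.

## State model and transform

The concentration state is ordered (x_e, x_c) — effect site first —
throughout.  The continuous-time rate matrix is the standard mammillary
two-compartment form with drug entering and being eliminated through
the central compartment; discretization is the exact matrix-exponential
(zero-order hold) map over the control interval, computed from the
augmented 3×3 exponential.  dt defaults to 1 s, the cadence at which
the loop updates its estimate and infusion rate.  Concentrations are
dimensionless: only the transform-mapped BSP is observable, so the
absolute scale is absorbed into the input gain b_in, which is an
identified parameter rather than a physical constant.

Two transform families are provided.  The default rectangular
hyperbola p = x_e/(1 + x_e) and tanh(x_e) are both monotone bijections
[0, ∞) → [0, 1); the default is preferred because (a) its inverse
x = p/(1 − p) is exact and cheap, and (b) composed with the log-state
it makes the binomial likelihood exactly logistic in z₁ = log x_e, so
the filter's Newton update has simple analytic derivatives and a
concave likelihood term.  tanh saturates to 1.0 in floating point
beyond x ≈ 19, which callers should keep in mind near p = 1.

## Reference parameters

The built-in `REFERENCE_RAT` (k10 = 0.9, k12 = 0.7, k21 = 1.4 min⁻¹,
b_in = 8) is a synthetic parameter set chosen to match the observable
dynamics reported for rodent propofol burst suppression rather than any
single animal's fit: continuous eigenvalues ≈ 0.5 and 2.5 min⁻¹, so a
bolus drives the BSP to its peak in about a minute and it decays back
over several minutes; an uncontrolled drop from BSP 0.9 re-enters the
0.4 ± 0.05 band in ≈ 5 minutes (matching the reported several-minute
fall times, which are washout-limited); and the equilibrium infusion at
BSP 0.9 is ≈ 2.0 mg/min, just inside a 2.4 mg/min pump cap so that an
upper bound binds transiently during upward transitions but not at
steady state.

The LQR weights default to Q = diag(1, 0) — only the EEG-observable
effect-site error is penalized — and R = 1.  R trades infusion effort
against speed and has meaning only relative to b_in; the default is
calibrated so the reference-rat closed loop completes an upward
transition in just under a minute (≈ 49 s to within 0.05 BSP units)
with overshoot below 10⁻³.  Users fitting their own parameters should
re-tune R to their desired transition speed.

## Estimator

The filter state is z = log x.  Prediction: mean′ = log(A e^mean + Bu);
covariance F P Fᵀ + W with F = diag(1/x_pred) A diag(e^mean), the exact
Jacobian of the log-domain map at the posterior mean.  Process noise W
defaults to diag(1e-4, 1e-4) per 1-s step — enough to admit slow drift
relative to the deterministic model without visibly inflating
steady-state variance.  A floor of 1e-12 concentration units guards
log(0) when the state washes out completely.

Update: the posterior ∝ N(z; prediction) × Binomial(n; N, p(e^{z₁})) is
replaced by its Laplace approximation.  The mode is found by damped
Newton iteration (backtracking line search on the log-posterior,
tolerance 1e-10 on the step, cap 50 iterations) with analytic gradient
and Hessian obtained by differentiating through the transform; the
covariance is the inverse negative Hessian at the mode.  A
non-convergent or non-concave update falls back to the prediction with
doubled covariance and a warning — in practice the default transform
makes the log-posterior strictly concave in z₁ and the fallback is
never taken.  An equivalent closed-form single-Newton-step update would
share the same fixed point; iterating to convergence is preferred for
robustness to large innovations.  The filter prior is anchored at the
first interval's empirical suppression fraction (floored at 0.05), with
unit log-variance, unless the caller supplies one.

The one-dimensional special case replaces the plant by a random walk
z_{t+1} = z_t + w, w ~ N(0, q); q (default 1e-3 per step) sets the
smoothness of the BSP trace it extracts from a binary record.  As
q → 0 the estimate converges to the global empirical suppression
fraction.

## System identification

Identification is two-step: the 1-D filter smooths the recorded bolus
response into a BSP trace, then bounded trust-region least squares
(`scipy.optimize.least_squares`, trf) matches the deterministic model
response from x(0) = 0 to that trace.  Bounds are wide and
positivity-enforcing (rates in [1e-4, 10] min⁻¹, b_in in [1e-4, 100]);
the fit is multi-start (default 8 seeded log-normal perturbations of
the initial guess) because the problem is nonconvex and no principled
initialization exists.  A bolus of D mg delivered in one 1-s step is
represented as a rate of 60·D mg/min for that step.

Identifiability deserves emphasis: the input→BSP map determines only
three parameter combinations — k21 + k10 + k12, k21·k10, and b_in·k12
(two poles and a gain) — so the free four-parameter fit recovers the
*response* exactly while the individual parameters trade off along a
one-dimensional ridge.  Pinning the gain (`fix=("b_in",)`), the natural
normalization given arbitrary concentration units, makes the rates
locally identifiable up to the exact k10 ↔ k21 relabeling symmetry,
which the fitter resolves toward the initial guess.  Noise-free
recovery is then exact to ≈ 1e-12 relative; under binomial observation
noise the individual rates blur along the near-flat directions but the
fitted response stays within a few hundredths of a BSP unit of truth —
which is the quantity the controller consumes.

## Controllers

The Riccati equation is solved by value iteration from S = Q to a
1e-12 step tolerance (the two-dimensional problem converges in a few
thousand cheap iterations); tests cross-check against
`scipy.linalg.solve_discrete_are` and a finite-horizon backward
recursion.  Input constraints are imposed on the LQR by projection
(clipping), generalizing "if the solution is negative, use zero" to an
upper bound.

The MPC minimizes Σ_{k=1..T} (x_k − x\*)ᵀQ(x_k − x\*) + R(u_k − u\*)²
subject to the dynamics and box bounds on u, re-solved each second with
only u₀ applied.  The condensed problem in the T controls is a bounded
least-squares program, solved exactly by BVLS (`scipy.optimize.
lsq_linear`) after first checking whether the unconstrained minimizer
(via a cached pseudo-inverse) already satisfies the box — it usually
does away from transitions, which keeps long-horizon closed-loop runs
fast.  Optional per-component state bounds switch the solve to SLSQP
with linear inequality constraints; infeasibility raises with the
binding constraint named.  The default horizon is 30 steps; a terminal
Riccati cost is off by default (the horizon-convergence behavior is the
point of the LQR–MPC comparison, and holds either way).  During
closed-loop simulation the MPC holds the *current* target over its
horizon rather than previewing scheduled changes, mirroring what the
LQR knows.

## Simulator and surrogate data

The closed loop is simulated at 1 s per step: plant step with the
previous rate, count draw n ~ Binomial(10, p_true) with the BSP taken
at the interval start, filter predict/update, controller output.  All
randomness derives from one seed; records are bit-reproducible and
truncation-consistent (the first t steps of a longer run equal a run of
length t).  Control starts at BSP 0.2 — within the 0.1–0.3 window
where a clinician would engage the controller after an induction
bolus — implemented as direct state initialization with the
compartments in their equilibrium ratio, which keeps run length
deterministic.

The surrogate raw-EEG generator exists to exercise the segmentation
stage: per 100-ms sub-interval it draws a suppressed/burst state with
the scheduled BSP as marginal and a persistence parameter (default 0.8,
mean dwell ≈ 0.5 s) emulating the seconds-scale alternation of real
burst suppression; bursts are 1–30 Hz band-limited noise at ≈ 50 µV
RMS, suppressions at ≈ 2 µV.  It is a statistical stand-in, not a
biophysical EEG model: it has no 1/f background, artifacts, or
amplitude nonstationarity, so segmentation accuracy on it bounds only
algorithmic, not clinical, performance.  Thresholds are suggested by a
two-component Gaussian mixture on log filtered magnitude (midpoint of
the component means), falling back to the 25th percentile with a
warning when no bimodality is found.

## Evaluation conventions

Percent errors use the target as denominator; MAD uses raw deviations
in BSP units (the 0.15/0.10 reliability thresholds are only
dimensionally consistent with BSP units).  Quantiles use linear
interpolation between order statistics.  Transition rates divide the
*target* change by the time to first enter the 0.05 band, and are
computed on the estimated BSP (the quantity plotted and controlled);
the steady-state mask removes 5 minutes after upward and 7 minutes
after downward changes, treating the initial acquisition like an
upward transition.  The credible interval for overall reliability is
one-sided, [q05, 1].

## Problem sizes

Default test and acceptance runs use 45-minute (2700-step) closed-loop
records, 20 seeded repetitions for the stochastic accuracy bound,
100 randomized cases for the Riccati-residual and grid-oracle checks
(the grid oracle is a 401² lattice over ±5 SD, refined once by zooming
onto the coarse argmax), and 30-minute bolus records for
identification.  These sizes put sampling error well inside the
asserted tolerances while keeping a full run of the suite and the
acceptance script in the minutes range.

## Known limitations

- Single-channel, artifact-free EEG is assumed; no artifact rejection
  or multi-channel fusion.
- The binomial observation model treats sub-samples as conditionally
  independent given the BSP; real suppression runs are serially
  correlated, which the evaluation's settling windows acknowledge but
  the filter's likelihood does not.
- Parameters are fitted once before control; there is no online
  re-estimation or adaptive filtering, so slow physiological drift
  (tolerance, temperature) appears as process noise.
- Two compartments only; no covariate (weight, age) scaling, and no
  joint control of other vital signs — the MPC's state-constraint
  machinery is in place but unused by default.
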