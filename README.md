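# bspctl — closed-loop control of medically-induced coma

Medically-induced coma is maintained for days at a time by titrating an
anesthetic (typically propofol) against the EEG's *burst suppression*
pattern: bursts of electrical activity alternating with near-isoelectric
suppressions.  `bspctl` implements, entirely in simulation, a
brain-machine interface that automates this titration: it estimates the
**burst suppression probability (BSP)** — the brain's instantaneous
probability of being in the suppressed state — in real time from
binarized EEG, and drives the infusion rate with optimal-control
feedback against time-varying BSP targets.

It is written for computational neuroscientists and control engineers
working on closed-loop anesthetic delivery (CLAD): every stage of the
loop is an importable, separately testable component.

## The model and the algorithm

**Pharmacokinetics.** A two-compartment model links the infusion rate
u(t) (mg/min) to a central (plasma) concentration x_c and an effect-site
(brain) concentration x_e, with first-order rates k10 (elimination), k12
(central→effect) and k21 (effect→central), all in 1/min:

    dx_e/dt = −k21 x_e + k12 x_c
    dx_c/dt =  k21 x_e − (k10 + k12) x_c + b_in u(t)

Discretized exactly (zero-order hold) at the 1-s control cadence this is
x_{t+1} = A x_t + B u_t.  The BSP is a monotone hyperbolic function of
the effect-site concentration, by default p = x_e / (1 + x_e), which
maps [0, ∞) onto [0, 1) and captures the steep growth of required drug
as the target approaches full suppression.

**Estimation.** The EEG is rectified, causally low-pass filtered below
5 Hz, and thresholded into a binary suppressed/burst series; each 1-s
interval is sub-sampled at 10 Hz, giving a count n_t ~ Binomial(N = 10,
p_t).  A recursive Bayesian filter tracks a Gaussian belief over
z = log x (log-concentrations, guaranteeing positivity): the prediction
step propagates the belief through the log-domain plant map linearized
at the posterior mean (extended-Kalman style), and the update step
replaces the exact binomial-times-Gaussian posterior with its Laplace
approximation, whose mode is found by damped Newton iteration.

**Control.** The target BSP p\* induces an equilibrium (x\*, u\*)
through (I − A) x\* = B u\*.  A steady-state LQR gain L from the
discrete algebraic Riccati equation gives the certainty-equivalence law
u = clip(u\* − L(x̂ − x\*), [u_min, u_max]); alternatively a
receding-horizon MPC solves the same quadratic cost as a constrained
program at every step, honoring pump bounds along the whole predicted
trajectory.  With input bounds only, the two agree increasingly well as
the MPC horizon grows.

**Evaluation.** Steady-state accuracy uses the standard
infusion-control metrics — MAD (median |p̂ − p\*|, BSP units), MDPE
(median percent error, a bias) and MDAPE (median absolute percent
error) — computed after masking 5 min following upward and 7 min
following downward target changes.  Reliability per level requires the
95th percentile of |p̂ − p\*| below 0.15 (0.10 for *highly* reliable);
pooling k reliable levels of n under a uniform prior gives the
posterior Beta(k+1, n−k+1) for the reliability probability, summarized
by its mode and the one-sided 95% credible interval.

## Worked example

`examples/run_closed_loop.py` runs the 45-minute three-level protocol
(targets 0.4, 0.7, 0.9 for 15 minutes each) against the built-in
reference-rat model with the bounded LQR controller:

```
steady-state performance (estimated BSP vs target):
    low: MAD=0.003  MDPE=-0.05%  MDAPE=0.70%  (n=600)
    mid: MAD=0.003  MDPE=+0.19%  MDAPE=0.49%  (n=600)
   high: MAD=0.001  MDPE=+0.03%  MDAPE=0.12%  (n=600)
  all  : MAD=0.002  MDPE=+0.05%  MDAPE=0.32%

reliability: 3/3 levels with 95th pct |error| < 0.15; posterior mode 1.00,
95% credible interval [0.47, 1.00]
transitions: median rise 49 s (0.30 BSP/min)
```

MDAPE below 1% means the controlled BSP tracked each target to within
a percent of its value at steady state; the 49-s rise time is how long
an upward target change takes to settle within 0.05 BSP units.  The
other examples cover EEG segmentation (`estimate_bsp_from_eeg.py`),
system identification from a bolus (`fit_pk_model.py`), and the
LQR–MPC comparison (`compare_lqr_mpc.py`).

A thin CLI wraps the same library for shell use:

```sh
bspctl protocol --out-dir schedules/
bspctl simulate --config sim.yaml --seed 7 --out run.csv --plot run.png
bspctl evaluate --run run.csv --schedule schedules/schedule_0.json --out report.json
bspctl fit --obs obs.csv --infusion u.csv --out params.json
bspctl replay --obs obs.csv --infusion u.csv --params params.json --out est.csv
```

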