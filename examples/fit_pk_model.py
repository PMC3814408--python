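"""Two-step system identification from a bolus response.

Simulates the preliminary experiment run before closed-loop control: a
single propofol bolus drives the EEG into burst suppression, the binary
record is smoothed into a BSP trace with the one-dimensional filter,
and the two-compartment parameters are recovered by nonlinear least
squares.  Prints the recovered rates next to the generating truth.
"""

import numpy as np

from bspctl import PKParams, estimate_target_trace, fit_pk_params
from bspctl.estimator import BinaryObservation
from bspctl.system_id import BolusExperiment, bolus_profile, predicted_bsp

truth = PKParams(k10=0.30, k12=0.85, k21=1.00, b_in=2.0)
u = bolus_profile(n_steps=1800, bolus_mg=8.0)     # 8 mg over one second
true_bsp = predicted_bsp(truth, u)
print(f"bolus response: peak BSP {true_bsp.max():.2f} at "
      f"t={true_bsp.argmax()} s, back below 0.1 by "
      f"t={np.argmax((true_bsp < 0.1) & (np.arange(1800) > 100))} s")

init = PKParams(k10=0.5, k12=0.4, k21=0.6, b_in=2.0)

# noise-free identification: with the gain pinned the rates come back exactly
fit = fit_pk_params(true_bsp, u, init=init, fix=("b_in",), seed=0)
print(f"\nnoise-free fit   {'true':>8} {'fitted':>8}")
for name in ("k10", "k12", "k21", "b_in"):
    print(f"{name:>14} {getattr(truth, name):8.3f} "
          f"{getattr(fit.params, name):8.3f}")

# realistic identification: binomial EEG counts -> smoothed trace -> fit
rng = np.random.default_rng(0)
obs = [BinaryObservation(t=t, n=int(rng.binomial(10, p)), N=10)
       for t, p in enumerate(true_bsp)]
trace = estimate_target_trace(
    BolusExperiment(infusion_profile=u, observations=obs))
noisy = fit_pk_params(trace, u, init=init, seed=0)
rmse = np.sqrt(np.mean((noisy.fitted_trace - true_bsp) ** 2))
print(f"\nwith binomial observation noise: fitted response RMSE vs true "
      f"BSP {rmse:.4f} BSP units")
print("The rates (1/min) govern drug exchange and elimination; the gain "
      "b_in is pinned in the noise-free fit because only the BSP, not "
      "absolute concentration, is observable.  Under noise the individual "
      "rates trade off along a flat direction, but the response the "
      "controller relies on is still recovered to a few percent.")
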