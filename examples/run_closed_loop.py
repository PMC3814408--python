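"""Closed-loop control of burst suppression over a three-level target
protocol, with the standard steady-state performance report.

Runs the 45-minute protocol (BSP targets 0.4 / 0.7 / 0.9, 15 minutes
each) against the reference-rat model with the bounded LQR controller,
then prints MAD (BSP units), MDPE and MDAPE (percent) per level plus
the per-level reliability verdicts and the pooled beta-posterior bound.
"""

import numpy as np

from bspctl import (
    generate_target_protocol,
    simulate_closed_loop,
    steady_state_mask,
    steady_state_metrics,
)
from bspctl.evaluation import reliability_from_run, transition_metrics

schedule = generate_target_protocol(levels=(0.4, 0.7, 0.9),
                                    minutes_per_level=15, permutation=0)
record = simulate_closed_loop(schedule=schedule, controller="lqr", seed=7)

mask = steady_state_mask(schedule, dt=1.0, n_steps=record.p_hat.size)
report = steady_state_metrics(record.p_hat, record.p_target, mask)

print("steady-state performance (estimated BSP vs target):")
for band, m in report.per_level.items():
    print(f"  {band:>5}: MAD={m.mad:.3f}  MDPE={m.mdpe:+.2f}%  "
          f"MDAPE={m.mdape:.2f}%  (n={m.n_samples})")
o = report.overall
print(f"  all  : MAD={o.mad:.3f}  MDPE={o.mdpe:+.2f}%  MDAPE={o.mdape:.2f}%")

rel = reliability_from_run(record.p_hat - record.p_target, mask, record.p_target)
print(f"\nreliability: {rel.k}/{rel.n} levels with 95th pct |error| < 0.15; "
      f"posterior mode {rel.posterior_mode:.2f}, "
      f"95% credible interval [{rel.credible_lower_95:.2f}, 1.00]")

tr = transition_metrics(record.p_hat, schedule, dt=1.0)
print(f"transitions: median rise {tr.median_rise_s:.0f} s "
      f"({tr.median_rise_rate_per_min:.2f} BSP/min)")
print("\nA MDAPE of a few percent means the controlled BSP tracked each "
      "target to within a few percent of its value at steady state; the "
      "credible interval bounds the probability that any given level is "
      "controlled reliably.")
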