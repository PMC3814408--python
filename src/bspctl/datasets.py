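"""Reference data bundled with the package.

``RODENT_SESSION_METRICS`` reproduces the published per-experiment
steady-state performance table from the six in-vivo closed-loop
burst-suppression control sessions in rodents that this framework was
validated on.  Keys are level bands; each entry maps metric name to the
six per-experiment values (MAD in BSP units, MDPE/MDAPE in percent).
These serve as inputs to the cross-experiment aggregation
(`evaluation.pool_reports`) in worked examples and tests — the package
does not re-measure them.
"""

from __future__ import annotations

RODENT_SESSION_METRICS = {
    "low": {
        "mad": [0.027, 0.043, 0.017, 0.032, 0.034, 0.031],
        "mdape": [5.43, 10.72, 4.90, 11.44, 8.47, 6.18],
        "mdpe": [-0.80, 10.72, 1.79, -11.44, -8.47, -3.04],
    },
    "mid": {
        "mad": [0.018, 0.016, 0.019, 0.017, 0.052, 0.019],
        "mdape": [2.62, 2.32, 3.80, 3.35, 7.37, 2.68],
        "mdpe": [1.75, 1.00, -0.40, -1.45, -7.37, -0.06],
    },
    "high": {
        "mad": [0.012, 0.016, 0.031, 0.038, 0.043, 0.017],
        "mdape": [1.35, 1.75, 3.69, 4.35, 4.81, 1.87],
        "mdpe": [-0.81, -1.73, -3.69, -4.35, -4.81, -1.84],
    },
    "all": {
        "mad": [0.019, 0.022, 0.021, 0.032, 0.041, 0.022],
        "mdape": [2.82, 3.01, 4.14, 4.98, 5.61, 3.07],
        "mdpe": [-0.13, 0.99, -1.24, -4.87, -5.60, -1.63],
    },
}

#: Reliability tallies from the same sessions: all 20 tested levels met
#: the 0.15 bound; 17 of 20 met the stricter 0.10 bound.
RODENT_RELIABILITY_COUNTS = {"reliable": (20, 20), "highly_reliable": (17, 20)}
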