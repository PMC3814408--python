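"""Performance metrics for closed-loop burst-suppression control.

Steady-state accuracy is summarized with the standard infusion-control
statistics: per-step deviation e_t = p̂_t − p*_t and percent error
100·e_t/p*_t, reduced to the median absolute deviation (MAD, BSP
units), the median prediction error (MDPE, %, a bias measure) and the
median absolute performance error (MDAPE, %, a normalized error).
Samples inside a settling window after each target change — 5 minutes
after an upward transition, 7 minutes after a downward one — are
masked out so only steady-state data enter the medians, and the masking
also decorrelates adjacent levels.

Transition speed is summarized by the rise/fall time (first time after
a target change at which the BSP is within 0.05 units of the new
target) and the corresponding rate of BSP change per minute.

Reliability is assessed per level — the 95th percentile of |e_t| must
be below 0.15 (reliable) or 0.10 (highly reliable) — and overall with a
beta-binomial posterior: with k reliable levels out of n and a uniform
prior, the reliability probability has posterior Beta(k+1, n−k+1),
reported as its mode (k/n) and the one-sided 95% credibility interval
[q05, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import TargetSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "LevelMetrics",
    "MetricsReport",
    "TransitionReport",
    "ReliabilityReport",
    "steady_state_mask",
    "performance_error",
    "steady_state_metrics",
    "pool_reports",
    "transition_metrics",
    "level_reliability",
    "overall_reliability",
]

RISE_FALL_BAND = 0.05          # BSP units: "reached" the new target
RELIABLE_THRESHOLD = 0.15      # 95th pct |error| bound for reliable
HIGHLY_RELIABLE_THRESHOLD = 0.10
UP_MASK_S = 300.0              # settle window after upward transition
DOWN_MASK_S = 420.0            # settle window after downward transition


@dataclass
class LevelMetrics:
    mad: float
    mdpe: float
    mdape: float
    n_samples: int


@dataclass
class MetricsReport:
    """MAD/MDPE/MDAPE per level band (low/mid/high) and over all levels."""

    per_level: dict
    overall: LevelMetrics


@dataclass
class TransitionReport:
    """Per-transition timing plus medians by direction."""

    transitions: list
    median_rise_s: float | None
    median_fall_s: float | None
    median_rise_rate_per_min: float | None
    median_fall_rate_per_min: float | None
    rate_denominator: str = "target_change"


@dataclass
class ReliabilityReport:
    per_level: dict
    k: int
    n: int
    posterior_mode: float
    credible_lower_95: float
    reliable_overall: bool


def steady_state_mask(schedule: TargetSchedule, dt: float, n_steps: int,
                      initial_window_s: float | None = None) -> np.ndarray:
    """Boolean mask of steady-state samples.

    False for ``UP_MASK_S`` (5 min) after each upward target change and
    ``DOWN_MASK_S`` (7 min) after each downward change; the initial
    acquisition of the first level is masked like an upward transition
    (override with ``initial_window_s``).
    """
    t = np.arange(n_steps) * dt
    mask = np.ones(n_steps, dtype=bool)
    init_w = UP_MASK_S if initial_window_s is None else initial_window_s
    mask &= t >= (schedule.breakpoints[0] + init_w)
    for prev, (bp, lvl) in zip(
        schedule.levels, zip(schedule.breakpoints[1:], schedule.levels[1:])
    ):
        w = UP_MASK_S if lvl > prev else DOWN_MASK_S
        mask &= ~((t >= bp) & (t < bp + w))
    return mask


def performance_error(p_hat, p_target):
    """Per-step (deviation, percent error) arrays.

    deviation = p̂ − p* in BSP units; percent = 100 (p̂ − p*)/p*.
    Zero-target samples are returned as NaN percent with a warning (the
    percent error is undefined there).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    p_target = np.asarray(p_target, dtype=float)
    deviation = p_hat - p_target
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = 100.0 * deviation / p_target
    bad = p_target == 0
    if np.any(bad):
        logger.warning("%d zero-target samples excluded from percent error",
                       int(bad.sum()))
        percent = np.where(bad, np.nan, percent)
    return deviation, percent


def _band_labels(p_target, levels=None):
    """Assign each sample a low/mid/high band by target value.

    With more than three distinct levels the lowest levels fold into
    'low' and the highest into 'high' so three bands remain.
    """
    p_target = np.asarray(p_target, dtype=float)
    uniq = np.sort(np.unique(p_target)) if levels is None else np.sort(np.asarray(levels))
    bands = {}
    k = len(uniq)
    if k == 1:
        bands[uniq[0]] = "mid"
    elif k == 2:
        bands[uniq[0]], bands[uniq[1]] = "low", "high"
    else:
        n_low = (k - 1) // 2
        n_high = k - 1 - n_low
        for i, v in enumerate(uniq):
            if i < n_low:
                bands[v] = "low"
            elif i >= k - n_high:
                bands[v] = "high"
            else:
                bands[v] = "mid"
    return np.array([bands[v] for v in p_target])


def steady_state_metrics(p_hat, p_target, mask, levels=None) -> MetricsReport:
    """MAD/MDPE/MDAPE per level band and overall, on masked-in samples."""
    deviation, percent = performance_error(p_hat, p_target)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(percent)
    labels = _band_labels(p_target, levels)
    per_level = {}
    for band in ("low", "mid", "high"):
        sel = mask & (labels == band)
        if not np.any(sel):
            logger.warning("no steady-state samples for %s level; omitted", band)
            continue
        per_level[band] = LevelMetrics(
            mad=float(np.median(np.abs(deviation[sel]))),
            mdpe=float(np.median(percent[sel])),
            mdape=float(np.median(np.abs(percent[sel]))),
            n_samples=int(sel.sum()),
        )
    if not np.any(mask):
        raise ValueError("mask excludes every sample")
    overall = LevelMetrics(
        mad=float(np.median(np.abs(deviation[mask]))),
        mdpe=float(np.median(percent[mask])),
        mdape=float(np.median(np.abs(percent[mask]))),
        n_samples=int(mask.sum()),
    )
    return MetricsReport(per_level=per_level, overall=overall)


def pool_reports(values) -> float:
    """Cross-experiment aggregation: the median of per-experiment values."""
    return float(np.median(np.asarray(values, dtype=float)))


def transition_metrics(p_hat, schedule: TargetSchedule, dt: float) -> TransitionReport:
    """Rise/fall times and rates of BSP change for each target change.

    Time is measured from the breakpoint to the first sample with
    |p̂ − p*_new| <= 0.05; the rate divides the *target* change by that
    time (in minutes).  A transition that never reaches the band is
    flagged with time None.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    t = np.arange(p_hat.size) * dt
    transitions = []
    if len(schedule.breakpoints) < 2:
        raise ValueError("schedule has no transitions")
    for prev, bp, new in zip(
        schedule.levels, schedule.breakpoints[1:], schedule.levels[1:]
    ):
        direction = "up" if new > prev else "down"
        after = t >= bp
        inband = after & (np.abs(p_hat - new) <= RISE_FALL_BAND)
        if np.any(inband):
            t_reach = float(t[inband][0] - bp)
            rate = abs(new - prev) / (t_reach / 60.0) if t_reach > 0 else np.inf
        else:
            t_reach, rate = None, None
        transitions.append(
            {"direction": direction, "time_s": t_reach,
             "rate_per_min": rate, "from": prev, "to": new}
        )
    def _median(vals):
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.median(vals)) if vals else None

    ups = [tr for tr in transitions if tr["direction"] == "up"]
    downs = [tr for tr in transitions if tr["direction"] == "down"]
    return TransitionReport(
        transitions=transitions,
        median_rise_s=_median([tr["time_s"] for tr in ups]),
        median_fall_s=_median([tr["time_s"] for tr in downs]),
        median_rise_rate_per_min=_median([tr["rate_per_min"] for tr in ups]),
        median_fall_rate_per_min=_median([tr["rate_per_min"] for tr in downs]),
    )


def level_reliability(abs_deviations, min_samples: int = 20) -> dict:
    """Reliability verdict for one level from its |error| distribution.

    Uses the linear-interpolation 95th percentile; reliable iff it is
    below 0.15, highly reliable iff below 0.10.  Fewer than
    ``min_samples`` samples gives an undetermined verdict.
    """
    a = np.asarray(abs_deviations, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < min_samples:
        return {"p95": None, "reliable": None, "highly_reliable": None,
                "n_samples": int(a.size)}
    p95 = float(np.percentile(a, 95))  # linear interpolation
    return {
        "p95": p95,
        "reliable": p95 < RELIABLE_THRESHOLD,
        "highly_reliable": p95 < HIGHLY_RELIABLE_THRESHOLD,
        "n_samples": int(a.size),
    }


def overall_reliability(k: int, n: int) -> ReliabilityReport:
    """Beta-binomial posterior over the per-level reliability probability.

    With a uniform prior and k reliable levels out of n, the posterior
    is Beta(k+1, n−k+1); reported are its mode k/n and the one-sided
    95% credibility interval [q05, 1] (q05 = posterior 5th percentile).
    The system is called reliable overall iff q05 > 0.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    a, b = k + 1, n - k + 1
    q05 = float(stats.beta.ppf(0.05, a, b))
    mode = k / n
    return ReliabilityReport(
        per_level={}, k=k, n=n, posterior_mode=mode,
        credible_lower_95=q05, reliable_overall=q05 > 0,
    )


def reliability_from_run(deviation, mask, labels) -> ReliabilityReport:
    """Per-level verdicts plus the pooled beta-posterior summary for one
    or more runs; ``labels`` assigns each sample to a level identifier."""
    deviation = np.abs(np.asarray(deviation, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    per_level = {}
    k = n = 0
    for lev in np.unique(labels):
        verdict = level_reliability(deviation[mask & (labels == lev)])
        per_level[str(lev)] = verdict
        if verdict["reliable"] is not None:
            n += 1
            k += int(verdict["reliable"])
    if n == 0:
        raise ValueError("no level with enough steady-state samples")
    rep = overall_reliability(k, n)
    rep.per_level = per_level
    return rep
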