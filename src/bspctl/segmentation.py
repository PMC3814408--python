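"""Real-time segmentation of raw EEG into binary burst/suppression
labels and per-interval binomial suppression counts.

The pipeline follows standard burst-suppression practice: rectify the
raw voltage, low-pass filter the magnitude (below 5 Hz by default) with
a *causal* filter so the method runs sample-by-sample in real time, and
threshold — filtered magnitude below the threshold means the EEG is
suppressed.  The binary series is then sub-sampled at 10 Hz within each
1-s observation interval, producing the count n out of N = 10 that the
Bayesian estimator consumes as a binomial observation.

The threshold separating burst from suppression amplitudes is normally
chosen by visual inspection; `suggest_threshold` automates a starting
point by fitting a two-component Gaussian mixture to the log filtered
magnitude and placing the threshold between the two modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter, lfilter_zi

from .estimator import BinaryObservation

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecord",
    "SegmentationConfig",
    "binarize_eeg",
    "filtered_magnitude",
    "aggregate_counts",
    "suggest_threshold",
]


@dataclass
class EEGRecord:
    """Single-channel EEG: voltage samples (µV) at sampling rate fs (Hz)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SegmentationConfig:
    """Segmentation settings.

    lowpass_hz : cutoff of the causal low-pass applied to the rectified
        signal (default 5 Hz).
    threshold : filtered-magnitude cutoff in µV; below it the sample is
        labelled suppressed.
    interval_s : observation interval (default 1 s).
    subrate_hz : sub-sampling rate within each interval (default 10 Hz),
        so N = interval_s * subrate_hz sub-samples per interval.
    """

    threshold: float
    lowpass_hz: float = 5.0
    interval_s: float = 1.0
    subrate_hz: float = 10.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.lowpass_hz <= 0:
            raise ValueError("lowpass cutoff must be positive")
        N = self.interval_s * self.subrate_hz
        if abs(N - round(N)) > 1e-9 or round(N) < 1:
            raise ValueError("interval_s * subrate_hz must be a positive integer")

    @property
    def N(self) -> int:
        return int(round(self.interval_s * self.subrate_hz))


def filtered_magnitude(rec: EEGRecord, cfg: SegmentationConfig) -> np.ndarray:
    """Causally low-pass-filtered magnitude (rectified voltage) of the EEG.

    2nd-order Butterworth; the filter state is initialized to the first
    sample's steady state so the startup transient does not misclassify
    the opening samples.
    """
    if cfg.lowpass_hz >= rec.fs / 2:
        raise ValueError(
            f"lowpass cutoff {cfg.lowpass_hz} Hz must be below Nyquist "
            f"({rec.fs / 2} Hz)"
        )
    mag = np.abs(rec.samples)
    b, a = butter(2, cfg.lowpass_hz, fs=rec.fs)
    zi = lfilter_zi(b, a) * (mag[0] if mag.size else 0.0)
    y, _ = lfilter(b, a, mag, zi=zi)
    return y


def binarize_eeg(rec: EEGRecord, cfg: SegmentationConfig) -> np.ndarray:
    """Binary suppression labels at the raw sampling rate.

    1 where the causally filtered magnitude is strictly below the
    threshold (suppression), 0 otherwise (burst).
    """
    y = filtered_magnitude(rec, cfg)
    return (y < cfg.threshold).astype(np.int8)


def aggregate_counts(binary, cfg: SegmentationConfig, fs: float) -> list[BinaryObservation]:
    """Binomial counts per observation interval.

    Sub-samples the binary series at ``cfg.subrate_hz`` (the label at
    each sub-sample instant) and counts suppressed sub-samples, giving
    n out of N per interval.  A stream of T seconds yields exactly
    floor(T / interval_s) observations; a stream shorter than one
    interval yields none.
    """
    binary = np.asarray(binary)
    n_per_interval = cfg.N
    samples_per_interval = cfg.interval_s * fs
    n_intervals = int(np.floor(binary.size / samples_per_interval))
    out = []
    for t in range(n_intervals):
        start = t * cfg.interval_s
        # sub-sample instants within [start, start + interval)
        instants = start + np.arange(n_per_interval) / cfg.subrate_hz
        idx = np.minimum((instants * fs).astype(int), binary.size - 1)
        n = int(binary[idx].sum())
        out.append(BinaryObservation(t=t, n=n, N=n_per_interval))
    return out


def suggest_threshold(magnitudes, fallback_percentile: float = 25.0,
                      random_state: int = 0) -> float:
    """Data-driven threshold between burst and suppression amplitudes.

    Fits a two-component Gaussian mixture to the log filtered magnitude
    and returns the midpoint (in µV) between the two component means.
    If the distribution is effectively unimodal (components closer than
    one pooled standard deviation, or degenerate input), falls back to
    the ``fallback_percentile`` of the magnitude with a warning.  The
    result is advisory — an explicitly configured threshold wins.
    """
    from sklearn.mixture import GaussianMixture

    mags = np.asarray(magnitudes, dtype=float).ravel()
    mags = mags[mags > 0]
    if mags.size < 20 or np.ptp(mags) < 1e-12:
        logger.warning(
            "magnitude distribution degenerate; falling back to the %gth "
            "percentile threshold", fallback_percentile,
        )
        base = np.asarray(magnitudes, dtype=float).ravel()
        return float(np.percentile(base, fallback_percentile))
    logm = np.log(mags).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(logm)
    means = np.sort(gm.means_.ravel())
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    if means[1] - means[0] < pooled_sd:
        logger.warning(
            "no clear bimodality in log magnitude; falling back to the %gth "
            "percentile threshold", fallback_percentile,
        )
        return float(np.percentile(mags, fallback_percentile))
    return float(np.exp(means.mean()))
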