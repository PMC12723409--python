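"""Evoked local-field-potential averaging, peak-latency detection, and the
coefficient-of-variation reliability criterion.

The conduction-time measurement rests on the first positive deflection (P1)
of the trial-averaged transcallosal evoked potential: stereotrode channels
are averaged within each trial, trials are averaged, the result is baseline
corrected, and P1/N1 are detected inside fixed post-stimulus windows
(P1: +1 to +9 ms, first positive local maximum; N1: +5 to +20 ms, global
minimum).  A condition is considered reliable when the coefficient of
variation of the per-trial amplitude at the N1 latency is below 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LFPTrace",
    "PeakSet",
    "P1_WINDOW_MS",
    "N1_WINDOW_MS",
    "COV_RELIABILITY_LIMIT",
    "average_and_baseline",
    "detect_peaks",
    "reliability_cov",
    "n1_onset_latency",
]

#: Post-stimulus detection windows, ms.
P1_WINDOW_MS = (1.0, 9.0)
N1_WINDOW_MS = (5.0, 20.0)

#: A condition is reliable when CoV of the N1 amplitude over trials < 1.00.
COV_RELIABILITY_LIMIT = 1.00


@dataclass
class LFPTrace:
    """Multi-trial, multi-channel evoked recording.

    ``data`` is (trials, channels, samples) in µV; ``stim_index`` is the
    sample of stimulus onset; ``baseline_window`` is (start, end) in ms
    relative to the stimulus (default −50 to 0 ms).
    """

    data: np.ndarray
    fs: float
    stim_index: int
    baseline_window: tuple = (-50.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or 0 in self.data.shape:
            raise ValueError("data must be (trials, channels, samples), all non-empty")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.stim_index < self.data.shape[2]):
            raise ValueError("stim_index outside the record")

    def ms_to_sample(self, t_ms):
        return self.stim_index + int(round(t_ms * self.fs / 1000.0))

    def trial_means(self):
        """Channel-mean trace per trial, (trials, samples)."""
        return self.data.mean(axis=1)


@dataclass
class PeakSet:
    """Detected deflections; latencies in ms relative to stimulus."""

    p1_latency: float | None
    p1_amplitude: float | None
    n1_latency: float | None
    n1_amplitude: float | None
    cov_n1: float | None = None

    @property
    def reliable(self):
        return self.cov_n1 is not None and self.cov_n1 < COV_RELIABILITY_LIMIT


def average_and_baseline(trace: LFPTrace):
    """Channel-mean, then trial-mean, then baseline-subtracted trace (1D µV)."""
    mean = trace.trial_means().mean(axis=0)
    i0 = trace.ms_to_sample(trace.baseline_window[0])
    i1 = trace.ms_to_sample(trace.baseline_window[1])
    if i0 < 0 or i1 > len(mean) or i1 <= i0:
        raise ValueError("baseline window outside the record")
    return mean - mean[i0:i1].mean()


def detect_peaks(mean_trace, fs, stim_index,
                 p1_window_ms=P1_WINDOW_MS, n1_window_ms=N1_WINDOW_MS,
                 min_amplitude="auto", noise_floor_k=3.0):
    """Detect P1 and N1 on an averaged, baseline-corrected trace.

    P1 is the *first* strict local maximum with positive amplitude inside
    the P1 window (ties broken by the earlier sample); N1 is the global
    minimum inside the N1 window, required to be negative.  Absent peaks
    are reported as ``None`` (an animal with no detectable P1 yields no
    conduction time).

    Deflections must additionally clear a noise floor: residual noise on a
    trial average produces spurious sample-level local extrema, so a peak
    only counts when its magnitude exceeds ``min_amplitude``.  The default
    ``"auto"`` sets the floor to ``noise_floor_k`` times the standard
    deviation of the 50 ms pre-stimulus segment (0 when the record has no
    pre-stimulus samples, e.g. constructed clean fixtures).
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    if min_amplitude == "auto":
        pre = mean_trace[max(0, stim_index - int(round(0.05 * fs))):stim_index]
        min_amplitude = noise_floor_k * pre.std() if pre.size > 1 else 0.0

    def window(lo_ms, hi_ms):
        lo = stim_index + int(round(lo_ms * fs / 1000.0))
        hi = stim_index + int(round(hi_ms * fs / 1000.0))
        if lo < 0 or hi > len(mean_trace):
            raise ValueError("detection window exceeds the record")
        return lo, hi

    lo, hi = window(*p1_window_ms)
    p1_lat = p1_amp = None
    seg = mean_trace[lo:hi]
    for i in range(1, len(seg) - 1):
        if (seg[i] > 0 and seg[i] > min_amplitude
                and seg[i] > seg[i - 1] and seg[i] > seg[i + 1]):
            p1_lat = (lo + i - stim_index) * 1000.0 / fs
            p1_amp = float(seg[i])
            break

    lo, hi = window(*n1_window_ms)
    seg = mean_trace[lo:hi]
    n1_lat = n1_amp = None
    imin = int(np.argmin(seg))
    if seg[imin] < 0 and -seg[imin] > min_amplitude:
        n1_lat = (lo + imin - stim_index) * 1000.0 / fs
        n1_amp = float(seg[imin])

    return PeakSet(p1_latency=p1_lat, p1_amplitude=p1_amp,
                   n1_latency=n1_lat, n1_amplitude=n1_amp)


def reliability_cov(trace: LFPTrace, n1_latency_ms):
    """CoV of the per-trial amplitude at the N1 latency.

    Each trial's channel-mean trace is baseline-corrected with the trace's
    baseline window, sampled at the N1 latency, and the coefficient of
    variation is SD (ddof=1) divided by the absolute value of the mean.
    A zero mean amplitude yields ``inf`` (never reliable).
    """
    if n1_latency_ms is None:
        raise ValueError("N1 latency required for the reliability criterion")
    trials = trace.trial_means()
    i0 = trace.ms_to_sample(trace.baseline_window[0])
    i1 = trace.ms_to_sample(trace.baseline_window[1])
    trials = trials - trials[:, i0:i1].mean(axis=1, keepdims=True)
    amps = trials[:, trace.ms_to_sample(n1_latency_ms)]
    mean = amps.mean()
    if mean == 0:
        return float("inf")
    sd = amps.std(ddof=1) if len(amps) > 1 else 0.0
    return float(sd / abs(mean))


def n1_onset_latency(mean_trace, fs, stim_index, peaks: PeakSet):
    """First post-P1 zero-crossing into negative territory preceding N1, ms.

    Experimental summary metric: the N1 onset has no standard operational
    definition, so treat this value as indicative only.
    """
    if peaks.p1_latency is None or peaks.n1_latency is None:
        return None
    mean_trace = np.asarray(mean_trace, dtype=float)
    i_p1 = stim_index + int(round(peaks.p1_latency * fs / 1000.0))
    i_n1 = stim_index + int(round(peaks.n1_latency * fs / 1000.0))
    for i in range(i_p1, i_n1):
        if mean_trace[i] >= 0 > mean_trace[i + 1]:
            return (i + 1 - stim_index) * 1000.0 / fs
    return None
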