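"""Sympathetic/baroreceptor nerve-activity processing.

Implements the standard rectify-and-integrate chain for multifibre nerve
recordings (aortic depressor nerve activity, ADNA): DC-offset removal,
50–10,000 Hz band-pass (upper edge clipped below Nyquist when the
sampling rate cannot carry it), full-wave rectification and first-order
leaky integration with a 3 ms time constant. The integrated trace is then
averaged per heartbeat, background (post-euthanasia) activity is
subtracted, and each beat is expressed relative to the mean of the 10
beats immediately preceding the intervention (baseline = 100%).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NerveSignal",
    "exponential_smooth",
    "integrate_nerve_signal",
    "beat_average_relative",
]


@dataclasses.dataclass
class NerveSignal:
    """A raw nerve recording sampled at a fixed rate.

    ``background`` is the integrated level measured after euthanasia and
    is treated as instrumentation/noise floor.
    """

    samples: np.ndarray
    rate: float  # Hz
    beat_times: np.ndarray  # s
    background: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")


def exponential_smooth(x: np.ndarray, rate: float, tau_ms: float = 3.0) -> np.ndarray:
    """First-order leaky integrator y_t = α x_t + (1−α) y_{t−1}.

    α = Δt / (τ + Δt); a step input settles to 95% within ≈ 3τ.
    """
    if tau_ms <= 0:
        raise ValueError("time constant must be positive")
    dt = 1.0 / rate
    alpha = dt / (tau_ms * 1e-3 + dt)
    return sps.lfilter([alpha], [1.0, alpha - 1.0], np.asarray(x, dtype=float))


def integrate_nerve_signal(
    raw: NerveSignal,
    band: tuple[float, float] = (50.0, 10000.0),
    tau_ms: float = 3.0,
    filter_order: int = 4,
) -> np.ndarray:
    """DC removal → band-pass → rectify → leaky integration.

    The band-pass is a zero-phase forward-backward Butterworth filter of
    the given order. An upper band edge at or above Nyquist is clipped to
    0.45 × rate (logged); the sampling rate must exceed twice the lower
    edge.
    """
    lo, hi = band
    if lo <= 0 or hi <= lo:
        raise ValueError("band edges must satisfy 0 < low < high")
    nyquist = raw.rate / 2.0
    if raw.rate < 2.0 * lo or 0.45 * raw.rate <= lo:
        raise ValueError(f"sampling rate {raw.rate} Hz too low for a {lo} Hz lower edge")
    if hi >= nyquist:
        hi_clipped = 0.45 * raw.rate
        logger.info("band upper edge %.0f Hz >= Nyquist; clipped to %.0f Hz", hi, hi_clipped)
        hi = hi_clipped

    x = raw.samples - raw.samples.mean()
    sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=raw.rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return exponential_smooth(np.abs(x), raw.rate, tau_ms=tau_ms)


def beat_average_relative(
    trace: np.ndarray,
    rate: float,
    beat_times: np.ndarray,
    background: float = 0.0,
    baseline_beats: int = 10,
    event_time: float | None = None,
) -> np.ndarray:
    """Per-heartbeat relative nerve activity (%, baseline = 100).

    The background level is subtracted from the whole integrated trace,
    the trace is averaged over each interbeat window [t_b, t_{b+1}), and
    every beat is scaled by the mean of the ``baseline_beats`` beats
    immediately before ``event_time`` (default: the beat right after the
    baseline block). Raises when the baseline mean is not positive —
    the signal is then indistinguishable from the noise floor.
    """
    trace = np.asarray(trace, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    n = trace.size
    if beat_times.size < baseline_beats + 1:
        raise ValueError(f"need more than {baseline_beats} beats")
    if event_time is None:
        event_time = float(beat_times[baseline_beats])

    corrected = trace - background
    means = np.empty(beat_times.size)
    edges = np.round(beat_times * rate).astype(int)
    edges = np.append(edges, n)
    for b in range(beat_times.size):
        lo, hi = max(edges[b], 0), min(edges[b + 1], n)
        if hi <= lo:
            raise ValueError(f"beat {b} window is empty at this sampling rate")
        means[b] = corrected[lo:hi].mean()

    pre = np.nonzero(beat_times < event_time)[0]
    if pre.size < baseline_beats:
        raise ValueError(f"fewer than {baseline_beats} beats before the event")
    baseline = means[pre[-baseline_beats:]].mean()
    if baseline <= 0:
        raise ValueError("baseline activity not above background noise")
    return 100.0 * means / baseline
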