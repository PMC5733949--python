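"""Stimulus-timing audit for audio-loopback recordings.

A timing test feeds the stimulus device's audio output (a square-wave
burst per trial) straight into one recording channel, while the stimulus
software emits an event marker per intended playback.  The audit measures,
per trial, the latency between the marker and the physical sound onset,
and summarises a session by its lag (central tendency of latencies) and
jitter (their trial-to-trial standard deviation).

Onset detection follows a half-maximum rule: the rectified trial-averaged
response sets a threshold at half its maximum, and each single trial's
latency is the time from the marker to the first sample whose rectified
amplitude exceeds that threshold.  The threshold is relative, so the audit
is invariant to the loopback channel's gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_streams import ContinuousRecording, MarkerStream
from .preprocess import extract_epochs

__all__ = ["TimingReport", "SessionComparison", "measure_latencies",
           "session_compare"]


@dataclass
class TimingReport:
    """Per-trial onset latencies (seconds; NaN = no detectable onset) and
    session summary statistics.

    ``jitter_sd`` uses the n-1 denominator.  Outliers are flagged by the
    1.5·IQR rule on the detected latencies.
    """

    latencies: np.ndarray
    lag_mean: float
    lag_median: float
    jitter_sd: float
    outlier_indices: list[int]
    half_max_threshold: float
    n_trials: int
    fs: float

    @property
    def sample_period(self) -> float:
        """Measurement resolution of the audit: one sample period, seconds."""
        return 1.0 / self.fs

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.latencies).sum())


def measure_latencies(recording: ContinuousRecording, markers: MarkerStream,
                      search_window: tuple[float, float] = (0.0, 0.2),
                      ) -> TimingReport:
    """Measure per-trial marker-to-onset latencies on a loopback channel.

    Procedure: epoch the (single) audio channel around each marker over
    ``search_window``; rectify and average the trials; set the threshold
    at half the maximum of that average; per trial, the latency is the
    time from the marker to the first rectified sample above threshold.
    Trials that never cross are reported as missing (NaN) and excluded
    from the summary statistics.

    The default window is causal (0–200 ms after the marker); pass a
    negative lower edge (e.g. ``(-0.04, 0.2)``) to also search for sound
    onsets that precede their marker, as happens when a stimulus stack
    timestamps markers late.
    """
    if len(markers) < 1:
        raise ValueError("need at least one marker")
    if recording.n_channels != 1:
        raise ValueError("timing audit expects a single loopback channel")

    epochs, skipped = extract_epochs(recording, markers, window=search_window)
    if epochs.n_trials == 0:
        raise ValueError(f"no usable trials ({len(skipped)} markers out of range)")

    rect = np.abs(epochs.trials[:, 0, :])
    avg = rect.mean(axis=0)
    threshold = 0.5 * float(avg.max())
    times = epochs.times  # seconds relative to the marker

    latencies = np.full(epochs.n_trials, np.nan)
    for i in range(epochs.n_trials):
        above = np.flatnonzero(rect[i] > threshold)
        if above.size:
            latencies[i] = times[above[0]]

    detected = latencies[~np.isnan(latencies)]
    if detected.size == 0:
        raise ValueError("no detectable onsets in any trial")

    q1, q3 = np.percentile(detected, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [int(i) for i in np.flatnonzero(
        ~np.isnan(latencies) & ((latencies < lo) | (latencies > hi)))]

    return TimingReport(
        latencies=latencies,
        lag_mean=float(detected.mean()),
        lag_median=float(np.median(detected)),
        jitter_sd=float(detected.std(ddof=1)) if detected.size > 1 else 0.0,
        outlier_indices=outliers,
        half_max_threshold=threshold,
        n_trials=epochs.n_trials,
        fs=recording.fs,
    )


@dataclass
class SessionComparison:
    """Across-session view of repeated timing tests."""

    session_medians: list[float]
    spread: float                       # max - min of the session medians, s
    median_of_medians: float
    negative_lag_sessions: list[int]    # sessions whose median lag is < 0


def session_compare(reports: list[TimingReport]) -> SessionComparison:
    """Compare median lags across repeated timing-test sessions.

    Within-session jitter is typically small, but the median lag can move
    considerably between sessions (and occasionally go negative, when
    markers are timestamped after the physical sound onset) — so the
    across-session spread of medians is the quantity to watch.
    """
    if len(reports) < 2:
        raise ValueError("need at least two sessions to compare")
    medians = [r.lag_median for r in reports]
    return SessionComparison(
        session_medians=medians,
        spread=float(max(medians) - min(medians)),
        median_of_medians=float(np.median(medians)),
        negative_lag_sessions=[i for i, m in enumerate(medians) if m < 0],
    )
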