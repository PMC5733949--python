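"""Online-style EEG preprocessing: epoching, baseline, causal filtering,
rereferencing, and joint-probability epoch rejection.

The pipeline mirrors an online single-trial analysis chain and is therefore
strictly causal: epochs are cut by timestamp with a half-open window,
baseline correction subtracts the whole-epoch mean, and the bandpass is a
single forward pass of a Butterworth IIR filter realised in Direct Form II
Transposed with zero initial state per trial.  Zero-phase (two-pass)
filtering is deliberately not offered — it cannot exist in a causal system.

Canonical pipeline order, fixed and documented: extract -> baseline ->
filter -> rereference.  Baseline correction and rereferencing are both
linear and commute; the order is a convention, not a constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .io_streams import ContinuousRecording, MarkerStream, onset_sample

__all__ = [
    "EpochSet",
    "FilterSpec",
    "extract_epochs",
    "baseline_correct",
    "design_bandpass",
    "filter_causal",
    "rereference",
    "reject_epochs_jointprob",
]


@dataclass
class EpochSet:
    """Marker-locked trials: ``trials`` has shape (n_trials, n_channels, n_win).

    ``window`` is the (t_min, t_max) extraction window in seconds relative
    to each trial's onset marker, half-open, with
    ``n_win = round((t_max - t_min) * fs)``.
    """

    trials: np.ndarray
    labels: list[str]
    window: tuple[float, float]
    fs: float
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels length must equal trial count")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.trials.shape[1]:
            raise ValueError("channel_labels length must equal channel count")
        n_win = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.trials.shape[2] != n_win:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {n_win} samples, "
                f"trials have {self.trials.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_win(self) -> int:
        return self.trials.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times relative to the onset marker, in seconds."""
        return self.window[0] + np.arange(self.n_win) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; available: {', '.join(self.channel_labels)}"
            ) from None

    def select_labels(self, wanted: Sequence[str]) -> "EpochSet":
        keep = [i for i, lb in enumerate(self.labels) if lb in set(wanted)]
        return replace(self, trials=self.trials[keep],
                       labels=[self.labels[i] for i in keep])


def extract_epochs(recording: ContinuousRecording, markers: MarkerStream,
                   window: tuple[float, float] = (-0.5, 3.5),
                   label_map: Mapping[str, str] | None = None,
                   ) -> tuple[EpochSet, list[str]]:
    """Cut marker-locked trials out of a continuous recording.

    The onset sample of each marker is the first sample with timestamp >=
    the marker time; the trial covers ``data[:, s0 : s0 + n_win)`` with
    ``s0 = onset + round(t_min * fs)``.  Markers whose window falls outside
    the recording are skipped and reported, never silently dropped.

    Parameters
    ----------
    label_map
        Optional mapping from marker label to trial label; markers whose
        label is missing from the map are ignored entirely.  With ``None``
        every marker produces a trial labelled with its own marker label.

    Returns
    -------
    (EpochSet, skipped)
        ``skipped`` lists one message per out-of-range marker.
    """
    t_min, t_max = window
    if not t_min < t_max:
        raise ValueError("window must satisfy t_min < t_max")
    n_win = int(round((t_max - t_min) * recording.fs))
    off = int(round(t_min * recording.fs))

    trials, labels, skipped = [], [], []
    for m in markers:
        if label_map is not None and m.label not in label_map:
            continue
        s0 = onset_sample(m.time, recording.start_time, recording.fs) + off
        if s0 < 0 or s0 + n_win > recording.n_samples:
            skipped.append(
                f"marker {m.label!r} at t={m.time}: window outside recording"
            )
            continue
        trials.append(recording.data[:, s0:s0 + n_win])
        labels.append(label_map[m.label] if label_map else m.label)

    arr = (np.stack(trials) if trials
           else np.empty((0, recording.n_channels, n_win)))
    return (EpochSet(arr, labels, (t_min, t_max), recording.fs,
                     recording.channel_labels), skipped)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract, per trial and channel, the mean over the whole epoch.

    Idempotent; after correction every channel of every trial has zero mean
    (to ~1e-12 µV).
    """
    if epochs.n_trials == 0:
        return replace(epochs, trials=epochs.trials.copy())
    corrected = epochs.trials - epochs.trials.mean(axis=2, keepdims=True)
    return replace(epochs, trials=corrected)


@dataclass(frozen=True)
class FilterSpec:
    """A designed causal Butterworth bandpass.

    ``prototype_order`` is the order of the analog lowpass prototype; the
    bandpass transformation doubles it, so the default prototype order 4
    yields an order-8 transfer function (the common toolbox convention for
    a "4th-order bandpass").  Set ``interpret='overall'`` in
    :func:`design_bandpass` to request the stated order as the overall
    bandpass order instead.
    """

    b: tuple[float, ...]
    a: tuple[float, ...]
    band: tuple[float, float]
    fs: float
    prototype_order: int

    def magnitude(self, freqs) -> np.ndarray:
        """|H(f)| of the designed digital filter at frequencies in Hz."""
        _, h = scipy.signal.freqz(self.b, self.a, worN=np.atleast_1d(freqs),
                                  fs=self.fs)
        return np.abs(h)

    @property
    def stable(self) -> bool:
        poles = np.roots(self.a)
        return bool(np.all(np.abs(poles) < 1.0))


def design_bandpass(band: tuple[float, float] = (1.0, 11.0), fs: float = 250.0,
                    prototype_order: int = 4,
                    interpret: str = "prototype") -> FilterSpec:
    """Design the Butterworth bandpass used for single-trial preprocessing.

    Parameters
    ----------
    band
        (f_lo, f_hi) passband edges in Hz; default 1–11 Hz, the band that
        retains slow evoked-response energy while rejecting drift and
        line noise.
    interpret
        ``'prototype'``: ``prototype_order`` is the analog lowpass prototype
        order (bandpass order doubles).  ``'overall'``: the stated order is
        the overall bandpass order (must be even).
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError(f"band {band} must satisfy 0 < f_lo < f_hi < fs/2 = {fs / 2}")
    if interpret == "prototype":
        order = prototype_order
    elif interpret == "overall":
        if prototype_order % 2:
            raise ValueError("overall bandpass order must be even")
        order = prototype_order // 2
    else:
        raise ValueError("interpret must be 'prototype' or 'overall'")
    b, a = scipy.signal.butter(order, band, btype="bandpass", fs=fs)
    spec = FilterSpec(tuple(b), tuple(a), (float(f_lo), float(f_hi)), float(fs),
                      prototype_order=order)
    if not spec.stable:
        raise ValueError(f"designed filter for band {band} at fs={fs} is unstable")
    return spec


def filter_causal(obj, spec: FilterSpec):
    """Single causal forward pass of *spec* (Direct Form II Transposed).

    Applied per trial and channel with zero initial filter state, exactly
    as an online system filters each freshly buffered trial.  Accepts an
    :class:`EpochSet` or a :class:`ContinuousRecording` (the latter is
    filtered as one continuous segment).
    """
    if not spec.stable:
        raise ValueError("refusing to apply an unstable filter")
    if isinstance(obj, EpochSet):
        out = scipy.signal.lfilter(spec.b, spec.a, obj.trials, axis=2)
        return replace(obj, trials=out)
    if isinstance(obj, ContinuousRecording):
        out = scipy.signal.lfilter(spec.b, spec.a, obj.data, axis=1)
        return ContinuousRecording(out, fs=obj.fs,
                                   channel_labels=obj.channel_labels,
                                   start_time=obj.start_time)
    raise TypeError(f"cannot filter object of type {type(obj).__name__}")


def rereference(obj, channel: str, reference: str):
    """Derive a single bipolar channel: ``channel - reference``, samplewise.

    The derived channel is labelled ``"{channel}-{reference}"`` (e.g.
    ``"Cz-TP9"``, a frontocentral site against a mastoid).  Returns an
    object of the same kind with exactly one channel.
    """
    label = f"{channel}-{reference}"
    if isinstance(obj, EpochSet):
        ci, ri = obj.channel_index(channel), obj.channel_index(reference)
        out = obj.trials[:, ci:ci + 1, :] - obj.trials[:, ri:ri + 1, :]
        return replace(obj, trials=out, channel_labels=(label,))
    if isinstance(obj, ContinuousRecording):
        ci, ri = obj.channel_index(channel), obj.channel_index(reference)
        out = obj.data[ci:ci + 1, :] - obj.data[ri:ri + 1, :]
        return ContinuousRecording(out, fs=obj.fs, channel_labels=(label,),
                                   start_time=obj.start_time)
    raise TypeError(f"cannot rereference object of type {type(obj).__name__}")


def _jointprob_scores(trials: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Per-trial mean negative log-density score, averaged over channels.

    For each channel, the empirical amplitude distribution is estimated by
    a histogram over all trials' samples; each trial is scored by the mean
    negative log of the density at its samples, and scores are averaged
    across channels.  Improbable (artifact-laden) trials score high.
    """
    n_trials, n_channels, _ = trials.shape
    scores = np.zeros((n_trials, n_channels))
    for c in range(n_channels):
        pooled = trials[:, c, :].ravel()
        hist, edges = np.histogram(pooled, bins=n_bins, density=True)
        # density floor of one pooled count per bin, avoids -log(0)
        bin_width = (edges[-1] - edges[0]) / n_bins
        dens = np.maximum(hist, 1.0 / (pooled.size * bin_width + 1e-300))
        idx = np.clip(np.searchsorted(edges, trials[:, c, :], side="right") - 1,
                      0, n_bins - 1)
        scores[:, c] = -np.log(dens[idx]).mean(axis=1)
    return scores.mean(axis=1)


def reject_epochs_jointprob(epochs: EpochSet, sd_criterion: float = 2.0,
                            n_bins: int = 32) -> tuple[EpochSet, list[int]]:
    """Reject improbable trials by a joint log-probability criterion.

    A simplified, self-contained variant of joint-probability artifact
    rejection: trials whose improbability score exceeds
    ``mean + sd_criterion * SD`` of the scores are rejected, and the
    criterion is applied once more on the survivors (one iteration).
    Exact parity with any external toolbox routine is a non-goal; the
    behaviour here is fully specified by :func:`_jointprob_scores`.

    Returns the kept :class:`EpochSet` and the indices (into the input)
    of rejected trials.
    """
    if epochs.n_trials < 3:
        raise ValueError("joint-probability rejection needs at least 3 trials")
    keep = np.arange(epochs.n_trials)
    rejected: list[int] = []
    for _ in range(2):  # initial pass + one iteration
        if keep.size < 3 or not np.isfinite(sd_criterion):
            break
        scores = _jointprob_scores(epochs.trials[keep], n_bins=n_bins)
        sd = scores.std(ddof=1)
        if sd == 0:
            break
        bad = scores > scores.mean() + sd_criterion * sd
        if not bad.any():
            break
        rejected.extend(int(i) for i in keep[bad])
        keep = keep[~bad]
    kept = replace(epochs, trials=epochs.trials[keep],
                   labels=[epochs.labels[i] for i in keep])
    return kept, sorted(rejected)
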