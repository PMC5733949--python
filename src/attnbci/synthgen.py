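"""Synthetic EEG, marker streams, and audio-loopback timing fixtures.

Every downstream stage of the pipeline — buffering, preprocessing,
classification, timing audit, ERP statistics — is exercised against data
from this module, which therefore carries its ground truth openly: the
:class:`GroundTruth` record stores the exact trial labels, onset times,
injected per-trial lags and ERP component parameters that the generators
used, so recovery can be asserted rather than eyeballed.

Three generators:

* :func:`gen_recording` — a two-class selective-attention session:
  marker-locked class templates (distinct burst envelopes, echoing
  melody streams with different tone counts) added to 1/f background
  noise on a 24-channel, 250 Hz montage.
* :func:`gen_erp_cohort` — per-subject recordings with a P1–N100–P200
  complex after sound onsets and a feedback response where the incorrect
  condition carries an extra negative shift in the FRN window.
* :func:`gen_timing_fixture` — a single-channel audio-loopback session:
  a square-wave burst begins a known, normally distributed lag after
  each marker, quantized (floor) to the sample grid.

All generators are bit-deterministic given their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .io_streams import (DEFAULT_MONTAGE, ContinuousRecording, EventMarker,
                         MarkerStream)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "pink_noise",
    "default_class_templates",
    "gen_recording",
    "gen_erp_cohort",
    "gen_timing_fixture",
]

#: Relative evoked-response gain per electrode: frontocentral maximum,
#: near-zero at the mastoids (so a frontocentral-vs-mastoid bipolar
#: derivation retains the signal).
TOPOGRAPHY_GAIN: dict[str, float] = {
    "Fp1": 0.40, "Fp2": 0.40, "F7": 0.35, "Fz": 0.90, "F8": 0.35,
    "FC1": 0.95, "FC2": 0.95, "C3": 0.70, "Cz": 1.00, "C4": 0.70,
    "T7": 0.30, "T8": 0.30, "TP9": 0.05, "TP10": 0.05, "CP5": 0.40,
    "CP1": 0.65, "CPz": 0.70, "CP2": 0.65, "CP6": 0.40, "P3": 0.45,
    "Pz": 0.50, "P4": 0.45, "O1": 0.20, "O2": 0.20,
}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic attention session.

    Defaults mirror a smartphone-amplifier recording setup: 24 channels at
    250 Hz, trials epoched from −500 ms to +3500 ms around onset, 3 s of
    stimulus playback, and an inter-trial interval long enough for the
    full epoch window plus a break.
    """

    n_channels: int = 24
    fs: float = 250.0
    n_trials_per_class: int = 20
    epoch_window: tuple[float, float] = (-0.5, 3.5)
    class_templates: dict[str, np.ndarray] | None = None  # label -> ch x n
    noise_sd: float = 10.0
    inter_trial_interval: float = 6.5
    seed: int = 0
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials_per_class < 0:
            raise ValueError("n_trials_per_class must be >= 0")
        t_min, t_max = self.epoch_window
        if not t_min < t_max:
            raise ValueError("epoch window must satisfy t_min < t_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.inter_trial_interval < (t_max - t_min):
            raise ValueError(
                f"inter-trial interval {self.inter_trial_interval} s shorter "
                f"than the epoch window ({t_max - t_min} s): trials would overlap"
            )
        if self.channel_labels is None:
            if self.n_channels == len(DEFAULT_MONTAGE):
                self.channel_labels = DEFAULT_MONTAGE
            else:
                self.channel_labels = tuple(
                    f"ch{i:02d}" for i in range(self.n_channels))
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")


@dataclass
class GroundTruth:
    """Hidden parameters of a generated session, kept for recovery tests."""

    trial_labels: list[str]
    true_onset_times: np.ndarray
    injected_lag_per_trial: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    erp_components: list[tuple] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.true_onset_times = np.asarray(self.true_onset_times, dtype=float)
        self.injected_lag_per_trial = np.asarray(self.injected_lag_per_trial,
                                                 dtype=float)
        if len(self.trial_labels) != self.true_onset_times.size:
            raise ValueError("one label per onset required")
        if not np.all(np.isfinite(self.injected_lag_per_trial)):
            raise ValueError("injected lags must be finite")


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               sd: float) -> np.ndarray:
    """1/f ("pink") noise by spectral shaping of white Gaussian noise.

    The white spectrum is scaled by 1/sqrt(f) (DC removed) and each channel
    is renormalised to standard deviation ``sd`` µV, giving an EEG-like
    power spectrum without modelling physiology.
    """
    if sd == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped * (sd / std)


def _hann_bump(fs: float, center: float, width: float, amplitude: float,
               length: int) -> np.ndarray:
    """Compactly supported Hann bump on the sample grid.

    Peak value is exactly ``amplitude`` at the grid sample nearest
    ``center``; zero outside ``center ± width/2``.  Compact support keeps
    component injections from bleeding into each other's measurement
    windows.
    """
    out = np.zeros(length)
    half = int(round(width / 2 * fs))
    c = int(round(center * fs))
    if half == 0:
        if 0 <= c < length:
            out[c] = amplitude
        return out
    w = amplitude * np.hanning(2 * half + 1)
    lo, hi = c - half, c + half + 1
    src_lo, src_hi = max(0, -lo), (2 * half + 1) - max(0, hi - length)
    out[max(0, lo):min(length, hi)] = w[src_lo:src_hi]
    return out


def default_class_templates(config: SynthConfig, duration: float = 3.0,
                            amplitude: float = 5.0) -> dict[str, np.ndarray]:
    """Two discriminable marker-locked envelopes: 4 bursts vs 5 bursts.

    Each class template spans the stimulus playback (default 3 s) and is a
    train of Hann-windowed bursts — 4 for "left", 5 for "right", echoing
    competing melody streams with different tone counts — scaled per
    channel by the frontocentral topography gain.  The differing burst
    timing makes the two classes separable by lagged cross-correlation.
    """
    n = int(round(duration * config.fs))
    gains = np.array([TOPOGRAPHY_GAIN.get(ch, 0.5)
                      for ch in config.channel_labels])
    out: dict[str, np.ndarray] = {}
    for label, n_bursts in (("left", 4), ("right", 5)):
        env = np.zeros(n)
        centers = np.linspace(0.3, duration - 0.3, n_bursts)
        for c in centers:
            env += _hann_bump(config.fs, c, 0.35, amplitude, n)
        out[label] = gains[:, None] * env[None, :]
    return out


def _inject(data: np.ndarray, onset: int, component: np.ndarray) -> None:
    """Add ``component`` (channels x k) to ``data`` starting at sample ``onset``."""
    k = component.shape[1]
    lo, hi = max(0, onset), min(data.shape[1], onset + k)
    if hi > lo:
        data[:, lo:hi] += component[:, lo - onset:hi - onset]


def gen_recording(config: SynthConfig,
                  ) -> tuple[ContinuousRecording, MarkerStream, GroundTruth]:
    """Generate a two-class selective-attention session.

    One onset marker per trial, labelled with its class; at each onset the
    class's template is added to pink background noise.  Trial order is a
    seeded permutation with exact class counts.  Markers lie on the sample
    grid, with at least ``|t_min|`` s of lead-in and ``t_max`` s of tail.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    templates = config.class_templates or default_class_templates(config)
    for label, tpl in templates.items():
        if tpl.shape[0] != config.n_channels:
            raise ValueError(
                f"template {label!r} has {tpl.shape[0]} channels, "
                f"config has {config.n_channels}"
            )
    t_min, t_max = config.epoch_window
    tpl_len = max((t.shape[1] for t in templates.values()), default=0)

    labels = [lb for lb in templates for _ in range(config.n_trials_per_class)]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    n_trials = len(labels)

    lead_in = abs(t_min) + 0.5
    onset_samples = np.array([
        int(round((lead_in + i * config.inter_trial_interval) * fs))
        for i in range(n_trials)
    ], dtype=int)
    tail = max(t_max, tpl_len / fs) + 0.5
    n_samples = int(round(((onset_samples[-1] / fs if n_trials else lead_in)
                           + tail) * fs))

    data = pink_noise(rng, config.n_channels, n_samples, config.noise_sd)
    for lb, s in zip(labels, onset_samples):
        _inject(data, s, templates[lb])

    onset_times = onset_samples / fs
    recording = ContinuousRecording(data, fs=fs,
                                    channel_labels=config.channel_labels)
    markers = MarkerStream([EventMarker(lb, float(t))
                            for lb, t in zip(labels, onset_times)])
    truth = GroundTruth(trial_labels=labels, true_onset_times=onset_times,
                        seed=config.seed)
    return recording, markers, truth


def gen_erp_cohort(n_subjects: int,
                   n100_latency: float = 0.177,
                   n100_amplitude: float = -2.6,
                   frn_shift: float = -2.0,
                   noise_sd: float = 5.0,
                   seed: int = 0,
                   n_sound_trials: int = 30,
                   n_feedback_per_condition: int = 25,
                   fs: float = 250.0,
                   ) -> list[tuple[ContinuousRecording, MarkerStream, GroundTruth]]:
    """Generate a cohort of subjects for ERP validation.

    Each subject's recording contains sound-onset trials carrying a
    P1–N100–P200 complex — the N100 trough at ``n100_latency`` (quantized
    to the sample grid) with peak amplitude ``n100_amplitude`` µV at the
    vertex — followed by feedback trials in which the incorrect condition
    carries an additional ``frn_shift`` µV boxcar over 250–300 ms on the
    frontocentral ROI channels (Fz, FC1, FC2, Cz).

    Defaults emulate a frontocentral auditory evoked response to slowly
    ramping complex sounds (late N100) and a typical FRN effect size.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    labels = DEFAULT_MONTAGE
    n_ch = len(labels)
    gains = np.array([TOPOGRAPHY_GAIN.get(ch, 0.5) for ch in labels])
    roi_mask = np.array([ch in ("Fz", "FC1", "FC2", "Cz") for ch in labels],
                        dtype=float)

    lat_q = round(n100_latency * fs) / fs
    comp_len = int(round(0.8 * fs))
    aep = (_hann_bump(fs, 0.06, 0.06, 1.2, comp_len)          # P1
           + _hann_bump(fs, lat_q, 0.08, n100_amplitude, comp_len)  # N100
           + _hann_bump(fs, 0.28, 0.08, 1.5, comp_len))       # P200
    aep_chan = gains[:, None] * aep[None, :]
    # Cz carries the component at unit gain so the vertex measurement is exact
    assert TOPOGRAPHY_GAIN["Cz"] == 1.0

    fb_common = _hann_bump(fs, 0.35, 0.20, 3.0, comp_len)     # P300-like
    fb_common_chan = gains[:, None] * fb_common[None, :]
    t_rel = np.arange(comp_len) / fs
    frn_box = ((t_rel >= 0.25) & (t_rel < 0.30)).astype(float) * frn_shift
    frn_chan = roi_mask[:, None] * frn_box[None, :]

    iti = 1.5
    lead_in = 0.7
    out = []
    rng = np.random.default_rng(seed)
    for _ in range(n_subjects):
        subj_seed = int(rng.integers(0, 2**31 - 1))
        srng = np.random.default_rng(subj_seed)
        fb_labels = (["fb_correct"] * n_feedback_per_condition
                     + ["fb_incorrect"] * n_feedback_per_condition)
        fb_labels = [fb_labels[i] for i in srng.permutation(len(fb_labels))]
        trial_labels = ["sound_onset"] * n_sound_trials + fb_labels
        n_trials = len(trial_labels)
        onsets = np.array([int(round((lead_in + i * iti) * fs))
                           for i in range(n_trials)])
        n_samples = int(round(onsets[-1] + (0.8 + 0.5) * fs))
        data = pink_noise(srng, n_ch, n_samples, noise_sd)
        for lb, s in zip(trial_labels, onsets):
            if lb == "sound_onset":
                _inject(data, s, aep_chan)
            else:
                _inject(data, s, fb_common_chan)
                if lb == "fb_incorrect":
                    _inject(data, s, frn_chan)
        recording = ContinuousRecording(data, fs=fs, channel_labels=labels)
        markers = MarkerStream([EventMarker(lb, float(s / fs))
                                for lb, s in zip(trial_labels, onsets)])
        truth = GroundTruth(
            trial_labels=trial_labels,
            true_onset_times=onsets / fs,
            erp_components=[
                (("Cz",), lat_q, n100_amplitude, 0.08, "N100"),
                (("Fz", "FC1", "FC2", "Cz"), 0.275, frn_shift, 0.05, "FRN"),
            ],
            seed=subj_seed,
        )
        out.append((recording, markers, truth))
    return out


def gen_timing_fixture(lag_mean: float = 0.01267,
                       jitter_sd: float = 0.00287,
                       n_trials: int = 200,
                       square_freq: float = 25.0,
                       fs: float = 250.0,
                       seed: int = 0,
                       burst_duration: float = 0.1,
                       trial_spacing: float = 0.5,
                       amplitude: float = 1.0,
                       ) -> tuple[ContinuousRecording, MarkerStream, GroundTruth]:
    """Audio-loopback timing fixture: square bursts a known lag after markers.

    After each of ``n_trials`` markers, a square-wave burst begins at
    ``marker_time + lag_i`` with ``lag_i ~ Normal(lag_mean, jitter_sd**2)``
    drawn before quantization, then floored to the sample grid.  The
    ground truth stores the exact post-quantization per-trial lags, so a
    timing audit can be scored against what was physically injected.

    Defaults emulate a realistic smartphone audio stack: ~13 ms mean lag,
    ~3 ms jitter, 200 trials per session.
    """
    if lag_mean + 4 * jitter_sd >= trial_spacing - burst_duration:
        raise ValueError(
            "lag_mean + 4*jitter_sd must be shorter than the inter-trial "
            "spacing minus the burst duration"
        )
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lags = rng.normal(lag_mean, jitter_sd, size=n_trials) if jitter_sd > 0 \
        else np.full(n_trials, lag_mean)

    lead_in = 0.5
    marker_samples = np.array([int(round((lead_in + i * trial_spacing) * fs))
                               for i in range(n_trials)])
    lag_samples = np.floor(lags * fs + 1e-9).astype(int)   # floor-to-grid
    onset_samples = marker_samples + lag_samples
    if np.any(np.diff(onset_samples) <= 0) or np.any(onset_samples < 0):
        raise ValueError("jitter produced out-of-order or negative onsets")

    burst_n = int(round(burst_duration * fs))
    t_burst = np.arange(burst_n) / fs
    burst = amplitude * scipy.signal.square(2 * np.pi * square_freq * t_burst)

    n_samples = int(onset_samples[-1] + burst_n + round(0.5 * fs))
    data = np.zeros((1, n_samples))
    for s in onset_samples:
        data[0, s:s + burst_n] += burst

    recording = ContinuousRecording(data, fs=fs, channel_labels=("audio",))
    markers = MarkerStream([EventMarker("burst", float(s / fs))
                            for s in marker_samples])
    truth = GroundTruth(
        trial_labels=["burst"] * n_trials,
        true_onset_times=onset_samples / fs,
        injected_lag_per_trial=lag_samples / fs,
        seed=seed,
    )
    return recording, markers, truth
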