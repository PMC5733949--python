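"""End-to-end closed-loop runs: simulate -> stream/batch -> preprocess ->
classify -> feedback record.

A run emulates one session of a feedback BCI experiment: a training block
whose trials build the per-class templates, then a feedback block whose
trials are classified one by one, each classification standing in for the
feedback shown to a user.  ``mode="batch"`` processes the feedback
recording in one pass; ``mode="replay"`` pushes it chunk-by-chunk through
the marker-triggered stream buffer exactly as a live system would — the
two modes produce identical classifications, which is the core online/
offline equivalence contract of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .classify import (ChanceLevel, build_templates, chance_level,
                       classify_trial)
from .io_streams import (ContinuousRecording, EventMarker, MarkerStream,
                         StreamBuffer, StreamChunk, replay)
from .preprocess import (EpochSet, baseline_correct, design_bandpass,
                         extract_epochs, filter_causal, rereference)
from .synthgen import SynthConfig, gen_recording

__all__ = ["RunConfig", "RunReport", "run_closed_loop", "preprocess_trial_set"]


@dataclass
class RunConfig:
    """Effective parameters of a closed-loop run.

    Block sizes default to the standard session layout of the paradigm:
    40 training trials (20 per attended side) and 120 feedback trials.
    """

    seed: int = 0
    mode: str = "batch"                      # "batch" | "replay"
    n_train_per_class: int = 20
    n_feedback_per_class: int = 60
    noise_sd: float = 10.0
    window: tuple[float, float] = (-0.5, 3.5)
    band: tuple[float, float] = (1.0, 11.0)
    prototype_order: int = 4
    max_lag_s: float = 0.032
    channel: str = "Cz"
    reference: str = "TP9"
    chunk_size: int = 250
    alpha: float = 0.05
    inter_trial_interval: float = 6.5

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "replay"):
            raise ValueError("mode must be 'batch' or 'replay'")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-trial feedback labels and session summary of a closed-loop run."""

    trial_labels: list[str]          # classifier output per feedback trial
    true_labels: list[str]
    r_left: list[float]
    r_right: list[float]
    n_correct: int
    accuracy: float
    chance: ChanceLevel
    above_chance: bool
    mode: str
    seed: int
    config_hash: str
    version: str

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def preprocess_trial_set(epochs: EpochSet, config: RunConfig) -> EpochSet:
    """The canonical single-trial chain: baseline -> causal bandpass ->
    bipolar rereference to ``channel - reference``."""
    spec = design_bandpass(config.band, epochs.fs,
                           prototype_order=config.prototype_order)
    out = baseline_correct(epochs)
    out = filter_causal(out, spec)
    return rereference(out, config.channel, config.reference)


def _feedback_epochs_replay(recording: ContinuousRecording,
                            markers: MarkerStream,
                            config: RunConfig) -> EpochSet:
    """Collect feedback trials through the stream buffer, chunk by chunk."""
    buffer = StreamBuffer(recording.fs, config.window,
                          capacity=max(10.0, 2 * (config.window[1]
                                                  - config.window[0])))
    collected = []

    def sink(item):
        if isinstance(item, EventMarker):
            collected.extend(buffer.push_marker(item))
        elif isinstance(item, StreamChunk):
            collected.extend(buffer.push_chunk(item))

    replay(recording, markers, config.chunk_size, sink)
    trials = np.stack([c.data for c in collected])
    labels = [c.marker.label for c in collected]
    return EpochSet(trials, labels, config.window, recording.fs,
                    recording.channel_labels)


def run_closed_loop(config: RunConfig) -> RunReport:
    """Run one simulated closed-loop session and score it.

    Training and feedback blocks are generated with independent seeds
    derived from ``config.seed``; templates are built from the training
    block and every feedback trial is classified against them.  The
    summary compares the session accuracy against the exact binomial
    chance level for the number of feedback trials.
    """
    train_cfg = SynthConfig(n_trials_per_class=config.n_train_per_class,
                            noise_sd=config.noise_sd,
                            epoch_window=config.window,
                            inter_trial_interval=config.inter_trial_interval,
                            seed=config.seed)
    fb_cfg = SynthConfig(n_trials_per_class=config.n_feedback_per_class,
                         noise_sd=config.noise_sd,
                         epoch_window=config.window,
                         inter_trial_interval=config.inter_trial_interval,
                         seed=config.seed + 1)
    train_rec, train_mk, _ = gen_recording(train_cfg)
    fb_rec, fb_mk, fb_truth = gen_recording(fb_cfg)

    train_ep, skipped = extract_epochs(train_rec, train_mk, config.window)
    if skipped:
        raise RuntimeError(f"training stage: {len(skipped)} trials skipped: "
                           f"{skipped[0]}")
    templates = build_templates(preprocess_trial_set(train_ep, config))

    if config.mode == "replay":
        fb_raw = _feedback_epochs_replay(fb_rec, fb_mk, config)
    else:
        fb_raw, skipped = extract_epochs(fb_rec, fb_mk, config.window)
        if skipped:
            raise RuntimeError(f"feedback stage: {len(skipped)} trials "
                               f"skipped: {skipped[0]}")
    fb_ep = preprocess_trial_set(fb_raw, config)

    out_labels, r_left, r_right = [], [], []
    for i in range(fb_ep.n_trials):
        res = classify_trial(fb_ep.trials[i, 0, :], templates,
                             max_lag_s=config.max_lag_s, fs=fb_ep.fs)
        out_labels.append(res.label)
        r_left.append(res.r_left)
        r_right.append(res.r_right)

    true_labels = list(fb_ep.labels)
    n_correct = sum(a == b for a, b in zip(out_labels, true_labels))
    n = len(true_labels)
    chance = chance_level(n, 2, config.alpha)
    accuracy = n_correct / n
    return RunReport(
        trial_labels=out_labels,
        true_labels=true_labels,
        r_left=r_left,
        r_right=r_right,
        n_correct=n_correct,
        accuracy=accuracy,
        chance=chance,
        above_chance=100.0 * accuracy >= chance.threshold_percent,
        mode=config.mode,
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
    )
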