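"""Event-related potential validation statistics.

Two ERP components serve as physiological sanity checks of a recording
chain:

* the auditory N100 — a negative deflection over frontocentral sites
  following sound onset (late, ~150–200 ms, for slowly ramping complex
  sounds), measured at the vertex channel as the most negative sample of
  the trial average within a search window;
* the feedback-related negativity (FRN) — a relative negativity after
  unfavourable feedback, quantified as the mean amplitude 250–300 ms
  post-feedback over a frontocentral region of interest (Fz, FC1, FC2,
  Cz), and reported as the incorrect-minus-correct difference.

Group inference uses one value per subject and plain t statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .preprocess import EpochSet

__all__ = ["ErpResult", "TTestResult", "DEFAULT_FRN_ROI", "n100_measure",
           "frn_measure", "ttest"]

DEFAULT_FRN_ROI: tuple[str, ...] = ("Fz", "FC1", "FC2", "Cz")


@dataclass(frozen=True)
class ErpResult:
    """One component measurement for one subject."""

    component: str              # "N100" | "FRN"
    amplitude: float            # µV
    latency: float | None       # s, N100 only
    channel_or_roi: tuple[str, ...]
    n_trials: int
    degenerate: bool = False    # flat input; amplitude/latency are fallbacks


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    kind: str                   # "one-sample" | "paired"


def n100_measure(epochs: EpochSet, channel: str = "Cz",
                 search_window: tuple[float, float] = (0.10, 0.25),
                 ) -> ErpResult:
    """N100 peak amplitude and latency from sound-onset epochs.

    The trials are averaged; the N100 is the most negative sample of the
    average at *channel* within ``search_window`` (relative to sound
    onset).  No trough fitting — the single-sample peak is the simplest
    defensible estimate and is exact on noise-free input.  A flat-zero
    average is flagged degenerate and reported as amplitude 0 at the
    window start.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    ci = epochs.channel_index(channel)
    times = epochs.times
    # 1 ns guard keeps grid-aligned window edges robust to float summation
    mask = ((times >= search_window[0] - 1e-9)
            & (times <= search_window[1] + 1e-9))
    if not mask.any():
        raise ValueError(
            f"search window {search_window} contains no samples for "
            f"epoch window {epochs.window} at fs={epochs.fs}"
        )
    avg = epochs.trials[:, ci, :].mean(axis=0)
    seg = avg[mask]
    seg_times = times[mask]
    if np.all(seg == 0):
        return ErpResult("N100", 0.0, float(seg_times[0]), (channel,),
                         epochs.n_trials, degenerate=True)
    k = int(np.argmin(seg))
    return ErpResult("N100", float(seg[k]), float(seg_times[k]), (channel,),
                     epochs.n_trials)


def frn_measure(correct: EpochSet, incorrect: EpochSet,
                roi: tuple[str, ...] = DEFAULT_FRN_ROI,
                window: tuple[float, float] = (0.25, 0.30),
                ) -> tuple[ErpResult, ErpResult, np.ndarray]:
    """FRN ROI amplitudes per feedback condition and the difference wave.

    Per condition, the ROI waveform is the mean over the ROI channels of
    the trial average; the FRN amplitude is the mean of that waveform
    inside ``window``.  Returns ``(correct_result, incorrect_result,
    difference_wave)`` where the difference wave is the full-epoch ROI
    waveform of incorrect minus correct (µV).
    """
    if correct.n_trials < 1 or incorrect.n_trials < 1:
        raise ValueError("need at least one trial per condition")
    if correct.window != incorrect.window or correct.fs != incorrect.fs:
        raise ValueError("conditions must share epoch window and sampling rate")

    def roi_wave(ep: EpochSet) -> np.ndarray:
        idx = [ep.channel_index(ch) for ch in roi]
        return ep.trials[:, idx, :].mean(axis=0).mean(axis=0)

    times = correct.times
    # half-open window; 1 ns guards keep grid-aligned edges unambiguous
    mask = (times >= window[0] - 1e-9) & (times < window[1] - 1e-9)
    if not mask.any():
        raise ValueError(f"FRN window {window} contains no samples")

    wave_c, wave_i = roi_wave(correct), roi_wave(incorrect)
    res_c = ErpResult("FRN", float(wave_c[mask].mean()), None, tuple(roi),
                      correct.n_trials)
    res_i = ErpResult("FRN", float(wave_i[mask].mean()), None, tuple(roi),
                      incorrect.n_trials)
    return res_c, res_i, wave_i - wave_c


def ttest(values, kind: str = "one-sample", paired_with=None) -> TTestResult:
    """One-sample (against zero) or paired t-test on per-subject measures.

    ``t = mean / (sd / sqrt(n))`` with the n-1 standard deviation; for the
    paired test the same statistic is computed on the within-subject
    differences ``values - paired_with``.  Two-sided p from the t
    distribution with n-1 degrees of freedom.  A zero-variance sample is
    degenerate and refused.
    """
    x = np.asarray(values, dtype=np.float64)
    if kind == "paired":
        y = np.asarray(paired_with, dtype=np.float64)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
    elif kind != "one-sample":
        raise ValueError("kind must be 'one-sample' or 'paired'")
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    t = float(x.mean() / (sd / np.sqrt(n)))
    p = float(2 * scipy.stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, df=n - 1, p=p, kind=kind)
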