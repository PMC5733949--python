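import numpy as np
import pytest

import attnbci as ab
from attnbci.synthgen import default_class_templates


@pytest.fixture(scope="session")
def bandpass_spec():
    return ab.design_bandpass((1.0, 11.0), fs=250.0)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free two-class session: 2 trials per class, fully separable."""
    cfg = ab.SynthConfig(n_trials_per_class=2, noise_sd=0.0, seed=101)
    rec, markers, truth = ab.gen_recording(cfg)
    return cfg, rec, markers, truth


@pytest.fixture(scope="session")
def noisy_session():
    """Moderate-noise session used by buffering/replay equivalence tests."""
    cfg = ab.SynthConfig(n_trials_per_class=3, noise_sd=8.0, seed=202)
    rec, markers, truth = ab.gen_recording(cfg)
    return cfg, rec, markers, truth


@pytest.fixture(scope="session")
def null_session():
    """Signal-free session: class labels carry no information."""
    base = ab.SynthConfig(n_trials_per_class=1)
    zero = {lb: np.zeros_like(t)
            for lb, t in default_class_templates(base).items()}
    cfg = ab.SynthConfig(n_trials_per_class=60, noise_sd=10.0, seed=303,
                         class_templates=zero)
    rec, markers, truth = ab.gen_recording(cfg)
    return cfg, rec, markers, truth
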