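import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture(scope="session")
def pipeline_config():
    return tk.PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tone_window(freq_hz, amp, fs=100, axis=0, duration_s=4.0, phase=0.0):
    """Pure sinusoid on one gyroscope axis."""
    t = np.arange(int(duration_s * fs)) / fs
    w = np.zeros((t.size, 3))
    w[:, axis] = amp * np.sin(2 * np.pi * freq_hz * t + phase)
    return w


def noise_window(rng, sd=1.0, fs=100, duration_s=4.0):
    return rng.normal(0.0, sd, size=(int(duration_s * fs), 3))


@pytest.fixture(scope="session")
def small_cohort_features():
    """Featurized 6-subject, 2-hour cohort shared across detector tests."""
    cfg = tk.SimulationConfig(n_subjects=6, fraction_tremor_subjects=0.5,
                              days_per_subject=1, day_hours=2.0, seed=7)
    return cfg, tk.simulate_and_featurize(cfg)
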