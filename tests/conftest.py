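import numpy as np
import pytest

from navload import EEGRecording, PipelineConfig, TrialConfig, generate_trial


def tone(freq, amp=1.0, duration=10.0, rate=512.0, labels=("O1",)):
    """A pure-sinusoid EEG recording, identical on every channel."""
    t = np.arange(int(round(duration * rate))) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    return EEGRecording(np.tile(x, (len(labels), 1)), rate, list(labels))


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def db(out, ref):
    """Attenuation in dB of `out` relative to `ref` (positive = attenuated)."""
    return 20 * np.log10(rms(ref) / rms(out))


def steady(values, rate=512.0, margin=2.0):
    """Interior of a filtered signal, clear of start-up/edge transients."""
    m = int(margin * rate)
    return values[..., m:-m]


@pytest.fixture(scope="session")
def trial_dir(tmp_path_factory):
    """One synthetic trial with injected effects, shared across tests."""
    d = tmp_path_factory.mktemp("trial")
    config = TrialConfig(
        duration=60.0,
        seed=11,
        asym_ratios={"alpha": 2.0},
        scr_times=(8.0, 25.0, 45.0),
        scr_amplitudes=(0.2, 0.3, 0.25),
        spontaneous_scr_rate=0.0,
        event_schedule=[("Start", 0.0), ("Collision", 20.0), ("Find", 30.0),
                        ("Collision", 42.0), ("Stop", 60.0)],
    )
    truth = generate_trial(config, d)
    return d, config, truth


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(seed=11)
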