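import numpy as np
import pytest

from wavebeat.records import RhythmLabel
from wavebeat.synth import NoiseConfig, SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_sinus():
    """Noise-free 10 s sinus record at 60 bpm with ground truth."""
    return generate_record(
        SynthConfig(duration_s=10.0, rhythm=RhythmLabel.NORMAL,
                    mean_hr_bpm=60.0, noise=NoiseConfig.none(), seed=11)
    )


@pytest.fixture(scope="session")
def af_record():
    """Noise-free AF record long enough for >= 100 beats."""
    return generate_record(
        SynthConfig(duration_s=60.0, rhythm=RhythmLabel.AF,
                    noise=NoiseConfig.none(), seed=21)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
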