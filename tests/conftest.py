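import numpy as np
import pytest

import cardioqt as cq
from cardioqt.lead_derivation import CHANNELS_8


@pytest.fixture(scope="session")
def clean_session():
    """Default 60 s synthetic session plus its full-pipeline analysis.

    Session-scoped: the generator and pipeline are deterministic under the
    fixed seed, so tests may share one run.
    """
    beat = cq.SynthBeatParams()
    sess = cq.SynthSessionParams(seed=11)
    rec, truth = cq.generate_recording(beat, sess)
    record = cq.run_analysis(rec, cq.AnalysisConfig(posture_label="sitting"))
    return rec, truth, record


@pytest.fixture(scope="session")
def noiseless_recording():
    """Disturbance-free recording with exact, jitter-free beat placement."""
    beat = cq.SynthBeatParams()
    sess = cq.SynthSessionParams(
        noise_rms_uv=0.0, baseline_wander_uv=0.0, mains_uv=0.0, hr_jitter_sd_ms=0.0, seed=0
    )
    return cq.generate_recording(beat, sess)


def per_lead(value):
    return {ch: value for ch in CHANNELS_8}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
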