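import numpy as np
import pytest

from medstate import spectral, synthetic

# Monte-Carlo preset used across the suite: shorter recordings and a fixed
# box constraint keep repeated end-to-end runs inside the time budget while
# preserving the statistical structure the assertions probe.
MC_DURATION_S = 60.0
MC_FS = 1000.0
MC_FIXED_C = 1.0


def make_subject_table(effect=(0.0, 0.0, 0.0, 0.0), seed=0,
                       duration_s=MC_DURATION_S, fs=MC_FS,
                       subject_id="S01", **spec_kwargs):
    """Generate one subject's recordings and run feature extraction."""
    spec = synthetic.SubjectSpec(subject_id,
                                 effect_log_power_shift=tuple(effect),
                                 **spec_kwargs)
    recs = {
        (c, h): synthetic.generate_source_signal(spec, c, h, duration_s, fs, seed)
        for c in synthetic.CONDITIONS for h in synthetic.HEMISPHERES
    }
    return spectral.build_feature_table(recs)


@pytest.fixture(scope="session")
def null_table():
    """Feature table of a subject with zero medication effect."""
    return make_subject_table(seed=0)


@pytest.fixture(scope="session")
def effect_table():
    """Feature table of a subject with a +1.0 log-power ON shift at 20-30 Hz."""
    return make_subject_table(effect=(0.0, 0.0, 1.0, 0.0), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
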