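import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nsr_record():
    """Clean synthetic NSR record, 30 s at 72 BPM."""
    from cardioedge.synthetic_ecg import RhythmSpec, generate_rhythm

    return generate_rhythm(RhythmSpec(rhythm="NSR", mean_hr=72), duration_s=30, seed=11)


@pytest.fixture(scope="session")
def nsr_sample(nsr_record):
    from cardioedge.preprocessing import preprocess_record

    return preprocess_record(nsr_record)[0]


@pytest.fixture(scope="session")
def afib_record():
    from cardioedge.synthetic_ecg import RhythmSpec, generate_rhythm

    return generate_rhythm(
        RhythmSpec(rhythm="AFIB", mean_hr=110, rr_cv=0.25), duration_s=30, seed=11
    )


@pytest.fixture(scope="session")
def small_feature_table():
    """Fast noiseless feature table for training-level tests (no denoising)."""
    from cardioedge.pipeline import build_feature_table, preprocess_records
    from cardioedge.synthetic_ecg import generate_labeled_dataset

    records = generate_labeled_dataset(
        n_per_class=50, patients_per_class=5, seed=42, noisy=False
    )
    samples = preprocess_records(records)
    return build_feature_table(samples, denoise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
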