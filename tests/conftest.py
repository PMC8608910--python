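import pytest

from iohexolpk import CohortSpec, EstimationSettings, load_bundled_model, simulate_subjects


@pytest.fixture(scope="session")
def cmt3_limited():
    return load_bundled_model("cmt3_limited")


@pytest.fixture(scope="session")
def cmt3_full():
    return load_bundled_model("cmt3_full")


@pytest.fixture(scope="session")
def cmt2_limited():
    return load_bundled_model("cmt2_limited")


@pytest.fixture(scope="session")
def cmt3_cov():
    return load_bundled_model("cmt3_limited_cov")


@pytest.fixture(scope="session")
def fast_settings():
    """Deterministic settings with a small multistart budget for test speed."""
    return EstimationSettings(seed=11, multistart=2)


@pytest.fixture(scope="session")
def noiseless_cohort(cmt3_limited):
    """12 noiseless subjects on the protocol grid incl. the 24 h sample."""
    spec = CohortSpec(n_subjects=12, residual_noise=False, seed=42)
    return simulate_subjects(cmt3_limited, spec)


@pytest.fixture(scope="session")
def noisy_cohort(cmt3_limited):
    spec = CohortSpec(n_subjects=12, seed=7)
    return simulate_subjects(cmt3_limited, spec)
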