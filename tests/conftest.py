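import numpy as np
import pytest

from ecglevel.cohort_gen import SubjectProfile, generate_cohort


@pytest.fixture(scope="session")
def noise_free_profile():
    return SubjectProfile(subject_id="SX", noise_uv=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """4-subject protocol-A cohort shared by I/O and evaluation tests."""
    return generate_cohort(4, protocol="A", master_seed=42)


@pytest.fixture(scope="session")
def tiny_cohort_b():
    """2-subject protocol-B cohort (multi-dose PK)."""
    return generate_cohort(2, protocol="B", master_seed=7)
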