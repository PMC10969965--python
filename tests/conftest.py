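import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sexlink import GenotypeMatrix, PAMatrix, Sex


def build_snp(calls, sexes, locus_ids=None, tags=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    locus_ids = locus_ids or [f"L{i + 1}" for i in range(calls.shape[0])]
    return GenotypeMatrix(
        locus_ids=locus_ids,
        individual_ids=[f"i{j + 1}" for j in range(calls.shape[1])],
        sexes=[Sex(s) for s in sexes],
        calls=calls,
        tags=tags,
    )


def build_pa(calls, sexes, locus_ids=None, tags=None) -> PAMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    locus_ids = locus_ids or [f"P{i + 1}" for i in range(calls.shape[0])]
    return PAMatrix(
        locus_ids=locus_ids,
        individual_ids=[f"i{j + 1}" for j in range(calls.shape[1])],
        sexes=[Sex(s) for s in sexes],
        calls=calls,
        tags=tags,
    )


@pytest.fixture
def snp_factory():
    return build_snp


@pytest.fixture
def pa_factory():
    return build_pa
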