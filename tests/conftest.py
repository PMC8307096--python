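import numpy as np
import pytest

from gshcohort import CohortTable, ParticipantRecord, default_config, generate_cohort


@pytest.fixture()
def tiny_cohort():
    """Two hand-written records, one per group."""
    return CohortTable(
        [
            ParticipantRecord(id="p1", group="CHR", gsh=1.8, gsh_crlb=9.0, sofas=65,
                              sops_total=10, cast=12, audit_c=5, age=22.0, gender="male"),
            ParticipantRecord(id="p2", group="HC", gsh=1.5, gsh_crlb=12.0, sofas=85,
                              cast=6, audit_c=6, age=21.0, gender="female"),
        ],
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the study's published group sizes and marginals."""
    return generate_cohort(default_config(seed=20240101 % 2**31))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
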