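import pytest

from trialemu.config import paper_like_config
from trialemu.instrument import attach_instrument
from trialemu.phenotyping import build_cohort
from trialemu.synthetic import generate_hes_like


@pytest.fixture(scope="session")
def paper_ds():
    """Small full-path dataset under the study-condition preset."""
    return generate_hes_like(paper_like_config(n_patients=1000, seed=202))


@pytest.fixture(scope="session")
def paper_cohort(paper_ds):
    cohort, attrition = build_cohort(paper_ds)
    return attach_instrument(cohort), attrition
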