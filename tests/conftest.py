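import numpy as np
import pytest

from oceanhealth.synthetic import GeneratorConfig, gen_survey
from oceanhealth.weighting import fit_maxdiff_logit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_survey():
    """Large synthetic maxdiff survey with known sum-zero utilities."""
    config = GeneratorConfig(seed=42, n_respondents=1000, tasks_per_respondent=6)
    return config, gen_survey(config)


@pytest.fixture(scope="session")
def recovery_fit(recovery_survey):
    config, responses = recovery_survey
    return config, fit_maxdiff_logit(responses)
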