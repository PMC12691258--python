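import pytest

from bayestriage import CohortState, derive_rates

# Asymptomatic metropolitan screening scenario: 19.6/100k prevalence,
# 73% sensitivity, 94% specificity.
METRO_PREVALENCE = 0.000196
METRO_SIZE = 100_000.0

# Symptomatic low/moderate-risk cohort calibrated from a 808-patient
# confusion table (TP 26, FP 256, TN 525, FN 1).
LMR_SIZE = 808.0
LMR_PREVALENCE = 27 / 808
SYMPTOMATIC_SENSITIVITY = 26 / 27
SYMPTOMATIC_SPECIFICITY = 525 / 781

# High-risk cohort from the same study: 345 patients, 16 confirmed cases,
# assumed tested with the same assay.
HR_SIZE = 345.0
HR_PREVALENCE = 16 / 345


@pytest.fixture(scope="session")
def metro_test():
    return derive_rates(0.73, 0.94)


@pytest.fixture(scope="session")
def metro_cohort():
    return CohortState(METRO_SIZE, METRO_PREVALENCE)


@pytest.fixture(scope="session")
def symptomatic_test():
    return derive_rates(SYMPTOMATIC_SENSITIVITY, SYMPTOMATIC_SPECIFICITY)


@pytest.fixture(scope="session")
def lmr_cohort():
    return CohortState(LMR_SIZE, LMR_PREVALENCE)


@pytest.fixture(scope="session")
def hr_cohort():
    return CohortState(HR_SIZE, HR_PREVALENCE)
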