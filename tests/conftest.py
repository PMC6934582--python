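import dataclasses

import pytest

import antiseq as aq


def make_config(seed=0, sizes=(10, 8, 7), n_trials=24, p_full=0.792, **kw):
    """A scaled-down cohort config keeping the default model parameters."""
    groups = dict(zip(("control", "MCI", "AD"), sizes))
    return dataclasses.replace(
        aq.SimConfig(seed=seed), group_sizes=groups, n_trials_full=n_trials,
        p_full_sequence=p_full, **kw
    )


@pytest.fixture(scope="session")
def tiny_frame():
    """Small mixed cohort (25 participants) for table-level tests."""
    return aq.cohort_to_frame(aq.simulate_cohort(make_config(seed=11)))


@pytest.fixture(scope="session")
def medium_cov():
    """Medium cohort (90 participants) with history covariates attached."""
    cfg = make_config(seed=5, sizes=(40, 30, 20))
    return aq.add_history_covariates(aq.cohort_to_frame(aq.simulate_cohort(cfg)))


@pytest.fixture(scope="session")
def medium_fit(medium_cov):
    fit = aq.fit_glmm(medium_cov)
    assert fit.converged
    return fit
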