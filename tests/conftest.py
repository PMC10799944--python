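import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas68():
    from covnet import desikan_atlas

    return desikan_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort at the default study conditions."""
    from covnet import SyntheticSpec, generate_cohort

    return generate_cohort(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def residualized_pair(small_cohort):
    """Baseline group tables residualized on the pooled covariate model."""
    import warnings

    from covnet import residualize_pair
    from covnet.simulate import GROUP_A, GROUP_B

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # onset_age is NaN for controls
        return residualize_pair(
            small_cohort.table(GROUP_A, "BL"),
            small_cohort.table(GROUP_B, "BL"),
            small_cohort.covariates["BL"],
        )


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down pipeline settings used by the simulation studies."""
    from covnet import PipelineConfig

    return PipelineConfig(n_null=1, swaps_per_edge=3, include_nodal=False)
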