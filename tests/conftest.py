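import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_bundle():
    """Synthetic reference dataset, coded and with covariates attached."""
    from ethnophylo import coding, pipeline
    from ethnophylo.reference import synthetic_reference_dataset

    data, tree, truth = synthetic_reference_dataset()
    coded = coding.code_table(data)
    table, pca_report = pipeline.attach_covariates(data, coded, seed=7)
    return {
        "raw": data,
        "tree": tree,
        "truth": truth,
        "coded": coded,
        "table": table,
        "pca_report": pca_report,
    }


@pytest.fixture(scope="session")
def ref_fits(ref_bundle):
    """The six response models fitted on the reference stand-in.

    Shared across acceptance and model-behaviour tests so the MCMC cost is
    paid once.
    """
    from ethnophylo import coding, pipeline
    from ethnophylo.dependence import MaternParams
    from ethnophylo.model import McmcConfig

    fits = {}
    mcmc = McmcConfig(chains=4, iterations=2000, seed=11)
    matern = MaternParams(range_=20.0)
    for label, preds in [
        ("n_functions", ["n_functions"]),
        ("functions", list(coding.MAIN_FUNCTIONS)),
    ]:
        for resp in pipeline.RESPONSES:
            fits[(label, resp)] = pipeline.fit_response(
                ref_bundle["table"], ref_bundle["tree"], resp,
                preds + list(pipeline.COVARIATE_NAMES),
                matern=matern, mcmc=mcmc,
            )
    return fits
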