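import pytest

from glutenquant import pipeline, simulate

SCENARIO_SEED = 2021


@pytest.fixture(scope="session")
def paper_run():
    """One paper-scenario simulation shared across tests."""
    return simulate.generate_scenario(simulate.paper_scenario(SCENARIO_SEED))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full file-based pipeline executed once over the paper scenario."""
    out = tmp_path_factory.mktemp("pipeline")
    run, report = pipeline.run_scenario("paper", seed=SCENARIO_SEED, outdir=out)
    return run, report, out
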