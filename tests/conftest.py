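import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case2_run(tmp_path_factory):
    """One case2_like simulation plus a full pipeline run, shared by tests."""
    from clonevo import RunConfig, run_all, synthetic

    root = tmp_path_factory.mktemp("case2")
    cfg = synthetic.preset("case2_like", seed=11)
    paths, truth = synthetic.simulate_case(cfg, root / "sim")
    bundle = run_all(
        paths["vcf"], paths["segments"], paths["panel"], root / "out",
        RunConfig(seed=11),
    )
    return {"config": cfg, "paths": paths, "truth": truth, "bundle": bundle}


@pytest.fixture(scope="session")
def case1_run(tmp_path_factory):
    """One case1_like simulation plus a full pipeline run, shared by tests."""
    from clonevo import RunConfig, run_all, synthetic

    root = tmp_path_factory.mktemp("case1")
    cfg = synthetic.preset("case1_like", seed=5)
    paths, truth = synthetic.simulate_case(cfg, root / "sim")
    bundle = run_all(
        paths["vcf"], paths["segments"], paths["panel"], root / "out",
        RunConfig(seed=5),
    )
    return {"config": cfg, "paths": paths, "truth": truth, "bundle": bundle}
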