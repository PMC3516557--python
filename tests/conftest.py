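import pytest

from painmap.pipeline import RunConfig, SimulateParams, run_all
from painmap.synthetic import UniverseSpec, generate_universe


@pytest.fixture(scope="session")
def small_universe():
    """A 300-gene fly universe with mixed orthology topology."""
    return generate_universe(UniverseSpec(n_fly=300, n_mouse=420, n_human=420, seed=11))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One reduced-scale end-to-end pipeline run shared across tests.

    Sizes are scaled down from the study conditions purely to keep the suite
    quick; the statistical acceptance checks run at full scale separately.
    """
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = RunConfig(
        outdir=str(outdir),
        seed=7,
        simulate=SimulateParams(
            n_fly=2000, n_mouse=2300, n_human=2300,
            n_hits=150, n_lethal=60, mean_degree=0.4,
            n_sets=60, n_planted=5, set_size_min=15, set_size_max=40,
            n_classes=8,
        ),
        r_lists=25,
    )
    manifest = run_all(config)
    return config, manifest
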