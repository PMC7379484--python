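import pytest

from chromtrans import PipelineConfig, SimConfig, run_pipeline, simulate


@pytest.fixture(scope="session")
def sim_noiseless(tmp_path_factory):
    """Default synthetic study (500 genes, seed 42), zero noise."""
    outdir = tmp_path_factory.mktemp("sim_noiseless")
    truth = simulate(SimConfig(seed=42), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def sim_noisy(tmp_path_factory):
    """Default synthetic study with moderate noise (20% amplitude sd)."""
    outdir = tmp_path_factory.mktemp("sim_noisy")
    truth = simulate(SimConfig(seed=42, noise_level=0.2), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def pipeline_noiseless(sim_noiseless, tmp_path_factory):
    simdir, truth = sim_noiseless
    outdir = tmp_path_factory.mktemp("pipe_noiseless")
    results = run_pipeline(PipelineConfig(), simdir / "manifest.yaml", outdir)
    return simdir, truth, outdir, results


@pytest.fixture(scope="session")
def pipeline_noisy(sim_noisy, tmp_path_factory):
    simdir, truth = sim_noisy
    outdir = tmp_path_factory.mktemp("pipe_noisy")
    results = run_pipeline(PipelineConfig(), simdir / "manifest.yaml", outdir)
    return simdir, truth, outdir, results
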