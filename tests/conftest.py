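from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import regulonkit as rk

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset() -> rk.SyntheticDataset:
    """One default-parameter simulated study, shared across tests."""
    return rk.simulate_dataset(rk.SimulationParams(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory) -> rk.PipelineResult:
    """A full default pipeline run (seed 1), shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    config = rk.PipelineConfig(
        outdir=outdir, seed=1, simulation=rk.SimulationParams()
    )
    return rk.run_pipeline(config)


@pytest.fixture()
def toy_annotation() -> rk.GenomeAnnotation:
    """Two genes on one contig, used by classification/assignment examples."""
    return rk.GenomeAnnotation(
        [
            rk.Gene("geneA", "chr1", 1000, 2000, "+"),
            rk.Gene("geneB", "chr1", 3000, 4000, "-"),
        ],
        contig_lengths={"chr1": 10_000},
    )
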