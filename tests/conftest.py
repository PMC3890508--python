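from __future__ import annotations

import pytest

from orthoscreen.pipeline import PipelineConfig, run_pipeline
from orthoscreen.simulate import SimulationParams


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default simulated study (seed 42).

    Shared by the acceptance-level tests; outputs are written so the
    determinism check can compare bytes against a second run.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(output_dir=str(outdir))
    report, artifacts = run_pipeline(config, write_outputs=True)
    return {"config": config, "report": report, "artifacts": artifacts,
            "outdir": outdir}


@pytest.fixture()
def tiny_params():
    """A small, fast study: a handful of families, no stress classes."""
    return SimulationParams(
        n_families=4, loss_prob=0.0, dup_rate=0.0,
        n_novel_per_species=1, n_divergent_families=0,
        forced_loss_families={}, n_phylotypic_families=2,
        conserved_elevated_per_stage=1, novel_elevated_per_stage=1,
        rng_seed=7,
    )
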