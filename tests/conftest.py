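from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirhunt import pipeline, synthetic

SCENARIO_SEED = 101


def build_config(scenario, paths, out_dir) -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        mature_catalog=paths["catalog_matures"],
        hairpin_catalog=paths["catalog_hairpins"],
        genomes=[(gid, paths[gid]) for gid, _ in scenario.genomes],
        count_tables=[(t.experiment_id, paths[t.experiment_id]) for t in scenario.tables],
        known_mature_fasta=paths["known_matures"],
        known_precursor_gff=paths["known_gff"],
        out_dir=out_dir,
        cutoff=scenario.cutoff,
        target_prefix=scenario.target_prefix,
    )


@pytest.fixture(scope="session")
def scenario():
    return synthetic.make_scenario(SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario_run(scenario, tmp_path_factory):
    """One full pipeline run on the reference synthetic study."""
    base = tmp_path_factory.mktemp("scenario")
    paths = synthetic.write_scenario(scenario, base / "in")
    cfg = build_config(scenario, paths, base / "out")
    result = pipeline.run_pipeline(cfg)
    return scenario, paths, result
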