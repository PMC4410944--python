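import pytest

from imprintscan.config import PipelineConfig, SimulationConfig, demo_config
from imprintscan.pipeline import run_pipeline
from imprintscan.synthetic_data import build_genome


def tiny_config(seed: int = 3, **overrides) -> SimulationConfig:
    """A 60 kb single-chromosome genome that builds in ~0.1 s."""
    cfg = demo_config(seed=seed)
    cfg.chrom_lengths = {"chr1": 60_000}
    cfg.genes_per_chrom = 6
    cfg.n_imprinted = 3
    cfg.n_ko_disrupted = 1
    cfg.chip_depth = 5_000
    cfg.rna_depth = 20_000
    cfg.intergenic_cgis_per_chrom = 1
    cfg.ervk_per_chrom = 1
    cfg.line_per_chrom = 1
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture
def tiny_genome():
    return build_genome(tiny_config())


@pytest.fixture(scope="session")
def demo_pipeline(tmp_path_factory):
    """One full default pipeline run shared by integration-level tests."""
    out = tmp_path_factory.mktemp("demo_pipeline")
    return run_pipeline(PipelineConfig(seed=0, out_dir=str(out)))
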