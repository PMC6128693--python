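import numpy as np
import pandas as pd
import pytest

from chiprx.model import AlignedReadSet, GenomeTag
from chiprx.pipeline import analyze_chiprx
from chiprx.simulate import SimulationConfig, simulate_chiprx_experiment


def make_readset(rows, sample_id="s", condition="ctrl", replicate=1, role="IP",
                 prefix="dmel_"):
    """AlignedReadSet from (chrom, start, end, strand) tuples."""
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return AlignedReadSet(
        sample_id=sample_id, condition=condition, replicate=replicate, role=role,
        reads=reads, genome_tag=GenomeTag(prefix),
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A compact simulated experiment reused by pipeline-level tests."""
    cfg = SimulationConfig(
        seed=42, n_genes=80, genome_length_target=500_000,
        genome_length_spikein=60_000, reads_per_library=40_000,
    )
    return cfg, simulate_chiprx_experiment(cfg)


@pytest.fixture(scope="session")
def default_analysis():
    """Full-size default simulation (no global shift) plus its analysis."""
    cfg = SimulationConfig(seed=1)
    exp = simulate_chiprx_experiment(cfg)
    result = analyze_chiprx(
        exp.libraries, exp.genes, contrast=("treat", "ctrl"),
        chrom_lengths={cfg.target_chrom: cfg.genome_length_target},
    )
    return cfg, exp, result


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
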