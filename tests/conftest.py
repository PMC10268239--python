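"""Shared fixtures: a small simulated experiment reused across test modules."""

import numpy as np
import pytest

from rnetseq.pause_calling import pileup_3prime_ends
from rnetseq.synthetic import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, genome_length=100_000, n_genes=50, n_pauses=100,
                     depth_per_condition=200_000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Genome + annotation + truth + reads for both conditions."""
    genome, features, truth = simulate_genome(small_config)
    reads = {
        "WT": simulate_reads(truth, "WT", small_config, 101),
        "depleted": simulate_reads(truth, "depleted", small_config, 102),
    }
    return {"config": small_config, "genome": genome, "features": features,
            "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def small_coverage(small_sim):
    g = small_sim["genome"]
    return {cond: pileup_3prime_ends(rs, len(g), g.id)
            for cond, rs in small_sim["reads"].items()}
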