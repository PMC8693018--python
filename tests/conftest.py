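import numpy as np
import pytest

from sexlinkscan import mapper, simgen


@pytest.fixture(scope="session")
def small_cfg():
    """Small read-mapping panel: full 15M + 16F design, genome scaled to
    11 kb so mapping-based tests run in seconds."""
    return simgen.SimConfig(
        seed=3,
        scaffold_lengths=(6_000, 5_000),
        msr_scaffold="scaffold_1", msr_start=1_500, msr_length=2_500,
        paralog_scaffold="scaffold_2", paralog_length=2_000,
        paralog_identity=0.92, cassette_deletion=7,
        coverage=30.0, read_length=100, error_rate=0.001)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    female, male, truth = simgen.make_genomes(small_cfg)
    return small_cfg, female, male, truth


@pytest.fixture(scope="session")
def small_reads(small_sim):
    cfg, female, male, truth = small_sim
    return {s: list(simgen.sample_reads(cfg, truth, female, male, s))
            for s in truth.sample_sheet}


@pytest.fixture(scope="session")
def unmasked_alignments(small_sim, small_reads):
    """Panel mapped to the female (paralog-containing, unmasked) reference."""
    cfg, female, male, truth = small_sim
    idx = mapper.ReferenceIndex(female, k=15)
    return {s: mapper.map_reads(reads, idx, max_mismatch=12)
            for s, reads in small_reads.items()}


@pytest.fixture(scope="session")
def desk_panel():
    """Desk-scale depth-only panel: 2 scaffolds totalling 1 Mb, male-specific
    region of 60,750 bp, 15 males + 16 females at coverage 30."""
    cfg = simgen.SimConfig(seed=11)
    female, male, truth = simgen.make_genomes(cfg)
    depths = simgen.simulate_depth(cfg, truth)
    return cfg, truth, depths
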