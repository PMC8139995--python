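import pytest

from tgintegrity import io_utils
from tgintegrity.synthgenome import (
    GeneratorConfig,
    build_reference,
    build_transgenic_genome,
    default_construct,
    simulate_reads,
    table_line_specs,
)


@pytest.fixture(scope="session")
def genome():
    """Default annotated two-contig toy reference."""
    return build_reference(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def refs(genome):
    return genome.seqs


@pytest.fixture(scope="session")
def construct():
    return default_construct()


@pytest.fixture(scope="session")
def line_specs(genome):
    return table_line_specs(genome)


@pytest.fixture(scope="session")
def flat_genome():
    """Single gene-free 20-kb contig for junction-recovery sweeps."""
    cfg = GeneratorConfig(
        n_contigs=1, contig_len=20_000, gene_density=0.0, antisense_pair=False
    )
    return build_reference(cfg, seed=5)


@pytest.fixture(scope="session")
def line_sams(tmp_path_factory, genome, construct, line_specs):
    """Truth SAMs at 35x for the three study-line-like fixtures."""
    root = tmp_path_factory.mktemp("line_sams")
    out = {}
    for name, spec in line_specs.items():
        tg, _ = build_transgenic_genome(genome, construct, spec)
        sim = simulate_reads(tg, coverage=35, read_len=100, seed=11)
        path = str(root / f"{name}.sam")
        io_utils.write_truth_sam(sim, path)
        out[name] = {"sam": path, "tg": tg, "sim": sim, "spec": spec}
    return out
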