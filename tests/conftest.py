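import numpy as np
import pytest

from dgetp.mapping import MappedTag
from dgetp.simulate import (SimulationConfig, generate_genome_and_annotation,
                            generate_tag_libraries)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down seven-library experiment used across stage tests."""
    return SimulationConfig(
        random_seed=7,
        n_supercontigs=2,
        supercontig_length=60_000,
        n_genes=40,
        reads_per_library=20_000,
    )


@pytest.fixture(scope="session")
def small_simulation(small_config):
    genome, genes, truth = generate_genome_and_annotation(small_config)
    reads, manifest = generate_tag_libraries(genome, genes, truth, small_config)
    return {
        "config": small_config, "genome": genome, "genes": genes,
        "truth": truth, "reads": reads, "manifest": manifest,
    }


@pytest.fixture(scope="session")
def clean_simulation():
    """Error-free variant: every read is an exact tag of the manifest."""
    cfg = SimulationConfig(
        random_seed=11,
        n_supercontigs=2,
        supercontig_length=60_000,
        n_genes=40,
        reads_per_library=20_000,
        sequencing_error_rate=0.0,
    )
    genome, genes, truth = generate_genome_and_annotation(cfg)
    reads, manifest = generate_tag_libraries(genome, genes, truth, cfg)
    return {
        "config": cfg, "genome": genome, "genes": genes,
        "truth": truth, "reads": reads, "manifest": manifest,
    }


def make_tag(tag="GATC" + "A" * 16, supercontig="sc1", start=0, strand="+",
             counts=None) -> MappedTag:
    return MappedTag(
        tag=tag, status="unique", supercontig=supercontig, start=start,
        strand=strand, counts=counts or {"Ctrl": 1},
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
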