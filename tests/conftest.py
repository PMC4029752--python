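import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from natsirna.annotation import AnnotationSet, GenomicInterval, TranscriptModel
from natsirna.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_srna_libraries,
)


def make_model(gene_id, chrom, start, end, strand, exons=None, biotype="coding"):
    span = GenomicInterval(chrom, start, end, strand)
    exon_ivs = (
        [GenomicInterval(chrom, s, e, strand) for s, e in exons] if exons else None
    )
    return TranscriptModel(gene_id + ".1", gene_id, span, exon_ivs or [], biotype=biotype)


def make_set(*models):
    return AnnotationSet(models)


@pytest.fixture(scope="session")
def sim_world():
    """One deterministic synthetic world shared across tests."""
    config = SimulationConfig(seed=7)
    genes, premirnas, manifest = simulate_annotation(config)
    tags, libraries = simulate_srna_libraries(genes, manifest, config)
    return {
        "config": config,
        "genes": genes,
        "premirnas": premirnas,
        "manifest": manifest,
        "tags": tags,
        "libraries": libraries,
    }
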