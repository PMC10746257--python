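import numpy as np
import pandas as pd
import pytest

from thermomics.io import Genome, GeneModel, EndTrack
from thermomics.simulate import SimConfig, Truth, make_genome_annotation


@pytest.fixture(scope="session")
def small_dataset():
    """A 100-gene synthetic genome with planted features (seed 11)."""
    cfg = SimConfig(seed=11, n_genes=100)
    genome, genes, truth = make_genome_annotation(cfg)
    return cfg, genome, genes, truth


@pytest.fixture()
def toy_genome():
    return Genome({"c1": "ACGTACGTACGTACGTACGT" * 5})


def mini_truth(n_genes: int) -> Truth:
    """Expression-only truth scaffold (no genome needed)."""
    ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    genes = pd.DataFrame({"gene_id": ids}).set_index("gene_id", drop=False)
    return Truth(genes=genes, ends=pd.DataFrame())


def make_track(counts, strand="+", contig="c1", total=None, normalized="raw",
               contig_length=100000):
    return EndTrack(
        contig=contig, strand=strand, counts=dict(counts),
        library_total=total if total is not None else sum(counts.values()),
        normalized=normalized, contig_length=contig_length,
    )
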