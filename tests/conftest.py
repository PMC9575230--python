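import numpy as np
import pandas as pd
import pytest

from repliscape.annotation import (
    AnnotationConfig,
    GenomeAnnotation,
    GENE_COLUMNS,
    make_genome_annotation,
)


@pytest.fixture(scope="session")
def small_ann() -> GenomeAnnotation:
    return make_genome_annotation(
        AnnotationConfig(
            chromosome_lengths=(200_000,), n_genes=50, n_origins=10, seed=1
        )
    )


def bare_annotation(
    chrom_len: int = 40_000,
    origin_positions=(500,),
    firing_irrelevant: bool = True,
    telomere_margin: int = 5_000,
) -> GenomeAnnotation:
    """Minimal single-chromosome annotation with hand-placed origins."""
    origins = pd.DataFrame(
        {
            "id": [f"ARS{i}" for i in range(len(origin_positions))],
            "chrom": "chr1",
            "pos": list(origin_positions),
            "licensed": True,
        }
    )
    return GenomeAnnotation(
        chromosomes=[("chr1", chrom_len)],
        genes=pd.DataFrame(columns=GENE_COLUMNS),
        origins=origins,
        centromeres={"chr1": chrom_len // 2},
        telomere_margin=telomere_margin,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
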