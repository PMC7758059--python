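import numpy as np
import pandas as pd
import pytest

from modscreen.containers import GeneModel, GeneModelSet, GenotypePanel
from modscreen.simulate import SimConfig, simulate_genotype_panel


@pytest.fixture
def tiny_panel() -> GenotypePanel:
    """4 strains x 5 variants with one missing call and one monomorphic site."""
    G = np.array(
        [
            [0, 1, 0, 0, 1],
            [1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1],
            [1, np.nan, 0, 1, 0],
        ],
        dtype=float,
    )
    variants = pd.DataFrame(
        {
            "chrom": "2L",
            "pos": [100, 250, 400, 900, 1500],
            "ref": "A",
            "alt": "T",
            "id": [f"v{i}" for i in range(5)],
        }
    )
    return GenotypePanel(strain_ids=["s1", "s2", "s3", "s4"], variants=variants, genotypes=G)


@pytest.fixture
def toy_genes() -> GeneModelSet:
    """Two genes on opposite strands with exon/UTR/intron substructure.

    geneA: + strand, body 1000-2000, UTRs at each end, intron 1400-1599.
    geneB: - strand, body 3000-4000.
    """
    a = GeneModel(
        gene_id="geneA",
        chrom="2L",
        start=1000,
        end=2000,
        strand="+",
        exons=[(1100, 1399), (1600, 1899)],
        utrs=[(1000, 1099), (1900, 2000)],
    )
    b = GeneModel(
        gene_id="geneB",
        chrom="2L",
        start=3000,
        end=4000,
        strand="-",
        exons=[(3100, 3899)],
        utrs=[(3000, 3099), (3900, 4000)],
    )
    return GeneModelSet(genes=[a, b])


@pytest.fixture(scope="session")
def medium_panel() -> GenotypePanel:
    """Unstructured 100-strain x 2000-variant panel reused across tests."""
    cfg = SimConfig(n_strains=100, n_variants=2000, seed=42)
    return simulate_genotype_panel(cfg)
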