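import numpy as np
import pytest

from allokit.io_formats import GenotypeMatrix, Site


def haplotypes_to_genotype_matrix(
    hap: np.ndarray, positions, chromosome: str = "chr1"
) -> GenotypeMatrix:
    """Pair haplotype columns (sites x 2k binary matrix) into k diploids."""
    dosage = (hap[:, ::2] + hap[:, 1::2]).astype(np.int8)
    sites = [Site(chromosome, int(p), "A", "T") for p in positions]
    samples = [f"s{i}" for i in range(dosage.shape[1])]
    return GenotypeMatrix(sample_ids=samples, sites=sites, genotypes=dosage)


def treeseq_to_genotype_matrix(ts, chromosome: str = "chr1") -> GenotypeMatrix:
    """Convert a tskit tree sequence (diploid individuals) for the scan code."""
    G = ts.genotype_matrix()
    keep, last = [], -1
    positions = [int(s.position) for s in ts.sites()]
    for i, p in enumerate(positions):
        if p > last:  # drop duplicate discretised positions
            keep.append(i)
            last = p
    G = np.clip(G[keep], 0, 1)
    return haplotypes_to_genotype_matrix(
        G, [positions[i] for i in keep], chromosome
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
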