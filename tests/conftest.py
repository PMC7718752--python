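import numpy as np
import pandas as pd
import pytest

from linkagekit import simulate as sim


@pytest.fixture(scope="session")
def small_genome() -> sim.GenomeModel:
    """3 chromosomes x 2 Mb, 24 contigs, 500 SNPs."""
    cfg = sim.GenomeConfig(
        n_chromosomes=3, chromosome_length=2_000_000, n_contigs=24, n_snps=500
    )
    return sim.build_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def landscape(small_genome) -> sim.RecombinationLandscape:
    """Uniform 60 cM per chromosome (30 cM/Mb on 2 Mb chromosomes)."""
    return sim.RecombinationLandscape.from_genetic_lengths(small_genome, 60.0)


def two_marker_genome(bp1: int, bp2: int, length: int = 2_000_000) -> sim.GenomeModel:
    """Single chromosome, single contig, two hk markers at fixed positions."""
    chroms = pd.DataFrame({"chrom": ["chr1"], "length": [length]})
    contigs = pd.DataFrame(
        {"contig": ["ctg0001"], "chrom": ["chr1"], "start": [1], "end": [length]}
    )
    snps = pd.DataFrame(
        {
            "snp": [f"chr1_{bp1}", f"chr1_{bp2}"],
            "contig": "ctg0001",
            "contig_pos": [bp1, bp2],
            "chrom": "chr1",
            "chrom_pos": [bp1, bp2],
            "true_chrom": "chr1",
            "true_pos": [bp1, bp2],
        }
    )
    g = sim.GenomeModel(chroms, contigs, snps)
    g.validate()
    return g


@pytest.fixture(scope="session")
def hk_designs(small_genome):
    """Three families where every SNP segregates bi-parentally (hk x hk)."""
    types = {s: "hkxhk" for s in small_genome.snps["snp"]}
    return [
        sim.FamilyDesign(
            family=f"fam{i}", sire=f"s{i}", dam=f"d{i}", n_progeny=60,
            mating_types=dict(types), sire_multiplier=1.0, dam_multiplier=1.0,
            error_rate=0.0, missing_rate=0.0, seed=100 + i,
        )
        for i in range(1, 4)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
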