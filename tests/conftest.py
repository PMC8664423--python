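import numpy as np
import pytest

from salmeth.io import GenomicInterval, MethylationMatrix, SampleMeta, SiteCounts
from salmeth.simulate import SimConfig, simulate_study


@pytest.fixture
def tiny_matrix():
    """3 sites x 2 samples with one missing cell."""
    chrom = np.array(["chr1", "chr1", "chr2"], dtype=object)
    pos = np.array([100, 150, 200])
    meth = np.array([[8.0, 5.0], [0.0, np.nan], [10.0, 2.0]])
    total = np.array([[10.0, 10.0], [5.0, np.nan], [10.0, 4.0]])
    return MethylationMatrix(chrom, pos, ["s1", "s2"], meth, total)


@pytest.fixture
def meta_two():
    return [
        SampleMeta("s1", "SAS", "liver", "F1"),
        SampleMeta("s2", "wild", "liver", "F2"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """One small full simulation used by several suites."""
    cfg = SimConfig(seed=11, n_chrom=1, chrom_len_bp=400_000,
                    n_dmrs=6, n_modules=1, module_size=12)
    backbone, genes, gene2go, counts, phenos = simulate_study(cfg)
    return dict(cfg=cfg, backbone=backbone, genes=genes, gene2go=gene2go,
                counts=counts, phenos=phenos)


def make_sites(rows):
    return [SiteCounts(*r) for r in rows]


def iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, name)
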