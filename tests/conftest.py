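import numpy as np
import pandas as pd
import pytest

from endbind.annotation import GeneModel
from endbind.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle shared by the unit tests."""
    return simulate(SimulationConfig(seed=42, n_genes=300))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, chrom, strand, start, end, biotype="protein_coding",
              tss=None, tes=None):
    if strand == "+":
        tss = tss or (start,)
        tes = tes or (end,)
    else:
        tss = tss or (end,)
        tes = tes or (start,)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                     end=end, biotype=biotype, tss_anchors=tss, tes_anchors=tes)


def make_peaks(rows):
    """rows: (peak_id, factor, chrom, summit, signal) or with start/end."""
    recs = []
    for r in rows:
        if len(r) == 5:
            pid, factor, chrom, summit, signal = r
            start, end = summit - 150, summit + 150
        else:
            pid, factor, chrom, start, end, summit, signal = r
        recs.append(dict(peak_id=pid, factor=factor, sample="", chrom=chrom,
                         start=max(1, start), end=end, summit=summit, signal=float(signal)))
    return pd.DataFrame(recs, columns=["peak_id", "factor", "sample", "chrom",
                                       "start", "end", "summit", "signal"])


def random_genes(rng, n, chrom="chrR", spacing=(2000, 30000), length=(6000, 25000)):
    genes, pos = [], 50_000
    for i in range(n):
        L = int(rng.integers(*length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene("R%04d" % i, chrom, strand, pos, pos + L - 1))
        pos += L + int(rng.integers(*spacing))
    return genes
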