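import numpy as np
import pytest

from epiblup import GenotypeData


def panel_from_x(x, chrom=None, pos=None):
    """GenotypeData from genotype codes; phase split deterministically.

    x=1 becomes hap1=0, hap2=1; x=0/2 are homozygous.
    """
    x = np.asarray(x, dtype=np.int8)
    n, m = x.shape
    hap1 = (x == 2).astype(np.int8)
    hap2 = (x >= 1).astype(np.int8)
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = []
        counters = {}
        for c in chrom:
            counters[c] = counters.get(c, 0) + 1
            pos.append(counters[c] * 1000)
    return GenotypeData(
        individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        hap1=hap1,
        hap2=hap2,
    )


def random_panel(rng, n, m, n_chrom=1):
    """Random phased panel with all SNPs polymorphic."""
    while True:
        hap1 = (rng.random((n, m)) < rng.uniform(0.2, 0.8, size=m)).astype(np.int8)
        hap2 = (rng.random((n, m)) < rng.uniform(0.2, 0.8, size=m)).astype(np.int8)
        x = hap1 + hap2
        p = x.mean(axis=0) / 2.0
        if np.all((p > 0) & (p < 1)):
            break
    per = m // n_chrom
    chrom = [f"chr{j // per + 1 if j // per < n_chrom else n_chrom}" for j in range(m)]
    pos = []
    counters = {}
    for c in chrom:
        counters[c] = counters.get(c, 0) + 1
        pos.append(counters[c] * 1000)
    return GenotypeData(
        individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        hap1=hap1,
        hap2=hap2,
    )


def with_individuals(g, idx):
    """Panel restricted to row positions ``idx`` (repeats allowed), fresh ids."""
    idx = np.asarray(idx)
    return GenotypeData(
        individual_ids=np.array([f"d{k}" for k in range(len(idx))], dtype=object),
        snp_ids=g.snp_ids.copy(),
        chrom=g.chrom.copy(),
        pos_bp=g.pos_bp.copy(),
        hap1=g.hap1[idx],
        hap2=g.hap2[idx],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
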