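"""Shared fixtures: small annotations, random-interval factories, NB draws."""

import numpy as np
import pytest

from chromadyn.annotation import GeneModel, GenomeAnnotation
from chromadyn.intervals import GenomicInterval
from chromadyn.nb import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_annotation():
    """Two chromosomes, genes on both strands, one multi-isoform gene."""
    genes = [
        GeneModel("gA", "chr1", "+", 4_000, 6_000),
        GeneModel("gB", "chr1", "-", 10_000, 14_000),
        GeneModel("gC", "chr1", "+", 20_000, 30_000, transcript_tss=(20_000, 22_000)),
        GeneModel("gD", "chr2", "-", 1_000, 3_000, biotype="non_coding"),
    ]
    return GenomeAnnotation(genes, {"chr1": 50_000, "chr2": 20_000})


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def nb_counts(rng, mean, dispersion, size):
    """Gamma-Poisson draws (the standard NB parameterization)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def two_group_matrix(counts, n_per_group=3):
    n, m = counts.shape
    assert m == 2 * n_per_group
    return CountMatrix(
        counts=counts,
        feature_ids=[f"r{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        conditions=["control"] * n_per_group + ["treated"] * n_per_group,
    )
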