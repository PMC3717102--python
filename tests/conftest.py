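import numpy as np
import pytest

from pynurd import ExonSegment, GeneModel


@pytest.fixture
def cassette_gene() -> GeneModel:
    """Two-isoform cassette-exon gene: iso1 = all three exons, iso2 skips the middle."""
    segs = [
        ExonSegment("chr1", 0, 100),
        ExonSegment("chr1", 150, 200),
        ExonSegment("chr1", 200, 300),
    ]
    incl = np.array([[1, 0, 1], [1, 1, 1]])
    return GeneModel("G", "chr1", "+", ["A", "B"], segs, incl)


@pytest.fixture
def single_isoform_gene() -> GeneModel:
    segs = [ExonSegment("chr1", 1000, 1100), ExonSegment("chr1", 1200, 1300)]
    return GeneModel("S", "chr1", "+", ["S.1"], segs, np.array([[1, 1]]))


def random_instance(rng, m_max=4, n_max=12):
    """Random feasible likelihood instance: (x, lengths, b, w, theta_true)."""
    m = rng.integers(1, m_max + 1)
    n = rng.integers(max(2, m), n_max + 1)
    # random 0/1 structure without empty rows/columns
    while True:
        a = (rng.random((m, n)) < 0.7).astype(float)
        if a.sum(axis=1).all() and a.sum(axis=0).all():
            break
    b = a * rng.uniform(0.3, 1.8, size=(m, n))
    lengths = rng.integers(50, 500, size=n).astype(float)
    w = 100_000
    theta_true = rng.uniform(0.2, 2.0, size=m) / w * 10
    lam = lengths * w * (theta_true @ b)
    x = rng.poisson(lam)
    return x, lengths, b, w, theta_true
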