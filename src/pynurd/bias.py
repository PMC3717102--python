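"""Nonparametric positional bias curves and weighted structure matrices.

Read starts in RNA-seq libraries are not uniform along transcripts; the
deviation is summarised by binned read-density curves over relative position
t in [0, 1), measured 5'->3':

* the **global bias curve (GBC)** pools all genes and captures the
  library-wide positional trend;
* the **local bias curve (LBC)** is the per-gene analogue over the gene's
  exonic union.

Each curve is mean-normalised (bin mean = 1) so a flat curve of ones encodes
"no bias".  A curve is converted to a weighted structure matrix by averaging
it over the relative positions each segment's bases occupy: the GBC in the
coordinate frame of each isoform (GBM), the LBC in the gene-union frame
(LBM).  The two are mixed as b = alpha * GBM + (1 - alpha) * LBM and replace
the 0/1 inclusion matrix in the likelihood.

The GBC is estimated from single-isoform genes only, where the transcript
frame of every read is unambiguous; each contributing gene gets equal weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .gene_models import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_BINS = 10


@dataclass
class BiasCurve:
    """A binned read-density curve over relative position, bin mean = 1."""

    bins: np.ndarray
    kind: str  # 'global' or 'local'

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if self.bins.ndim != 1 or self.bins.size < 2:
            raise ValueError("a bias curve needs at least 2 bins")
        if (self.bins < 0).any():
            raise ValueError("bias curve bins must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.bins.size

    @classmethod
    def flat(cls, n_bins: int = DEFAULT_BINS, kind: str = "global") -> "BiasCurve":
        return cls(np.ones(n_bins), kind)


def _normalize(bins: np.ndarray) -> np.ndarray:
    mean = bins.mean()
    if mean <= 0:
        return np.ones_like(bins)
    return bins / mean


def _five_prime_offsets(gene: GeneModel, offsets: np.ndarray) -> np.ndarray:
    """Convert genomic-left union offsets to 5'->3' offsets on the annotated strand."""
    if gene.strand == "-":
        return gene.union_length - 1 - offsets
    return offsets


def _bin_index(offsets: np.ndarray, length: int, n_bins: int) -> np.ndarray:
    idx = np.floor((offsets + 0.5) / length * n_bins).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def estimate_gbc(
    genes: Sequence[GeneModel],
    offsets_by_gene: Mapping[str, np.ndarray],
    n_bins: int = DEFAULT_BINS,
) -> BiasCurve:
    """Estimate the global bias curve from single-isoform genes.

    Each single-isoform gene with at least one assigned read contributes a
    per-gene histogram of relative read positions, normalised to sum 1 so
    that deep genes do not dominate; histograms are pooled and rescaled to
    bin mean 1.  If no gene qualifies the flat curve is returned with a
    warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pooled = np.zeros(n_bins)
    n_used = 0
    for gene in genes:
        if gene.m != 1:
            continue
        offs = offsets_by_gene.get(gene.gene_id)
        if offs is None or len(offs) == 0:
            continue
        off5 = _five_prime_offsets(gene, np.asarray(offs))
        hist = np.bincount(
            _bin_index(off5, gene.union_length, n_bins), minlength=n_bins
        ).astype(np.float64)
        pooled += hist / hist.sum()
        n_used += 1
    if n_used == 0:
        logger.warning("no single-isoform gene with reads; global bias curve set flat")
        return BiasCurve.flat(n_bins, kind="global")
    return BiasCurve(_normalize(pooled), kind="global")


def estimate_lbc(
    gene: GeneModel,
    offsets: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    min_reads: int = 50,
) -> BiasCurve | None:
    """Estimate the local bias curve of one gene over its exonic union.

    Returns ``None`` when fewer than ``min_reads`` reads are assigned: a
    histogram from that little data is noise, and the caller falls back to
    the global curve alone (alpha = 1).
    """
    offsets = np.asarray(offsets)
    if len(offsets) < min_reads:
        return None
    off5 = _five_prime_offsets(gene, offsets)
    hist = np.bincount(
        _bin_index(off5, gene.union_length, n_bins), minlength=n_bins
    ).astype(np.float64)
    return BiasCurve(_normalize(hist), kind="local")


def _segment_order(gene: GeneModel) -> list[int]:
    """Segment indices in 5'->3' order on the annotated strand."""
    order = list(range(gene.n))
    return order[::-1] if gene.strand == "-" else order


def _mean_curve_over_span(
    curve: BiasCurve, offset: int, length: int, frame_length: int
) -> float:
    """Mean curve value over ``length`` bases starting at 5' offset ``offset``."""
    base_offsets = offset + np.arange(length, dtype=np.float64)
    idx = _bin_index(base_offsets, frame_length, curve.n_bins)
    return float(curve.bins[idx].mean())


def compute_bias_matrix(
    gene: GeneModel, curve: BiasCurve, frame: str = "isoform"
) -> np.ndarray:
    """Average a bias curve over each included segment's relative positions.

    ``frame='isoform'`` (GBM): segment j's bases are located by their
    cumulative 5' offset within isoform i, divided by the isoform length.
    ``frame='gene_union'`` (LBM): bases are located within the gene's exonic
    union, the frame in which the local curve was estimated (the isoform of
    origin of a read is unknown there).  Entries where a_ij = 0 stay 0.
    """
    if frame not in {"isoform", "gene_union"}:
        raise ValueError(f"frame must be 'isoform' or 'gene_union', got {frame!r}")
    a = gene.inclusion
    mat = np.zeros((gene.m, gene.n), dtype=np.float64)
    lengths = gene.segment_lengths
    order = _segment_order(gene)

    if frame == "gene_union":
        L = gene.union_length
        offset = 0
        values = np.zeros(gene.n)
        for j in order:
            values[j] = _mean_curve_over_span(curve, offset, int(lengths[j]), L)
            offset += int(lengths[j])
        mat = values[None, :] * a
    else:
        for i in range(gene.m):
            L = gene.isoform_length(i)
            offset = 0
            for j in order:
                if not a[i, j]:
                    continue
                mat[i, j] = _mean_curve_over_span(curve, offset, int(lengths[j]), L)
                offset += int(lengths[j])
    return mat


def mix_bias(gbm: np.ndarray, lbm: np.ndarray, alpha: float) -> np.ndarray:
    """Arithmetic mixture alpha * GBM + (1 - alpha) * LBM."""
    gbm = np.asarray(gbm, dtype=np.float64)
    lbm = np.asarray(lbm, dtype=np.float64)
    if gbm.shape != lbm.shape:
        raise ValueError(f"shape mismatch: {gbm.shape} vs {lbm.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * gbm + (1.0 - alpha) * lbm


@dataclass
class BiasMatrices:
    """GBM, LBM and their mixture for one gene."""

    gbm: np.ndarray
    lbm: np.ndarray
    alpha: float

    @property
    def mixed(self) -> np.ndarray:
        """The bias-corrected structure matrix b_ij."""
        return mix_bias(self.gbm, self.lbm, self.alpha)
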