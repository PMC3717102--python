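"""End-to-end pipeline: annotation -> counts -> bias curves -> estimates.

Stages: parse the annotation into segmented gene models; stream the SAM file
and count reads per segment; estimate the global bias curve from
single-isoform genes (and, optionally, a local curve per gene); convert
curves to weighted structure matrices and mix them; maximize each gene's
Poisson log-likelihood by coordinate binary search; emit one TSV row per
isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .estimation import (
    ExpressionEstimate,
    OptimizerConfig,
    coordinate_binary_search,
    theta_to_rpkm,
)
from .gene_models import GeneModel, parse_annotation
from .read_counting import CountResult, FilterPolicy, StreamStats, count_reads, stream_alignments

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the full estimation pipeline.

    ``alpha`` weights the global against the local bias matrix
    (b = alpha * GBM + (1 - alpha) * LBM).  The default alpha = 1 uses the
    global curve only: on multi-isoform genes the naive local curve cannot
    distinguish gene-specific bias from the isoform mixture itself (a
    skipped exon looks like a read-depth dip), so mixing it in distorts the
    mixture estimate; lower alpha is available for single-isoform-dominated
    use.  ``use_bias=False`` falls back to the uniform 0/1 structure matrix.
    """

    alpha: float = 1.0
    n_bins: int = bias_mod.DEFAULT_BINS
    min_lbc_reads: int = 50
    use_bias: bool = True
    w_mode: str = "all"
    annotation_format: str | None = None
    optimizer: OptimizerConfig | None = None


def estimate_gene(
    gene: GeneModel,
    counts: np.ndarray,
    w: int,
    gbc: bias_mod.BiasCurve | None,
    offsets: np.ndarray | None,
    config: PipelineConfig,
) -> tuple[ExpressionEstimate, np.ndarray]:
    """Build the structure matrix for one gene and maximize its likelihood."""
    a = gene.inclusion.astype(np.float64)
    if not config.use_bias or gbc is None:
        b = a
    else:
        gbm = bias_mod.compute_bias_matrix(gene, gbc, frame="isoform")
        alpha = config.alpha
        lbm = gbm
        if alpha < 1.0 and offsets is not None:
            lbc = bias_mod.estimate_lbc(
                gene, offsets, n_bins=config.n_bins, min_reads=config.min_lbc_reads
            )
            if lbc is None:
                alpha = 1.0  # too few reads for a per-gene curve
            else:
                lbm = bias_mod.compute_bias_matrix(gene, lbc, frame="gene_union")
        b = bias_mod.mix_bias(gbm, lbm, alpha)
    est = coordinate_binary_search(
        counts, gene.segment_lengths, b, w,
        config=config.optimizer, gene_id=gene.gene_id,
    )
    return est, b


def run_pipeline(
    sam_path: str | Path,
    annotation_path: str | Path,
    config: PipelineConfig | None = None,
    out_path: str | Path | None = None,
    gbc_override: bias_mod.BiasCurve | None = None,
    dump_bias_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full estimation pipeline; return (and optionally write) the table.

    Output columns: gene_id, isoform_id, theta, rpkm, gene_read_count,
    loglik, converged, unidentifiable.  ``gbc_override`` substitutes a known
    global bias curve for the estimated one (useful for controlled studies);
    ``dump_bias_path`` writes the estimated curves as TSV (kind, gene_id with
    '*' for the global curve, bin_index, weight).
    """
    config = config or PipelineConfig()
    genes = parse_annotation(annotation_path, config.annotation_format)
    logger.info("parsed %d genes", len(genes))

    stats = StreamStats()
    need_offsets = config.use_bias
    result: CountResult = count_reads(
        stream_alignments(sam_path, FilterPolicy(), stats),
        genes,
        collect_offsets=need_offsets,
        w_mode=config.w_mode,
    )
    logger.info(
        "retained %d alignments (%d skipped as malformed, %d intergenic), w=%d",
        stats.retained, stats.skipped_malformed, result.intergenic, result.total_reads,
    )
    if result.total_reads == 0:
        logger.warning("zero retained alignments: all expression estimates will be 0")

    gbc = None
    if config.use_bias:
        gbc = gbc_override or bias_mod.estimate_gbc(
            genes, result.offsets, n_bins=config.n_bins
        )
    if dump_bias_path is not None:
        _dump_bias(dump_bias_path, gbc, genes, result, config)

    rows = []
    for gene in genes:
        counts = result.per_gene[gene.gene_id].counts
        est, _ = estimate_gene(
            gene, counts, result.total_reads or 1, gbc,
            result.offsets.get(gene.gene_id), config,
        )
        rpkm = theta_to_rpkm(est.theta)
        for i, iso in enumerate(gene.isoform_ids):
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "isoform_id": iso,
                    "theta": est.theta[i],
                    "rpkm": rpkm[i],
                    "gene_read_count": int(counts.sum()),
                    "loglik": est.loglik,
                    "converged": est.converged,
                    "unidentifiable": est.unidentifiable,
                }
            )
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


def _dump_bias(
    path: str | Path,
    gbc: bias_mod.BiasCurve | None,
    genes: list[GeneModel],
    result: CountResult,
    config: PipelineConfig,
) -> None:
    rows = []
    if gbc is not None:
        rows += [
            {"kind": "global", "gene_id": "*", "bin_index": k, "weight": wgt}
            for k, wgt in enumerate(gbc.bins)
        ]
    if config.alpha < 1.0:
        for gene in genes:
            lbc = bias_mod.estimate_lbc(
                gene,
                result.offsets.get(gene.gene_id, np.empty(0)),
                n_bins=config.n_bins,
                min_reads=config.min_lbc_reads,
            )
            if lbc is None:
                continue
            rows += [
                {"kind": "local", "gene_id": gene.gene_id, "bin_index": k, "weight": wgt}
                for k, wgt in enumerate(lbc.bins)
            ]
    pd.DataFrame(rows, columns=["kind", "gene_id", "bin_index", "weight"]).to_csv(
        path, sep="\t", index=False
    )
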