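"""SAM streaming and per-segment read counting.

Each retained alignment is reduced to its leftmost aligned genomic base
(chromosome, 0-based position) and assigned to the exonic segment containing
that base.  Junction-spanning reads therefore count toward the segment holding
their 5'-most genomic base, and every read lands in at most one segment per
gene.  Paired-end mates are treated as two independent single-end reads.

The library total ``w`` scales the Poisson rates lambda_j = l_j * w * sum_i
b_ij * theta_i; by default it counts every retained alignment whether or not
it overlaps the annotation (``w_mode='all'``), configurable to assigned-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .gene_models import GeneModel

logger = logging.getLogger(__name__)

# FLAG bits dropped by the default policy
_UNMAPPED = 0x4
_SECONDARY = 0x100
_SUPPLEMENTARY = 0x800


@dataclass
class FilterPolicy:
    """Alignment retention policy applied while streaming a SAM file."""

    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    min_mapq: int = 0  # 0 disables MAPQ filtering

    def keep(self, flag: int, mapq: int) -> bool:
        if self.drop_unmapped and flag & _UNMAPPED:
            return False
        if self.drop_secondary and flag & _SECONDARY:
            return False
        if self.drop_supplementary and flag & _SUPPLEMENTARY:
            return False
        if self.min_mapq and mapq < self.min_mapq:
            return False
        return True


@dataclass
class StreamStats:
    """Tally of records seen, retained, and skipped as unparseable."""

    seen: int = 0
    retained: int = 0
    skipped_malformed: int = 0
    filtered: int = 0


def stream_alignments(
    path: str | Path,
    policy: FilterPolicy | None = None,
    stats: StreamStats | None = None,
) -> Iterator[tuple[str, int]]:
    """Yield (chrom, 0-based leftmost position) for each retained alignment.

    Unmapped, secondary and supplementary records are dropped; both mates of
    a pair are yielded independently.  Unparseable records are skipped with a
    warning and tallied in ``stats.skipped_malformed``.  Headerless SAM bodies
    fall back to a plain-text parser.
    """
    policy = policy or FilterPolicy()
    stats = stats if stats is not None else StreamStats()
    try:
        yield from _stream_pysam(path, policy, stats)
    except ValueError:
        # pysam requires @SQ header lines; fall back for headerless bodies
        yield from _stream_text(path, policy, stats)


def _stream_pysam(
    path: str | Path, policy: FilterPolicy, stats: StreamStats
) -> Iterator[tuple[str, int]]:
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        for aln in fh:
            stats.seen += 1
            if not policy.keep(aln.flag, aln.mapping_quality):
                stats.filtered += 1
                continue
            if aln.reference_name is None or aln.reference_start < 0:
                stats.filtered += 1
                continue
            stats.retained += 1
            yield aln.reference_name, aln.reference_start


def _stream_text(
    path: str | Path, policy: FilterPolicy, stats: StreamStats
) -> Iterator[tuple[str, int]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            stats.seen += 1
            fields = line.rstrip("\n").split("\t")
            try:
                flag = int(fields[1])
                rname = fields[2]
                pos = int(fields[3]) - 1
                mapq = int(fields[4])
            except (IndexError, ValueError):
                stats.skipped_malformed += 1
                logger.warning("%s line %d: unparseable SAM record skipped", path, lineno)
                continue
            if not policy.keep(flag, mapq) or rname == "*" or pos < 0:
                stats.filtered += 1
                continue
            stats.retained += 1
            yield rname, pos


@dataclass
class SegmentCounts:
    """Observed per-segment read counts x_j for one gene, plus the library total w."""

    gene_id: str
    counts: np.ndarray  # (n,) non-negative ints
    total_reads: int  # w

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative segment count")


@dataclass
class CountResult:
    """Per-gene counts, the library total, and bookkeeping tallies.

    ``offsets`` holds, per gene, the sorted exonic-union offsets (bases from
    the genomic-leftmost union base) of the assigned reads; the bias module
    converts these to 5'->3' transcript-relative positions.
    """

    per_gene: dict[str, SegmentCounts]
    total_reads: int  # w
    intergenic: int
    offsets: dict[str, np.ndarray] = field(default_factory=dict)


def count_reads(
    alignments: Iterable[tuple[str, int]],
    genes: Sequence[GeneModel],
    collect_offsets: bool = False,
    w_mode: str = "all",
) -> CountResult:
    """Assign reads to exonic segments by leftmost aligned base.

    A read whose leftmost base lies inside segments of several overlapping
    genes increments each such gene.  ``w`` is the number of retained
    alignments (``w_mode='all'``) or only those assigned to at least one
    segment (``w_mode='assigned'``).
    """
    if w_mode not in {"all", "assigned"}:
        raise ValueError(f"w_mode must be 'all' or 'assigned', got {w_mode!r}")

    by_chrom: dict[str, list[int]] = {}
    n_total = 0
    for chrom, pos in alignments:
        by_chrom.setdefault(chrom, []).append(pos)
        n_total += 1
    pos_arrays = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}

    per_gene: dict[str, SegmentCounts] = {}
    offsets: dict[str, np.ndarray] = {}
    assigned_any: dict[str, np.ndarray] = {
        c: np.zeros(len(p), dtype=bool) for c, p in pos_arrays.items()
    }

    for gene in genes:
        pos = pos_arrays.get(gene.chrom)
        counts = np.zeros(gene.n, dtype=np.int64)
        gene_offsets: list[np.ndarray] = []
        if pos is not None and len(pos):
            cum = 0
            for j, seg in enumerate(gene.segments):
                lo = np.searchsorted(pos, seg.start, side="left")
                hi = np.searchsorted(pos, seg.end, side="left")
                counts[j] = hi - lo
                if hi > lo:
                    assigned_any[gene.chrom][lo:hi] = True
                    if collect_offsets:
                        gene_offsets.append(pos[lo:hi] - seg.start + cum)
                cum += seg.length
        per_gene[gene.gene_id] = SegmentCounts(gene.gene_id, counts, 0)
        if collect_offsets:
            offsets[gene.gene_id] = (
                np.concatenate(gene_offsets) if gene_offsets else np.empty(0, dtype=np.int64)
            )

    n_assigned = int(sum(a.sum() for a in assigned_any.values()))
    intergenic = n_total - n_assigned
    w = n_total if w_mode == "all" else n_assigned
    for sc in per_gene.values():
        sc.total_reads = w
    return CountResult(per_gene=per_gene, total_reads=w, intergenic=intergenic, offsets=offsets)
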