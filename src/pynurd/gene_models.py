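"""Gene models: annotation parsing and exon-union segmentation.

A gene with ``m`` isoforms is represented by a set of ``n`` disjoint exonic
segments (sub-exons) together with an ``m x n`` 0/1 inclusion matrix
``a[i, j]`` saying whether isoform ``i`` contains segment ``j``.  Segments are
the maximal genomic intervals over which the set of covering isoforms is
constant, so they form a partition of the gene's exonic union and each isoform
is exactly the concatenation of its included segments.  This is the counting
unit of the Poisson read-count model: segment ``j`` has length ``l_j`` and an
observed read count ``x_j``.

Coordinates are 0-based half-open internally.  GTF input (1-based closed) is
converted on parse; refFlat already uses 0-based half-open exon coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; message names the line number."""


@dataclass(frozen=True)
class ExonSegment:
    """A disjoint exonic segment (0-based half-open genomic interval)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene: isoforms over a shared panel of disjoint exonic segments."""

    gene_id: str
    chrom: str
    strand: str
    isoform_ids: list[str]
    segments: list[ExonSegment]
    inclusion: np.ndarray  # (m, n) 0/1, a[i, j]

    def __post_init__(self) -> None:
        self.inclusion = np.asarray(self.inclusion, dtype=np.int8)
        m, n = self.inclusion.shape
        if m != len(self.isoform_ids) or n != len(self.segments):
            raise ValueError("inclusion matrix shape does not match isoforms/segments")
        if (self.inclusion.sum(axis=1) == 0).any():
            raise ValueError(f"{self.gene_id}: isoform with no segments")
        if (self.inclusion.sum(axis=0) == 0).any():
            raise ValueError(f"{self.gene_id}: segment covered by no isoform")

    @property
    def m(self) -> int:
        """Number of isoforms."""
        return len(self.isoform_ids)

    @property
    def n(self) -> int:
        """Number of exonic segments."""
        return len(self.segments)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=np.int64)

    @property
    def union_length(self) -> int:
        return int(self.segment_lengths.sum())

    def isoform_length(self, i: int) -> int:
        return int(self.segment_lengths[self.inclusion[i] == 1].sum())

    def isoform_exons(self, i: int) -> list[Interval]:
        """Merged exonic intervals of isoform ``i`` (genomic order)."""
        segs = [
            (s.start, s.end)
            for s, a in zip(self.segments, self.inclusion[i])
            if a
        ]
        return _merge_adjacent(segs)


def segment_gene(
    isoform_exons: Sequence[Sequence[Interval]],
) -> tuple[list[Interval], np.ndarray]:
    """Partition isoform exon sets into disjoint segments with constant membership.

    Parameters
    ----------
    isoform_exons
        For each isoform, its exon intervals (0-based half-open, disjoint
        within the isoform).

    Returns
    -------
    segments, inclusion
        ``segments`` are the maximal runs of bases whose covering-isoform set
        is constant (restricted to covered bases), sorted by start;
        ``inclusion[i, j] = 1`` iff isoform ``i`` covers segment ``j``.
    """
    m = len(isoform_exons)
    if m == 0 or any(len(ex) == 0 for ex in isoform_exons):
        raise ValueError("every isoform needs at least one exon")

    bounds = sorted(
        {b for exons in isoform_exons for s, e in exons for b in (s, e)}
    )
    merged = [sorted(_merge_adjacent(list(ex))) for ex in isoform_exons]

    def membership(lo: int) -> frozenset[int]:
        return frozenset(
            i for i, exons in enumerate(merged)
            if any(s <= lo < e for s, e in exons)
        )

    pieces: list[tuple[int, int, frozenset[int]]] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mem = membership(lo)
        if mem:
            pieces.append((lo, hi, mem))

    segments: list[Interval] = []
    rows: list[frozenset[int]] = []
    for lo, hi, mem in pieces:
        if segments and segments[-1][1] == lo and rows[-1] == mem:
            segments[-1] = (segments[-1][0], hi)
        else:
            segments.append((lo, hi))
            rows.append(mem)

    inclusion = np.zeros((m, len(segments)), dtype=np.int8)
    for j, mem in enumerate(rows):
        for i in mem:
            inclusion[i, j] = 1
    return segments, inclusion


def _merge_adjacent(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended intervals."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _build_gene(
    gene_id: str,
    transcripts: dict[str, list[Interval]],
    chroms: dict[str, str],
    strands: dict[str, str],
) -> GeneModel | None:
    chrom_set = set(chroms.values())
    if len(chrom_set) > 1:
        logger.warning(
            "gene %s has transcripts on multiple chromosomes (%s); skipped",
            gene_id, sorted(chrom_set),
        )
        return None
    isoform_ids = sorted(transcripts)
    exon_lists = [sorted(transcripts[t]) for t in isoform_ids]
    segments, inclusion = segment_gene(exon_lists)
    chrom = next(iter(chrom_set))
    strand = strands[isoform_ids[0]]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        isoform_ids=isoform_ids,
        segments=[ExonSegment(chrom, s, e) for s, e in segments],
        inclusion=inclusion,
    )


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF annotation into gene models.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  1-based closed GTF coordinates are
    converted to 0-based half-open.  Genes are returned sorted by
    (chromosome, start).
    """
    genes: dict[str, dict[str, list[Interval]]] = {}
    chroms: dict[str, dict[str, str]] = {}
    strands: dict[str, dict[str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if len(line.split("\t")) < 9:
                    raise ValueError("expected 9 tab-separated GTF columns")
                feat = feature_from_line(line)
                if feat.featuretype != "exon":
                    continue
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
                start0, end = feat.start - 1, feat.end
                if start0 >= end:
                    raise ValueError("empty exon interval")
            except Exception as exc:
                raise AnnotationParseError(
                    f"{path}: malformed GTF record at line {lineno}: {exc}"
                ) from exc
            genes.setdefault(gene_id, {}).setdefault(tx_id, []).append((start0, end))
            chroms.setdefault(gene_id, {})[tx_id] = feat.seqid
            strands.setdefault(gene_id, {})[tx_id] = feat.strand

    models = []
    for gene_id, transcripts in genes.items():
        model = _build_gene(gene_id, transcripts, chroms[gene_id], strands[gene_id])
        if model is not None:
            models.append(model)
    models.sort(key=lambda g: (g.chrom, g.segments[0].start, g.gene_id))
    return models


def parse_refflat(path: str | Path) -> list[GeneModel]:
    """Parse a UCSC refFlat annotation (11 tab-separated columns) into gene models.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds.  Exon coordinates are already 0-based
    half-open.  Rows sharing ``geneName`` become isoforms of one gene; a
    duplicated transcript name within a gene is overwritten by the last row,
    with a warning.
    """
    genes: dict[str, dict[str, list[Interval]]] = {}
    chroms: dict[str, dict[str, str]] = {}
    strands: dict[str, dict[str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise AnnotationParseError(
                    f"{path}: refFlat row at line {lineno} has "
                    f"{len(fields)} columns, expected 11"
                )
            gene_name, tx_name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                exon_count = int(fields[8])
                starts = [int(v) for v in fields[9].rstrip(",").split(",")]
                ends = [int(v) for v in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: malformed refFlat row at line {lineno}: {exc}"
                ) from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                logger.warning(
                    "%s line %d: exonCount %d disagrees with exon lists; row rejected",
                    path, lineno, exon_count,
                )
                continue
            tx_map = genes.setdefault(gene_name, {})
            if tx_name in tx_map:
                logger.warning(
                    "%s line %d: duplicate transcript %s in gene %s; last row wins",
                    path, lineno, tx_name, gene_name,
                )
            tx_map[tx_name] = list(zip(starts, ends))
            chroms.setdefault(gene_name, {})[tx_name] = chrom
            strands.setdefault(gene_name, {})[tx_name] = strand

    models = []
    for gene_id, transcripts in genes.items():
        model = _build_gene(gene_id, transcripts, chroms[gene_id], strands[gene_id])
        if model is not None:
            models.append(model)
    models.sort(key=lambda g: (g.chrom, g.segments[0].start, g.gene_id))
    return models


def parse_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Dispatch on annotation format ('gtf' or 'refflat'), inferring from suffix."""
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "gtf" if suffix in {".gtf", ".gff"} else "refflat"
    if fmt == "gtf":
        return parse_gtf(path)
    if fmt == "refflat":
        return parse_refflat(path)
    raise ValueError(f"unknown annotation format: {fmt!r}")
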