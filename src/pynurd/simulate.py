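"""Ground-truthed RNA-seq read simulation for isoform-quantification studies.

The generator builds a synthetic chromosome of non-overlapping genes, then
samples single-end reads (default 75 bp) at the transcript level:

1. an isoform is chosen with probability proportional to
   ``weight_i * isoform_length_i`` (a read is a uniform draw over transcribed
   bases when weights encode per-base transcription rates);
2. a start position is drawn along the isoform from a positional bias density
   (flat for an unbiased library), resampling starts that would run past the
   3' end;
3. the start is projected through the isoform's exon chain to a genomic
   coordinate and emitted as one SAM record, with ``N`` operations in the
   CIGAR across introns.

Two-isoform genes follow a cassette-exon design — one isoform contains an
internal exon that the other skips — which is the canonical structure in
which mixture estimation is non-trivial.  Single-isoform "calibration" genes
are included so the global bias curve can be estimated the same way it is on
real data.  The truth table reports the sampling weights, the implied theta
(expected reads per start-position base per sequenced read, the scale the
estimator works on) and the realised per-isoform read counts.

Everything is driven by one integer seed; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import BiasCurve
from .gene_models import ExonSegment, GeneModel, segment_gene

CHROM = "chrS"


@dataclass
class SimulationSpec:
    """Study conditions for one simulated library.

    ``n_multi_genes`` cassette-exon genes with ``isoforms_per_gene`` isoforms
    are the evaluation set; ``n_single_genes`` single-isoform genes of length
    ``single_gene_length`` anchor the global bias curve.  Per-gene abundance
    is log-uniform over a 4-fold range and the major isoform takes a fraction
    of gene expression drawn uniformly from ``major_fraction_range`` — deep
    enough splits to be recoverable, close enough to be non-trivial.
    """

    n_multi_genes: int = 50
    isoforms_per_gene: int = 2
    n_single_genes: int = 20
    total_reads: int = 100_000
    read_length: int = 75
    bias: BiasCurve | str = "uniform"  # 'uniform', 'linear_decay', or a curve
    seed: int = 0
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length: int = 300
    gene_spacing: int = 1000
    single_gene_length: int = 3000
    major_fraction_range: tuple[float, float] = (0.6, 0.9)

    def bias_curve(self, n_bins: int = 50) -> BiasCurve | None:
        """Resolve the bias setting to a curve (None = exactly uniform)."""
        if isinstance(self.bias, BiasCurve):
            return self.bias
        if self.bias == "uniform":
            return None
        if self.bias == "linear_decay":
            return linear_decay_curve(n_bins)
        raise ValueError(f"unknown bias setting: {self.bias!r}")


def linear_decay_curve(n_bins: int = 50) -> BiasCurve:
    """Linear 5'-enriched density f(t) = 2(1 - t), discretised to bin means."""
    t_mid = (np.arange(n_bins) + 0.5) / n_bins
    return BiasCurve(2.0 * (1.0 - t_mid), kind="global")


def make_toy_annotation(
    spec: SimulationSpec, gtf_path: str | Path | None = None
) -> list[GeneModel]:
    """Build non-overlapping gene models on a synthetic chromosome.

    Multi-isoform genes alternate constitutive and cassette exons: isoform 1
    contains every exon, each further isoform skips one internal exon.  If
    ``gtf_path`` is given, a GTF encoding the models is written.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[GeneModel] = []
    cursor = spec.gene_spacing

    for g in range(spec.n_multi_genes):
        m = spec.isoforms_per_gene
        n_exons = max(3, m + 1)
        lo, hi = spec.exon_length_range
        lens = rng.integers(lo, hi + 1, size=n_exons)
        exons: list[tuple[int, int]] = []
        pos = cursor
        for L in lens:
            exons.append((pos, pos + int(L)))
            pos += int(L) + spec.intron_length
        iso_exons = [exons]  # isoform 1: all exons
        for k in range(1, m):
            skipped = 1 + (k - 1) % (n_exons - 2)  # internal exon to skip
            iso_exons.append([e for idx, e in enumerate(exons) if idx != skipped])
        segs, incl = segment_gene(iso_exons)
        gid = f"gene{g + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=CHROM,
                strand="+",
                isoform_ids=[f"{gid}.iso{i + 1}" for i in range(m)],
                segments=[ExonSegment(CHROM, s, e) for s, e in segs],
                inclusion=incl,
            )
        )
        cursor = pos + spec.gene_spacing

    for g in range(spec.n_single_genes):
        half = spec.single_gene_length // 2
        exons = [
            (cursor, cursor + half),
            (cursor + half + spec.intron_length,
             cursor + half + spec.intron_length + spec.single_gene_length - half),
        ]
        segs, incl = segment_gene([exons])
        gid = f"ref{g + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=CHROM,
                strand="+",
                isoform_ids=[f"{gid}.iso1"],
                segments=[ExonSegment(CHROM, s, e) for s, e in segs],
                inclusion=incl,
            )
        )
        cursor = exons[-1][1] + spec.gene_spacing

    if gtf_path is not None:
        write_gtf(genes, gtf_path)
    return genes


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon records (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gene in genes:
            for i, iso in enumerate(gene.isoform_ids):
                for start, end in gene.isoform_exons(i):
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{iso}";'
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def write_refflat(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models in the 11-column UCSC refFlat dialect."""
    with open(path, "w") as fh:
        for gene in genes:
            for i, iso in enumerate(gene.isoform_ids):
                exons = gene.isoform_exons(i)
                starts = ",".join(str(s) for s, _ in exons) + ","
                ends = ",".join(str(e) for _, e in exons) + ","
                tx_start, tx_end = exons[0][0], exons[-1][1]
                fh.write(
                    "\t".join(
                        [
                            gene.gene_id, iso, gene.chrom, gene.strand,
                            str(tx_start), str(tx_end), str(tx_start), str(tx_start),
                            str(len(exons)), starts, ends,
                        ]
                    )
                    + "\n"
                )


@dataclass
class _Isoform:
    gene_id: str
    isoform_id: str
    weight: float
    exons: list[tuple[int, int]]
    length: int


def _draw_weights(genes: list[GeneModel], spec: SimulationSpec, rng) -> list[_Isoform]:
    isoforms: list[_Isoform] = []
    for gene in genes:
        gene_weight = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        m = gene.m
        if m == 1:
            fracs = [1.0]
        else:
            major = rng.uniform(*spec.major_fraction_range)
            rest = np.full(m - 1, (1.0 - major) / (m - 1))
            fracs = np.concatenate([[major], rest])
            rng.shuffle(fracs)
        for i, iso in enumerate(gene.isoform_ids):
            exons = gene.isoform_exons(i)
            isoforms.append(
                _Isoform(
                    gene_id=gene.gene_id,
                    isoform_id=iso,
                    weight=gene_weight * float(fracs[i]),
                    exons=exons,
                    length=gene.isoform_length(i),
                )
            )
    return isoforms


def _sample_relative_positions(n: int, curve: BiasCurve | None, rng) -> np.ndarray:
    """Draw relative positions t in [0, 1) from the bias density (flat if None)."""
    if n == 0:
        return np.empty(0)
    if curve is None:
        return rng.random(n)
    p = curve.bins / curve.bins.sum()
    k = rng.choice(curve.n_bins, size=n, p=p)
    return (k + rng.random(n)) / curve.n_bins


def _project_to_genome(
    start: int, read_length: int, exons: list[tuple[int, int]]
) -> tuple[int, str]:
    """Map a transcript start to (genomic pos, CIGAR) across the exon chain."""
    remaining = read_length
    cigar: list[str] = []
    genome_pos = None
    offset = start
    for idx, (s, e) in enumerate(exons):
        seg_len = e - s
        if offset >= seg_len:
            offset -= seg_len
            continue
        if genome_pos is None:
            genome_pos = s + offset
        take = min(seg_len - offset, remaining)
        cigar.append(f"{take}M")
        remaining -= take
        offset = 0
        if remaining == 0:
            break
        gap = exons[idx + 1][0] - e
        cigar.append(f"{gap}N")
    if remaining > 0 or genome_pos is None:
        raise ValueError("read runs past the 3' end of the transcript")
    return genome_pos, "".join(cigar)


def simulate_reads(
    spec: SimulationSpec,
    sam_path: str | Path,
    genes: list[GeneModel] | None = None,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sample reads under the spec and write a SAM file; return the truth table.

    The truth table has one row per isoform with columns ``gene_id``,
    ``isoform_id``, ``weight`` (sampling weight), ``theta_true`` (implied
    expected reads per start base per sequenced read), ``reads_sampled``.
    Isoforms shorter than the read length are excluded from sampling with a
    warning-level weight of 0.
    """
    rng = np.random.default_rng(spec.seed)
    if genes is None:
        genes = make_toy_annotation(spec)
    isoforms = _draw_weights(genes, spec, rng)
    if weights is not None:
        for iso in isoforms:
            iso.weight = weights[iso.isoform_id]
    curve = spec.bias_curve()
    rl = spec.read_length

    sampleable = np.array([iso.length >= rl for iso in isoforms])
    raw = np.array([iso.weight * iso.length for iso in isoforms])
    raw[~sampleable] = 0.0
    if raw.sum() <= 0:
        raise ValueError("no isoform is long enough to sample reads from")
    p = raw / raw.sum()

    counts = rng.multinomial(spec.total_reads, p) if spec.total_reads else np.zeros(len(p), int)

    chrom_len = max(e for g in genes for seg in g.segments for e in (seg.end,)) + 1000
    lines = [
        "@HD\tVN:1.6\tSO:unsorted\n",
        f"@SQ\tSN:{CHROM}\tLN:{chrom_len}\n",
        "@PG\tID:pynurd-sim\tPN:pynurd-sim\n",
    ]
    read_idx = 0
    for iso, n_reads in zip(isoforms, counts):
        if n_reads == 0:
            continue
        L = iso.length
        n_eff = L - rl + 1  # admissible start positions
        starts = np.empty(n_reads, dtype=np.int64)
        filled = 0
        while filled < n_reads:
            t = _sample_relative_positions(n_reads - filled, curve, rng)
            cand = np.floor(t * L).astype(np.int64)
            ok = cand < n_eff
            n_ok = int(ok.sum())
            starts[filled:filled + n_ok] = cand[ok]
            filled += n_ok
        for s in starts:
            pos, cigar = _project_to_genome(int(s), rl, iso.exons)
            read_idx += 1
            lines.append(
                f"r{read_idx:08d}\t0\t{CHROM}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
            )
    with open(sam_path, "w") as fh:
        fh.writelines(lines)

    total_weighted = float(sum(iso.weight * iso.length for iso in isoforms if iso.length >= rl))
    rows = []
    for iso, n_reads in zip(isoforms, counts):
        if iso.length >= rl:
            n_eff = iso.length - rl + 1
            theta_true = iso.weight * iso.length / (total_weighted * n_eff)
        else:
            theta_true = 0.0
        rows.append(
            {
                "gene_id": iso.gene_id,
                "isoform_id": iso.isoform_id,
                "weight": iso.weight,
                "theta_true": theta_true,
                "reads_sampled": int(n_reads),
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    spec: SimulationSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write annotation, reads and truth table; return their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtf = out / "genes.gtf"
    sam = out / "reads.sam"
    truth_path = out / "truth.tsv"
    genes = make_toy_annotation(spec, gtf_path=gtf)
    truth = simulate_reads(spec, sam, genes=genes)
    truth.to_csv(truth_path, sep="\t", index=False)
    return sam, gtf, truth_path
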