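# Methods

## Counting model

Each gene is reduced to disjoint exonic segments — maximal genomic intervals
over which the set of covering isoforms is constant — because isoforms of one
gene overlap and a Poisson-per-exon model needs non-overlapping count units.
Segmentation is computed from interval boundaries and verified in the tests
against a base-level brute-force oracle; by construction the segments
partition the exonic union and each isoform is exactly the concatenation of
its included segments.

A read is assigned by its leftmost aligned genomic base (SAM POS, converted
to 0-based): junction-spanning reads count toward the segment containing
their 5'-most genomic base, so every read lands in at most one segment per
gene, and a base shared by overlapping genes increments each of them.
Unmapped, secondary and supplementary alignments are dropped; paired mates
are counted as two independent single-end reads; multi-mapping beyond the
primary alignment is ignored (the model has no multi-mapping term). The
library total `w` defaults to all retained alignments, annotation-overlapping
or not (`--w-mode assigned` restricts it); `w` only rescales every `θ`
uniformly, so the choice does not affect isoform ranking within genes.

With `x_j` the count on segment `j` of length `l_j`, the model is
`x_j ~ Poisson(l_j · w · Σ_i b_ij θ_i)` with segments independent. Segments
with `x_j = 0` keep the `−λ_j` penalty and drop the log term (the Poisson
pmf at zero). `θ_i` is expected reads per base per sequenced read; the RPKM
column is `θ · 10⁹` (10³ bases/kb × 10⁶ reads/million), making RPKM the
natural reporting unit of this parameterisation.

## Positional bias correction

Bias curves are binned, mean-normalised read densities over relative
transcript position `t ∈ [0,1)` measured 5'→3' on the annotated strand
(B = 10 bins by default; coarse bins keep per-gene histograms stable at
moderate depth). The global curve (GBC) is estimated from single-isoform
genes only — the transcript coordinate of a read is unambiguous only when
the isoform is known — with each gene's histogram normalised to sum 1 before
pooling, so deep genes do not dominate. Genes with fewer than
`--min-lbc-reads` (default 50) assigned reads get no local curve.

A curve becomes a weighted structure matrix by averaging it, per base, over
the relative positions each included segment occupies: the GBC in each
isoform's own coordinate frame (GBM), the local curve in the gene-union
frame where it was estimated (LBM, where the isoform of origin of a read is
unknown). The mixture `b = α·GBM + (1−α)·LBM` is arithmetic. A flat curve
reproduces `a_ij` exactly, so the corrected model reduces bit-for-bit to the
uniform one — a tested invariant.

**Default α = 1 (global curve only).** The naive per-gene local curve is the
raw read-density histogram over the gene union, and on a multi-isoform gene
that histogram confounds positional bias with the isoform mixture itself: a
skipped exon produces a genuine read-depth dip that the LBM would then
"correct away". Working through the two-isoform cassette case shows the
resulting estimator misranks the isoforms for a range of true mixtures even
at infinite depth, so mixing the local curve in by default harms exactly the
genes the tool exists for. The mixture weight remains exposed (`--alpha`)
for libraries dominated by single-isoform genes or gene-specific bias, and
genes under the read threshold always fall back to α = 1.

## Optimization

The log-likelihood is concave, so each coordinate restriction is concave and
its partial derivative monotone non-increasing; the 1-D maximizer is found
by bisection on the gradient — no step size, and at most
`⌈log₂(interval/ε)⌉` iterations. Multi-isoform genes cycle coordinates
(coordinate binary search). Implementation details:

* **Search interval** for `θ_i`: `[0, 2·Σ_j x_j / (w · min_{j: b_ij>0} l_j b_ij)]`;
  beyond `Σx/(w Σ l_j b_ij)` the partial derivative is provably negative, so
  the bracket always contains the coordinate-wise maximizer.
* **Precision `eps` (default 1e-10) is relative** to each coordinate's
  interval width, making the stopping rule scale-free in θ (which ranges
  over orders of magnitude with sequencing depth).
* **Initialisation** splits the gene's read mass equally:
  `θ_i = Σx / (m · w · Σ_j l_j b_ij)`. Concavity makes the optimum
  independent of the start; a scaled start just converges faster.
* **Pattern move**: plain cyclic coordinate ascent zigzags when two `b` rows
  are nearly collinear (contraction per sweep can approach 1). After each
  sweep the implementation performs one exact concave line search along the
  sweep's net displacement — the same bisection, applied to the directional
  derivative — which removes the slow ridge direction. `t = 0` lies inside
  the search interval, so monotone ascent is preserved; the recorded
  log-likelihood trace is non-decreasing in every run.
* **Stopping**: a sweep improving the log-likelihood by less than
  `loglik_tol = 1e-11` (absolute), capped at `max_sweeps = 5000`. With the
  pattern move, random 4-isoform instances converge in well under 700
  sweeps; the achieved log-likelihood matches an independent
  bound-constrained quasi-Newton maximizer to ~1e-10.
* **Degenerate cases**: genes with zero total counts return θ = 0 without
  optimizing; an isoform whose `b` row is all zero is pinned at 0; two
  isoforms with identical `b` rows make any split of their shared mass
  equally likely, so such genes are flagged `unidentifiable` and evaluation
  can exclude or fail them explicitly. The single-isoform closed form
  `θ = Σx_j / (w Σ l_j b_j)` is used as a test oracle, not a shortcut — the
  coordinate loop reproduces it to < 1e-6 relative error.

## Simulator

The generator emulates the evaluation protocol the estimator is designed
for: single-end 75 bp reads at depths from 10⁴ to 10⁶, sampled from
two-isoform genes. Defaults (deliberately fixed, not tuned per experiment):

* 50 cassette-exon genes — isoform 1 carries three exons of 150–400 bp,
  isoform 2 skips the middle one — the canonical structure where mixture
  estimation is non-trivial; plus 20 single-isoform genes of 3 kb that
  anchor the global bias curve exactly as real single-isoform genes would.
  Genes are placed non-overlapping on one synthetic chromosome (plus
  strand), so no read is ambiguous between genes.
* Per-gene abundance log-uniform over a 4-fold range; the major isoform
  takes a uniform 60–90 % share of its gene, giving a unique, recoverable
  but non-trivial major isoform.
* A read picks an isoform with probability ∝ weight × isoform length, draws
  a start from the positional bias density (flat, linear 5' decay
  `f(t) = 2(1−t)`, or any supplied curve) with starts within a read length
  of the 3' end rejected, and is projected through the exon chain to genomic
  coordinates with `N` CIGAR gaps across introns.
* The truth table reports sampling weights, realised read counts, and the
  implied `θ` (isoform sampling probability divided by its number of
  admissible start positions), which is the scale the estimator works on.

What the simulator does **not** emulate — and hence what passing tests do
not certify on real data: sequence-context (hexamer/GC) and mappability
bias, sequencing errors and quality values, mapping ambiguity between
paralogs, fragment-length effects in paired-end data, genes overlapping on
opposite strands, and annotation errors. The 3'-end rejection also means
start positions cover only `L − read_length + 1` bases; truth `θ` accounts
for this, and bias-curve tests use 3 kb genes so the truncation (< 2.5 % of
the last bin) is far below the tested tolerances.

## Problem sizes

Test and acceptance runs use 50 + 20 genes and depths up to 10⁶ reads with
5 replicate seeds — deep enough that the depth trend and the
corrected-vs-uniform comparison are stable, and the entire suite still runs
in a few minutes on one CPU. The MIRR depth sweep (mean over 5 seeds)
reproduces the expected qualitative behaviour: accuracy rises with depth and
saturates near 1.0 at 10⁶ reads, and under a strong 5'-decay bias the
corrected structure matrix recovers major isoforms at least as well as the
uniform model on identical data.

## Known limitations

* The local-curve estimator is intentionally naive (raw density histogram);
  a bias estimator that deconvolves the fitted mixture from the local
  density would let α < 1 help rather than hurt multi-isoform genes.
* Junction reads are assigned by leftmost base rather than split across
  segments; with long reads relative to exon lengths this shifts mass
  toward upstream segments.
* No multi-mapping model, no fragment-length model, no confidence
  intervals: point estimates only.
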