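# pynurd

Isoform-level expression estimation from RNA-seq alignments, with
nonparametric correction of positional sequencing bias.

Most genes produce several alternative-splicing isoforms, and reads from a
bulk (or pooled single-cell) RNA-seq library arrive as an unlabelled mixture
of them. `pynurd` recovers per-isoform expression by modelling segment-level
read counts with a Poisson likelihood and maximizing it by coordinate binary
search — a bisection-based scheme that needs no step size, is guaranteed by
concavity to reach the global optimum, and works from compact per-exon
counts rather than per-read data structures.

## Model

A gene's isoforms are decomposed into `n` disjoint exonic segments
(maximal intervals of constant isoform membership) with lengths `l_j` and a
0/1 inclusion matrix `a_ij` (isoform `i` contains segment `j`). With `w`
total reads in the library and `θ_i` the expression of isoform `i`
(expected reads per base per sequenced read; RPKM = `θ · 10⁹`), the read
count on segment `j` is modelled as Poisson with rate

```
λ_j = l_j · w · Σ_i b_ij θ_i
```

giving the concave log-likelihood

```
log L(Θ) = −w Σ_j Σ_i l_j b_ij θ_i + Σ_j x_j log(l_j w Σ_i b_ij θ_i) − Σ_j log x_j!
```

Under uniform sampling `b_ij = a_ij`. Real libraries are positionally
biased, so `b_ij` reweights `a_ij` by binned read-density curves over
relative transcript position: a **global bias curve (GBC)** estimated from
all single-isoform genes and an optional per-gene **local bias curve
(LBC)**, mixed as `b = α·GBM + (1−α)·LBM`. Maximization cycles exact 1-D
bisections on the partial derivatives (coordinate binary search), each 1-D
search finishing in `O(log 1/ε)` iterations, with a concave line search
along each sweep's displacement to accelerate near-collinear cases.

Accuracy is scored by **MIRR** (major isoform recovery rate): the fraction
of genes whose highest-expressed isoform is correctly identified.

## Worked example

Simulate a ground-truthed library (50 two-isoform cassette-exon genes plus
20 single-isoform calibration genes, 100,000 reads of 75 bp), estimate, and
score:

```bash
nurd simulate --out-dir sim --seed 42
nurd run --sam sim/reads.sam --gtf sim/genes.gtf --out expression.tsv
nurd mirr --truth sim/truth.tsv --est expression.tsv
```

which prints

```
MIRR    1.0000  (50/50 genes; 0 excluded, 0 estimate ties)
```

i.e. the estimated major isoform matched the simulated truth in all 50
two-isoform genes. The first output rows:

```
gene_id    isoform_id      theta                   rpkm                gene_read_count  loglik               converged  unidentifiable
gene0001   gene0001.iso1   4.242981962596519e-06   4242.981962596519   868              -16.760138217034182  True       False
gene0001   gene0001.iso2   1.0615308512970861e-05  10615.308512970862  868              -16.760138217034182  True       False
```

`theta` is the per-base sampling rate (truth for this gene: 4.35e-06 and
1.27e-05), `rpkm` its reads-per-kilobase-per-million scaling, and `loglik`
the gene's maximized log-likelihood. Isoform 2 is correctly identified as
major. Equivalent library calls: `pynurd.simulate_dataset`,
`pynurd.run_pipeline`, `pynurd.mirr`.

Estimation from real data needs only a SAM file mapped to the genome and a
GTF or refFlat annotation (`nurd run --sam aln.sam --gtf genes.gtf --out
out.tsv`); paired-end mates are treated as independent single-end reads.

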