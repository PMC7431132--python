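# nrchip

ChIP-seq analysis of nuclear-RNAi-induced heterochromatin marks, built for
studies of germline small-RNA silencing in *C. elegans*-like systems where
the marks of interest (H3K23me3, H3K9me3) concentrate on chromosome arms,
at repetitive elements, and at genes silenced by the nuclear RNAi pathway —
including transgenerationally, for several generations after an RNAi
trigger is removed.

The package covers the full post-alignment pipeline plus a ground-truth
simulator, so every stage is testable without downloading data:

* **Coverage** — each alignment of a read mapping to *n* loci is weighted
  1/*n*; alignments are extended to 500 bp fragments from the sequenced 5′
  end; tracks are mean per-base weighted depth per bin, normalized to reads
  per million aligned reads (value = mean depth × 10⁶/depth).
* **Window statistics** — 1 kb windows genome-wide; pseudocounted
  ChIP/input and mutant/WT ratios; arm-vs-center comparison by
  Mann–Whitney U with an arm/center median-ratio effect size; Pearson
  correlation between marks.
* **Dependence calling** — a gene's mark *depends* on a factor when the
  mutant shows a ≥ 2-fold decrease vs wild type with p < 0.05 (conditional
  binomial on read counts, given library depths) in every replicate pair.
* **Overlap analysis** — Venn intersections of dependent-gene sets with a
  one-sided Fisher's exact test, P(X ≥ k) = Σᵢ₌ₖ C(|A|,i)·C(N−|A|,|B|−i) /
  C(N,|B|) over a gene universe of size N, and repeat-class composition of
  target genes.
* **Simulation** — a toy multi-chromosome genome with arm heterochromatin,
  GRH/GRTS-style target regions, repeat families whose copies induce
  multimapping, genotype-dependent loss of planted enrichment, and
  geometric decay of enrichment across generations,
  fold(g) = 1 + (f₀ − 1)·effect·d^g.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a two-chromosome genome with 10 enrichment-target genes among 60,
knock the mark out in an hrde-1-like mutant, and recover the targets:

```python
from nrchip import *

cfg = SimConfig(chrom_lengths=[("chrI", 500_000), ("chrII", 500_000)],
                n_genes=60, n_target_genes=10, n_grh=3, n_grts=3,
                n_reads=30_000, seed=7)
layout, genes, repeats, regions, truth = build_toy_genome(cfg)

wt  = [simulate_library(cfg, truth, "H3K23me3", "WT", "chip", r) for r in (1, 2)]
mut = [simulate_library(cfg, truth, "H3K23me3", "hrde-1", "chip", r) for r in (1, 2)]
calls = call_dependent_genes(wt, mut, genes, layout)
called, targets = set(calls.loc[calls.dependent, "gene_id"]), set(truth.target_genes())
print("dependent genes called:", len(called), "of", len(targets), "planted targets")

windows = make_windows(layout, 1000)
sig = window_signal(compute_coverage(wt[0], layout, 1000), windows)
summ = arm_center_compare(sig, windows, layout)
print(f"arm/center median ratio: {summ.effect_ratio:.2f}  "
      f"(Mann-Whitney p = {summ.p_value:.3g})")

p, odds, _ = fisher_overlap(called, targets, set(genes["name"]))
print(f"overlap of called vs planted: p = {p:.3g}")
```

Output:

```
dependent genes called: 10 of 10 planted targets
arm/center median ratio: 3.04  (Mann-Whitney p = 1.45e-142)
overlap of called vs planted: p = 1.33e-11
```

All 10 planted targets are recovered with no false calls; the arm/center
ratio of 3.04 matches the planted 3× arm background; the Fisher p-value
confirms the called set overlaps the truth far beyond chance.

## Command line

The `nrchip` entry point exposes each stage: `simulate` (genome +
libraries + truth), `coverage` (library → bedGraph), `windows` (window
table, arm/center summary), `call-deps` (dependence table), `overlap`
(Venn/Fisher/repeat composition) and `report` (end-to-end from a YAML
config). For example:

```sh
nrchip simulate --outdir sim --seed 7
nrchip coverage sim/H3K23me3_WT_chip_rep1.tsv \
    --layout sim/genome.chrom.sizes --bin-size 1000 -o wt.bedgraph
```

Libraries are read and written as minimal SAM (with an `NH` hit-count tag)
or a 6-column alignment TSV; annotations as BED6; tracks as bedGraph. All
intervals are 0-based half-open.

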