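# Methods

`nrchip` implements a ChIP-seq analysis pipeline for heterochromatin histone
marks (H3K23me3, H3K9me3) at germline nuclear-RNAi targets, together with a
ground-truth alignment simulator that exercises every stage without any
external data. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Coverage model

The pipeline consumes alignments, not reads: short-read alignment is an
upstream tool's job, and the analysis assumes only perfect alignments are
reported. Three rules define the signal:

1. **Fractional multimapper weighting.** A read reported at *n* equally good
   loci contributes weight 1/*n* at each, so its total mass is exactly 1.
   This keeps repetitive nuclear-RNAi targets (transposons, repeat arrays)
   visible without double counting.
2. **Fragment extension.** Each alignment is replaced by a 500 bp interval
   extending downstream (3′) from the sequenced 5′ end — the standard
   single-end approximation of ChIP fragment occupancy. Intervals are
   clipped at chromosome boundaries; partial clipping keeps the partial
   mass (there is no basis for discarding boundary reads).
3. **Depth normalization.** Bin values are mean per-base weighted depth
   within the bin × 10⁶ / depth, where depth is the number of distinct
   aligned reads. Using the bin *mean* (not the sum) makes values
   independent of bin size: refining bins never changes genome-wide mass,
   and duplicating a library leaves the track unchanged. Units are
   reads-per-million (RPM); "per million aligned reads" is the conventional
   realization of depth normalization and preserves all ratios.

Per-base depth is accumulated with a difference array and cumulative sum;
an independent brute-force per-base oracle in the tests confirms exact mass
conservation. Default bin sizes: 25 bp for locus profiles, 1000 bp for
genome-wide analyses.

## Window statistics

Whole-genome analyses use 1 kb windows tiling every chromosome (terminal
windows may be short; window means are length-weighted, so this is exact).
Enrichment ratios are `(num + pc) / (den + pc)` with pseudocount `pc`
defaulting to one read's mass in one window at the library's depth
(`extension/window × 10⁶/depth`) — a scale-aware floor that sends
zero-vs-zero windows to ratio 1.

Arm-vs-center comparison assigns each window by midpoint (unambiguous for
boundary-straddling windows) and uses a two-sided Mann–Whitney U test: a
rank test matches the boxplot-style presentation of such comparisons and is
robust to the heavy right tail of ChIP coverage. The effect size is the
arm/center median ratio. Because genome-wide window counts make minute
shifts significant, the summary carries a `significant_but_negligible` flag:
p < 0.05 with median ratio inside [1/1.1, 1.1]. Between-mark correlation is
plain Pearson on window ratios (untransformed by default — scatter axes are
ratios — with a log2 option).

## Dependent-gene calling

A gene's mark is *dependent* on a factor when the mutant loses at least
two-fold relative to wild type, significantly, in **every** replicate pair
(pairs are matched by index). Per pair:

* fold change = WT/mutant on depth-normalized gene signals with a
  pseudocount (default: one read's mass over the median gene span);
* p-value from a depth-conditioned count test on the gene's raw weighted
  read masses: conditional on the summed mass, the WT share is binomial
  with success probability equal to WT's depth share, tested one-sided for
  loss in the mutant. A Fisher 2×2 variant is exposed as an alternative
  strategy. Fractional multimapper masses are rounded half-to-even because
  exact tests need integers.
* Masses come from cumulative per-base depth sums, so gene spans need no
  bin alignment. Gene span = annotated body with flank 0 by default
  (configurable).

Both raw-p (default, matching a "p < 0.05 in two replicas" criterion) and
Benjamini–Hochberg FDR thresholding are provided; different figures of this
kind of analysis use each. The calling is monotone in the threshold and
alpha by construction, and WT-vs-WT null pairs pass the per-replicate
criterion at most at rate α (verified in tests).

Region-class summaries assign each 1 kb window by midpoint to GRH, GRTS or
"rest" and report mutant/WT ratio quartiles per class.

## Overlap statistics

Gene-set overlap uses the hypergeometric upper tail P(X ≥ observed overlap)
over a fixed universe — one-sided, because the claim under test is that
overlaps exceed chance. The universe defaults to all annotated genes (the
natural maximal choice; configurable). `scipy.stats.hypergeom.sf` supplies
the tail at full precision; an exhaustive subset-enumeration oracle confirms
agreement to 12 digits for all configurations over universes ≤ 12. Venn
sizes are exact set arithmetic and satisfy inclusion–exclusion.

Gene–repeat annotation counts a gene as repeat-containing iff its interval
intersects a repeat interval by ≥ 1 bp (half-open convention: touching is
not overlap). Class fractions are computed among repeat-containing genes; a
gene can carry several classes.

## Synthetic-data generator

The generator emulates the experimental design at the alignment level —
sequence simulation and alignment are deliberately skipped, since the
pipeline's contract begins after alignment. The toy genome defaults:

* three 1 Mb chromosomes, arms covering 25% of each end (arms are where
  worm heterochromatin concentrates);
* 200 genes of 2 kb, of which 20 are enrichment targets; 8 GRH and 8 GRTS
  regions of 2 kb placed only on arms;
* repeat families (Low_complexity ×5×200 bp, DNA ×4×400 bp, LTR ×3×500 bp)
  of identical-length copies; 60% of target genes carry one planted copy,
  echoing the repeat-rich composition of nuclear-RNAi target genes;
* arm background fold 3, target fold 8 per mark, 100 000 reads of 50 bp per
  library.

Read 5′ starts are drawn from an additive mixture: uniform background plus
per-element excess proportional to (fold − 1), so expected in-region vs
background count ratios equal the planted fold. Input libraries ignore all
planted enrichment. The planted fold for a condition is

    fold(mark, genotype, g) = 1 + (fold₀(mark) − 1) · effect(genotype) · d^g

with genotype effect multipliers in [0, 1] (an hrde-1-like or set-32-like
mutant has effect 0; a met-2 set-25-like mutant 0.5 by default) and
geometric decay d per generation after the trigger is removed. The
geometric form is the simplest monotone model of persistence-then-decline;
no quantitative decay law is established for heritable RNAi, so this is a
modeling choice, not an inference. Multimapping is modeled by copy
identity: a read sampled wholly inside a repeat copy is reported at the
same offset in every copy of the family with `n_hits = copy_number`.
Strand is uniform (ChIP fragments are unstranded).

Sampling is exact: segment boundaries of the piecewise-constant intensity
are enumerated, a multinomial splits reads across segments, and positions
are uniform within segments. Exactly `n_reads` distinct reads are emitted;
identical seeds give byte-identical libraries, and per-library seeds are
derived from the config seed plus a hash of (mark, genotype, role,
replicate, generation) so replicates differ while remaining reproducible.

**What the simulator does not model:** sequencing error, PCR duplicates,
mappability variation beyond whole repeat copies, fragment-length
distributions, chromatin accessibility bias, or biological variance between
replicates (replicates differ only by sampling noise). Passing tests
therefore demonstrate the *pipeline's* correctness and statistical
calibration under the stated generative model, not robustness to every
artifact of real libraries.

## Problem sizes and numerics

Simulation-driven checks use 2–3 Mb genomes with 40k–200k reads per
library — large enough that planted folds are recovered within a few
percent of sampling error, small enough to run in seconds. Estimated folds
from count ratios are compared with tolerances derived from binomial
sampling error at those depths (e.g. ±15% for a 3× arm ratio at 100k
reads). Exact checks (mass conservation, Fisher enumeration, I/O round
trips) use machine-precision or printed-precision tolerances (bedGraph
values carry 10 significant digits). A count-ratio fold estimate at an
enriched region is mildly shrunk toward 1 (the enrichment excess inflates
the ChIP library's total intensity); tolerances account for this.

## Known limitations

* Arm boundaries are configuration inputs; no inference of heterochromatin
  domain boundaries is attempted.
* The per-gene significance model treats reads as independent Bernoulli
  draws; overdispersion between biological replicates is handled only by
  the two-replicate requirement, not by a dispersion model.
* `gene_signal` on a binned track is exact only when spans align to bin
  edges; the calling path uses per-base cumulative sums instead.
* BAM/CRAM and bigWig are out of scope; SAM, TSV, BED and bedGraph cover
  the pipeline's needs.
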