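# Methods

This package reimplements, as a tested pipeline over synthetic data, the
small-RNA-seq analysis used to discover "rogue" 21-nt siRNAs — rRNA-derived
siRNAs (risiRNAs) and coding-gene-derived siRNAs that appear in a
silencing-pathway mutant and compete with miRNAs for AGO loading. The raw
study data are not required: a synthetic genome and simulator reproduce the
statistical structure of the study, and every statistic is checked against
independent oracles or the simulator's ground truth.

## The synthetic testbed

`synthio.build_toy_genome` constructs a two-contig genome deterministically
from a seed: a ~47-kb main chromosome interleaving 8 MIR loci, 24 coding
genes, one TAS locus and 6 TEs (two of which are an identical repeat-family
pair, so TE reads genuinely multimap), plus a 7-kb rDNA transcription unit
tiled contiguously as 5'ETS–18S–ITS1–5.8S–ITS2–25S–3'ETS. Subfeature
lengths are fixed fractions of the unit length (minimum 6 kb, i.e. at least
sixty 100-bp bins).

Because alignment is exact-match (0 mismatches), sequence biases are baked
into the genome at build time: mature miRNAs start with U with probability
0.9, and the sense 5' position of every planted phase cycle is set to T
with probability 0.8. Simulated reads are verbatim genomic substrings.

`synthio.simulate_libraries` draws, per library, per-locus intensities from
the negative-binomial hierarchy *conditioned on the configured depth*:
Gamma(1/α, α·mean) intensities followed by a multinomial over loci. Each
library therefore contains exactly `depth` reads; with α = 0 this is the
conditional law of independent Poisson draws given their sum. The default
α = 0.02 is a typical biological-replicate dispersion for abundant sRNA
loci in count-model analyses; at 2 replicates it leaves the ~2.5-fold
AGO-IP miRNA enrichment comfortably detectable, which the IP analysis
presumes.

Populations and their default WT abundance shares:

| population      | share | lengths | notes |
|-----------------|-------|---------|-------|
| miRNA           | 0.30  | 21      | fixed geometric abundance ladder over 1.5 decades; 5'-U 0.9 |
| het-siRNA (TE)  | 0.45  | 24      | the dominant WT peak |
| TAS phasiRNA    | 0.04  | 21      | phased register planted, both genotypes |
| rDNA phasiRNA   | 0.28* | 21      | planted in ETS/ITS spacers, mutant only |
| gene phasiRNA   | 0.18* | 21      | 6 genes, mutant (and rescue) only |
| rRNA degradation| 0.15  | 18–30   | sense strand, all genotypes |
| antisense bkg   | 0.03  | 18–30   | 5'-C biased (genomic G at the 5' position) |

\* phased shares are the level in the genotype that expresses them; the
default effect map switches them off in WT (multiplier 0), on in the
mutant, and removes only the rDNA population in the rescue genotype. The
miRNA abundance ladder is fixed rather than drawn, because the genotype
contrasts planted on top of it (rRNA overtaking miRNA as the top 21-nt
category, the rescue restoring miRNA dominance in AGO) are design
guarantees of the generator, not outcomes left to a random draw. Three
abundant miRNAs are reduced ~3-fold in the mutant, the least abundant one
is up 1.6-fold, the rest are at 0.55 — most down, a few up.

AGO-IP libraries are importance-resampled from the matched input
composition: each distinct (insert, population) category is reweighted by a
length weight (21/22-nt: 2.0; 24-nt: 0.1; otherwise 0.5), a ×4 bonus for
21/22-nt reads starting with U, and a genotype-specific miRNA loading
factor (0.5 in the mutant). Resampling the input, rather than drawing
independently, makes per-locus IP/input ratios meaningful.

What the simulator does **not** model: sequencing errors, quality-score
variation, PCR duplicates, isomiR heterogeneity, and genome-scale
repetitiveness. Passing tests therefore demonstrate the correctness and
calibration of the analysis code under the study's statistical structure,
not performance on real libraries.

## Preprocessing and alignment

Trimming is a semi-global, mismatch-only match of the 3' adapter
(AGATCGGAAGAGC) against every read suffix: up to ceil(0.1 × matched length)
mismatches, minimum overlap 3, leftmost match wins; reads without any
adapter match are rejected, and inserts are then size-selected to 18–42 nt.
Reads containing N are discarded. A vectorized batch trimmer is the
production path; a scalar reference implementation defines the semantics
and the two are property-tested for read-for-read agreement.

Placement is exact-match via an 18-mer anchor index over both strands. The
5' end of a minus-strand placement is the rightmost genomic coordinate.
Multimappers are handled in three modes: `unique` (drop), `fractional`
(weight 1/n), and `guided`, where a candidate's weight is proportional to
1 + U_c with U_c the uniquely-placed read weight within ±100 nt of the
candidate 5' end. `guided` is a deterministic stand-in for density-guided
multimapper assignment; the tool the study used breaks residual ties
randomly and caps random placements, which we deliberately do not —
reproducibility was preferred over emulating a stochastic heuristic. Reads
with more than `max_hits` (default 1000) placements are suppressed.

## Quantification

Counting is by 5'-end coordinate: each placement adds its weight to exactly
one 100-bp bin, and to every feature unit (gene body, MIR locus, TE, TAS,
rRNA subfeature, 1000-bp gene-upstream region) containing the 5' end — a
read may legitimately count toward a gene and a neighbour's upstream
region. RPM normalizes by the per-library weighted placement total. Bins
are classified by the highest-precedence category covering ≥ 50 % of the
bin (miRNA > TAS > rRNA > gene > TE > other), with overlap summed per
category first so a bin spanning two contiguous rRNA subfeatures stays
rRNA; the 50 % rule and the precedence order are configurable. Strand
tracks export per-position 5'-end RPM as a bedGraph pair with
minus-strand values negative.

## The NB Wald test

Library size factors are median-of-ratios against the geometric-mean
pseudo-reference over all-positive units, falling back to column totals
when fewer than 50 such units exist (e.g. sparse per-length matrices); the
pipeline computes one set of factors per length class from the genome-wide
bin matrix and reuses it for gene-level tests.

Per-unit dispersion is method-of-moments on normalized counts,
α̂ = max(0, (s² − m̄)/m̄²) from the pooled within-condition variance, shrunk
halfway toward a trend α(μ) = a0 + a1/μ fitted by least squares on the
positive raw estimates with one outlier-trimming pass. Fitting on the
positive estimates makes the trend slightly conservative (upward-biased)
for units whose raw estimate clips at zero. With one replicate per
condition the per-unit estimate is undefined and the trend is used alone.

The test statistic is z = log2FC / SE with log2FC from 0.5-pseudocount
normalized means and SE² = (1/ln²2) Σ_g (1/(n_g (m_g+0.5)) + α/n_g); p is
two-sided normal, adjusted by Benjamini–Hochberg within each
(category × length) family, excluding all-zero (untestable) units from the
family size. Measured operating characteristics at the null
(μ = 50, α = 0.1, 2 vs 2): type-I error 0.057–0.063 at nominal 0.05 across
seeds; recovery of 8-fold effects planted on 50/2000 units: sensitivity
≈ 0.96, empirical FDR ≈ 0.05 (the acceptance script pools this measurement
over five replicate simulations, because a single 2000-unit realization
has visible Monte-Carlo spread in the FDR).

One known property worth stating plainly: with dispersion forced to zero
the log-scale Wald p agrees with the difference-scale two-proportion z-test
only for moderate fold changes. The z² gap grows like m·δ⁴ (m the count
scale, δ the relative difference), reaching ≈ 0.19 in log10 p at a
2.2-fold change with counts near 50. The oracle-equivalence check
therefore runs on a 20×20 grid of counts 50–88 (fold changes ≤ 1.76),
where the measured worst disagreement is 0.081 in log10 p; the divergence
outside that regime is a property of the two statistics, not an
implementation artifact.

DSR/DSG calls use padj < 0.05 and |log2FC| ≥ 1 by default (the thresholds
are configurable and recorded in run reports; the study does not state the
ones behind its printed counts). The miRNA summary reports per-miRNA fold
changes plus a one-sample two-tailed t test of the log2FC vector against
zero with df = n − 1. Overlap significance between unit sets uses the
exact k-set intersection distribution built recursively — the running
intersection against set j is hypergeometric(N, m, n_j) — which reduces to
the classic hypergeometric upper tail for two sets.

## Phasing

21-nt placements are pooled across strands after shifting minus-strand 5'
ends by +2 (the 2-nt 3'-overhang convention) and assigned to registers
modulo 21. Windows of 10 cycles (210 nt), stepped by one phase, score

    score = (k − 2) · ln(1 + 10·P/(1 + U)),  k ≥ 3, else 0

where P is the weight in the window's dominant register, U the rest, and k
the number of distinct cycles occupied in that register. Qualifying
windows (score ≥ 10 by default) are merged into regions whose score,
register and tallies come from the best window. The simulator plants
antisense phased reads so that sense and antisense pool into a single
register *under this shift rule*; published bookkeeping conventions for
the duplex overhang differ by a constant register offset, and internal
consistency was chosen over any one of them. Note that k counts any
occupancy of the dominant register, so stray background reads can extend
qualifying windows and merge nearby phased loci (the two rDNA ITS loci
merge into one region at default depth); per-locus register recovery is
still exact, and tests assert it per planted locus rather than per region.
A 22-nt phase is supported for DCL2-product analyses but off by default.

## AGO loading

IP enrichment reuses the NB Wald test with conditions {IP, input} and
calls units with padj < 0.05 and log2 enrichment > 0. Loading efficiency
is RPM(IP)/RPM(input) per miRNA; a zero input RPM is replaced by a 0.5-RPM
pseudocount and flagged. The top-N (default 20) membership is ranked by WT
input abundance with name tie-breaks, and genotypes are compared over the
same miRNAs with a two-sided paired Wilcoxon signed-rank test: zeros
dropped, average ranks for ties, exact null by convolution over sign
assignments for n ≤ 25 (ranks doubled to integers), otherwise a normal
approximation with continuity and tie corrections.

Because loading efficiency is a ratio of RPM values, a large planted
influx of competing siRNAs shifts the IP denominator composition: the
measured mutant/WT median efficiency ratio (~0.3–0.4) is systematically
below the planted per-read loading factor (0.5). That compression is the
competition effect itself, not an estimator defect, and the recovery test
allows for it.

## Problem sizes and determinism

Default study conditions: 2 replicates per genotype (the study text does
not state its replicate count; 2 is the configurable default), 100,000
reads per library, machine reads 75 nt padded with G after the adapter.
The test suite runs one session-wide study (WT, mutant, rescue; 60,000
reads/library) plus small targeted simulations; the acceptance script
re-runs everything from scratch, seeded from its `--seed`, in well under
its budget. Identical (genome, config, seed) give byte-identical FASTQ
and identical run-report checksums (path parameters are excluded from the
checksum).

## Known limitations

* Exact matching only; no mismatch/indel alignment, no large-genome index.
* The guided multimapper weighting is a declared emulation, not a
  reimplementation of the original tool's algorithm.
* The NB test targets calibration, not numerical parity with any external
  count-model package; GLMs with covariates and shrunken LFC estimators
  are out of scope.
* The phasing k-statistic is permissive toward background occupancy, as in
  the common published form; region boundaries are approximate where
  phased loci are close together.
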