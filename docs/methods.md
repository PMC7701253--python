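# Methods

## Pipeline model

`operonpp` treats operon discovery as the intersection of four independent
sources of evidence over an annotated bacterial genome:

1. **Genomic geometry** — operon members are adjacent, same-strand genes.
   "Nearby" is implemented as the start-to-start distance of consecutive
   genes ≤ `max_span_nt` (default 10,000 nt). Start-to-start is used
   because it stays well-defined for nested or overlapping genes; the
   cutoff is configurable.
2. **Phylogenetic profiles** — each gene inherits the binary
   presence/absence vector of its orthogroup over an ordered genome panel
   (focal genome first). Consecutive genes must have Jaccard distance
   `< max_distance` (default 0.001). On any panel of `G ≤ 1000` genomes
   the smallest nonzero Jaccard distance is `1/|union| ≥ 1/G > 0.001`, so
   the default rule is *exactly* equivalent to requiring identical
   vectors; it also makes the "all pairwise" and "consecutive pairs only"
   readings of the grouping rule coincide. Genes with no orthogroup get a
   flagged focal-only singleton profile; such a profile can only ever
   match another focal-only profile, so unassigned genes cannot link to
   panel-supported ones.
3. **Co-regulation** — all members must carry the same differential
   expression sign (up or down). Genes not called DE are ineligible; by
   default an ineligible gene between two eligible ones breaks the chain
   (members of one transcription unit are expected to respond together).
   A `skip_ineligible` mode links across such gaps instead.
4. **Promoter architecture** — a predicted operon is TSS-validated when a
   primary TSS is assigned to its leader gene (5′-most in transcription
   direction) and no primary TSS is assigned to a downstream member. A
   `leader_only` flag relaxes the second condition.

Grouping is the chaining of consecutive eligible pairs into maximal runs
(connected components restricted to genomic adjacency), so each gene joins
at most one operon.

## Differential expression

Normalisation is counts-per-million only; no trimmed-mean or median-ratio
scale factors. Consequences: (i) library scale factors cancel exactly, but
(ii) when a large, imbalanced mass of expression shifts between conditions,
CPM fold changes absorb a composition offset of
`log2(Σ treated mass / Σ control mass)`. With the simulator's defaults
(30 % of transcription units at |log2FC| = 2, signs balanced) the offset is
≈ 0.42, which biases up-gene fold-change estimates toward the `|log2FC| > 1`
cutoff and explains the down-vs-up asymmetry in called DEGs. This is a
documented property of CPM-only screens, not corrected here.

The per-gene test is the classical conditional binomial comparison of two
Poisson rates, applied to counts pooled within condition: conditional on
`n = x_t + x_c`, `x_t ~ Binomial(n, s_t/(s_t+s_c))` under the null, with
`s` the pooled library sizes; two-sided p = `min(1, 2·min(lower, upper))`,
p = 1 when `n = 0`. It is exactly computable and brute-force verifiable.
Its trade-off: pooling discards between-replicate variability, so the test
is calibrated under Poisson variation (verified: null rejection at 5 %
within ±3 Monte-Carlo SD on 2,000 genes) but anti-conservative under
overdispersion (dispersion 0.1 in the default simulation produces a ~10 %
empirical DEG false-positive rate, visible as predicted-operon fragments of
null units only when two adjacent false positives share a sign). Dispersion
estimation and shrinkage are deliberately out of scope.

The expression filter (mean CPM over *all* samples ≥ 1, the least
aggressive common reading) defines the universe both for BH adjustment and
for enrichment. Fold changes use pseudocount 0.5 on mean CPM to keep zeros
finite. Two DEG-labelling presets exist because two rules circulate for
this kind of screen: the default `q ≤ 0.05` on BH-adjusted values with
`|log2FC| > 1`, and `RESULTS_RULE_PRESET` (raw p < 0.001, same fold-change
cut). Both are exposed as config.

## TSS caller

A position is a candidate when its 5′-end count is ≥ `min_count` (10) AND
≥ `enrichment_factor` (5) × the local background, where background is the
mean coverage within ± `bg_window` (100 nt) excluding ± 2 nt of the
candidate, floored at 0.1 to avoid division by zero. Candidates within
`cluster_width` (5 nt) chain-merge, keeping the maximal count (ties →
smallest coordinate). Classification windows: primary within
[start − 300, start + 50] of a same-strand gene start (strand-aware:
for − genes "start" is the GFF3 end and the window extends to larger
coordinates), internal inside a same-strand gene body, antisense inside an
opposite-strand body, orphan otherwise; multiple primary candidates resolve
to the nearest start. All caller parameters are package defaults chosen for
sharp dRNA-seq-like libraries and are config-exposed; none is taken from
any published tool. The caller cannot detect that its input is not
5′-end-derived coverage — that is a documented input contract.

## Synthetic data generator

The generator emulates the study design the pipeline targets — a focal
genome under a two-condition cytokine-exposure contrast with a 130-genome
panel — at desk scale. Defaults: 300 genes in 40 operons (sizes uniform
2–6) plus monocistronic units, gene lengths uniform in [500, 1500] nt
(mean 1 kb), intra-operon gaps ≤ 50 nt, inter-unit gaps 210 + Exp(90) nt
(mean 300; the 210 nt floor keeps neighbouring units' TSSs — upstream
offsets ≤ 100 nt each — farther apart than the caller's cluster width, so
the planted truth is unambiguous at single-nucleotide resolution). Units
get random strands; one contig only.

Profiles: one Bernoulli(0.7) pattern per transcription unit over the 129
non-focal genomes, shared exactly by operon members; the focal column is
always 1. Optional noise flips each non-focal bit independently with
probability ε (symmetric gain/loss; asymmetric rates would be an
extension, not the default). Counts: `NB(mean = s_j · μ_g · 2^(lfc·[treated]),
dispersion φ = 0.1)` with `μ_g ~ LogNormal(5, 1)` (natural-log scale,
median ≈ 148 counts), `s_j ~ Uniform(0.8, 1.2)`, `φ = 0` degenerating to
Poisson. Condition effects (|log2FC| = 2, random sign) are planted per
transcription unit with probability 0.3, so DE signs are coherent within
operons by construction. TSS coverage: one true TSS per unit,
Uniform[20, 100] nt upstream of the leader in transcription direction,
Poisson(50) reads with Normal(0, 1) rounded jitter, over Poisson(0.1)
per-position background on each strand. Every generator is a pure function
of its config + seed (bit-identical reruns; independent substreams per
stage).

What the simulation does *not* emulate: real intergenic-distance
distributions, multi-contig genomes, tree-structured gain/loss on the
panel, GC/length biases in counts, processed 5′ ends and internal RppH
artefacts, or condition-dependent TSS usage. Passing recovery tests
therefore demonstrates correctness of the implemented criteria, not
real-data operon accuracy.

## Evaluation conventions

Operon recovery compares predictions with planted operons *restricted to
genes actually called DE* (a gene the DE stage missed cannot appear in any
prediction); with the default chaining rule the restriction also splits a
planted operon at each non-DE member, mirroring how the predictor can at
best behave. On the noise-free default fixture precision = recall = 1.0;
under profile noise ε ∈ {0, 0.005, 0.02, 0.05} mean recall (10 seeds)
decays monotonically, steeply — a single flipped bit among 129 panel
columns already pushes a pair past the 0.001 threshold.

The DE power experiment plants 4-fold effects in 10 % of 1,000 genes
(balanced signs) and measures sign-correct recovery among planted genes
with ≥ 100 mean control counts; the modest DE fraction keeps the CPM
composition offset (≈ 0.06) from confounding the sensitivity measurement,
which is the property under test. Power is ≥ 95 % there; under the default
pipeline fixture's heavier 30 % DE load the composition offset costs a few
percentage points for up-regulated genes.

TSS recovery matches called to true positions greedily within ± 2 nt on
the same strand, one-to-one. The hypergeometric upper tail and the BH
step-up are verified against brute-force enumerations (all instances with
N ≤ 12; min-over-suffix definition on random p-vectors).

## Numerical and interface choices

Coordinates are 1-based inclusive internally (GFF3 convention); BED and
bedGraph convert at the boundary. Jaccard distance of two all-zero vectors
is defined as 0. Unstranded GFF3 features are rejected, not guessed, since
strand is a hard operon criterion. The published fold-change table ships
with decimal commas and typographic minus signs exactly as printed; the
reader normalises both. "Delta" in enrichment output is `n_up − n_down`
per category — the only signed per-category quantity constructible from
"k/n"-style counts — reported alongside both raw counts so alternative
definitions can be recomputed. Category maps are user-supplied TSVs; no
database is downloaded.

Problem sizes throughout the tests and the acceptance script (300-gene
pipeline fixture, 1,000–2,000-gene DE experiments, 10-seed noise sweeps)
are the package's chosen desk-scale defaults; all complete in seconds on
one CPU.
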