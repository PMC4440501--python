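# Methods

This note documents the models and procedures implemented in `strandex`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Transcript classification

Transcripts come from a stranded assembly, so each sequence is 5'→3' in the
orientation it was transcribed, and an alignment's strand (query relative to
the subject's coding/transcript strand) distinguishes sense from antisense
transcription.

Classification is strictly sequential; each transcript receives exactly one
of six mutually exclusive categories:

1. **sense** — best sense-orientation hit to the reference proteome covers
   more than 60% of the protein (`sense_protein_cov = 0.60`, strict `>`).
   Transcripts whose proteome hit falls short of that bar may be rescued by a
   sense-orientation hit to a general protein database (nr) clearing the same
   bar.
2. **isoform propagation** — every transcript sharing a gene id (the first
   two underscore-delimited parts of a Trinity-style id) with a sense
   transcript becomes sense. This captures short splice variants that cannot
   individually cover 60% of the protein. Propagation runs before the
   antisense rules and is idempotent.
3. **antisense** — `antisense_to_protein`: best antisense-orientation hit to
   a protein covers more than 50% of it. `antisense_to_sense`: antisense hit
   to a sense transcript covering more than 80% of the query at ≥95%
   identity, where the partner sense transcript itself has a proteome hit
   (antisense transcripts hitting only a sense transcript typically cover
   untranslated regions). Both conditions → `antisense_to_both`.
4. **lncRNA** — genome or nucleotide-database hit covering more than 80% of
   the query at ≥95% identity.
5. **unknown** — everything else: misassemblies, or real transcripts with
   insufficient similarity to known sequences.

Boundary conventions: coverage thresholds are strict (`>`), identity
thresholds inclusive (`≥`); both readings are pinned by unit tests. Best hit
per database and orientation is the lowest e-value, ties broken by higher
bitscore, then lexicographically smaller subject id, making runs
deterministic when an upstream aligner reports ties. Whether nr-protein hits
may satisfy the antisense >50% rule is not determined by the procedure's
description; the default says yes, and a `Thresholds.nr_feeds_antisense`
flag turns it off. lncRNA coverage is query-relative (the fraction of the
*transcript* aligned), the natural reading of "alignment length" for a
transcript query against a genome.

The 200 bp minimum length is enforced at catalogue load, before
classification, matching its role as an assembly-level filter.

**Putative ORFs** are reported for lncRNA and unknown transcripts: an ATG
followed by an in-frame stop encoding ≥30 residues (Met counted, stop not).
The scan covers the three forward frames only — library strandedness fixes
the transcript orientation, so reverse frames would contradict the assembly.
Codons containing N neither start nor stop an ORF. The longest qualifying
ORF is returned, ties broken by the smaller start coordinate. The finder is
verified against a brute-force oracle that enumerates every ATG and walks to
the first in-frame stop.

## Expression filtering and differential expression

Counts are rounded effective read counts per transcript (upstream estimators
distribute multi-mapping reads and normalise for length; if real-valued
counts are supplied, they are rounded half-to-even). The expression filter
keeps transcripts ≥200 bp with cpm > 1 (strict) in at least 3 of the 12
samples per species.

The design per species is 4 groups (naive, 0 h, 4 h, 24 h after
conditioning) × 3 biological replicates. The model per transcript *i* and
sample *j* is

    y_ij ~ NB(mu_ij, phi_i),   Var = mu + phi mu^2,
    log mu_ij = log N_j + beta_0 + beta_g(j) + gamma_r(j),

with library-size offsets log N_j, time-point effects beta_g (naive as
baseline) and replicate block effects gamma_r. Replicate blocking absorbs
batch-level correlation between samples collected together.

**Dispersion estimation.** Counts are first scaled to the geometric-mean
library size. Each group with n ≥ 2 replicates contributes df-weighted
moment terms; the per-transcript estimate is

    phi_raw = max(0, Σ (n_g − 1)(s_g² − m_g) / Σ (n_g − 1)(m_g² − s_g²/n_g)).

The denominator uses `m² − s²/n`, the unbiased moment estimator of the
squared group mean — plain `m²` overestimates it by Var(m̄) and biases the
dispersion low. The abundance trend pools the numerator and denominator sums
within bins of 50 transcripts ordered by average log2-cpm and interpolates
linearly between bin medians (flat beyond the ends, so the trend is finite
and non-negative at any abundance). Pooling moments within a bin, rather
than taking a median of per-transcript ratios, was chosen after measurement:
with 2 df per group the per-transcript ratio is strongly right-skewed, its
bin median sits ~10% below the generative dispersion, and plugging that into
the likelihood-ratio test inflated the measured null type-I error to 0.067
at nominal 0.05; the pooled-moment trend restores near-unbiased dispersions
(median 0.098 at true 0.1) and a measured type-I error of ~0.054. The final
per-transcript dispersion shrinks the raw estimate toward the trend with
weight 0.7 — transcripts borrow strength from their abundance neighbourhood,
as count-based DE methods do, without attempting any specific tool's
empirical-Bayes machinery (Cox–Reid adjusted profile likelihood and
quasi-likelihood tests are out of scope).

**Testing.** With the shrunk dispersion held fixed, each transcript's GLM is
fitted by iteratively reweighted least squares, vectorised across
transcripts (shared design matrix; batched normal equations; max 50
iterations; convergence at max |Δβ| < 1e-8; linear predictor clipped at ±30
so zero-count groups degenerate gracefully instead of diverging). Each
contrast is tested by the likelihood ratio against the model without that
coefficient, χ² with 1 df; log2FC = β/ln 2. Transcripts with all-zero counts
in both compared groups are skipped with p = 1; non-converged fits are
flagged and given p = 1 with a logged warning, never silently. The fitter is
cross-checked against an independent GLM implementation (statsmodels) on NB
test data, and on balanced saturated designs the log2FC equals the log2
ratio of group means to 1e-8.

P-values are adjusted by the Benjamini–Hochberg step-up procedure, one
family per contrast per species (results are reported per time point, so
pooling families would mix report units). Significance is FDR < 0.05
(strict); direction is the sign of log2FC.

## Cross-species analyses

Gene identity across species is the best-hit protein in the single shared
reference proteome — both species' transcripts are aligned to the same
proteome, so reciprocal-best-hit machinery is unnecessary. A protein is
"shared" when at least one transcript of each species maps to it.

**Opposing-direction genes**: a gene qualifies when some mapped transcript is
significantly up in one species and some mapped transcript significantly
down in the other *at the same time point* (default). The same-time-point
requirement is a design choice — opposite transient responses at different
times are weaker evidence of opposite regulation — and the any-time-point
variant is available behind `same_timepoint=False`. The rule is symmetric in
the species.

**Known-memory-gene panel**: per panel gene and species, each DE transcript
contributes a row (numbered (1), (2), … when a gene has several), with the
log2FC shown in the cells where the transcript is significant and `ns`
elsewhere; |log2FC| ≥ 1.5 carries a display marker, which never affects DE
calls. Antisense presence per gene and species comes from the classifier:
an antisense transcript covers a panel gene when its deciding alignment
subject is that gene's protein or a sense transcript mapping to it.

**Naive between-species contrast**: the comparable set is proteins with
exactly one mapped transcript in each species (a 1:1 join keeps the joined
counts unambiguous; how a published comparable set of this kind was
constructed is typically unstated, and this is our documented choice). The
joined naive counts are analysed with the same NB machinery, species factor
plus replicate blocks.

## GO enrichment

One-sided Fisher's exact test per term: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n) with N the annotated background, K the term's
annotated genes, n the DE set (annotated members only), k the overlap. The
universe is restricted to annotated proteins — genes without any GO term
carry no information for a term-membership test. Significance follows the
permissive raw p < 0.05 convention of small-study GO scans; BH-adjusted
values are reported alongside. The annotation table is consumed pre-slimmed
(GO-slim); ontology traversal is out of scope, but an optional child→parent
table enables the "most specific terms" filter (a term is dropped from a
cell when one of its children is also significant there).

## Synthetic data generator

The generator emulates the *structure* of a two-species stranded
head-transcriptome study, not its sequences: transcripts are random
nucleotide strings with controlled ORF content, and alignments are emitted
directly as tabular records consistent with each transcript's true category
under the classifier's thresholds (every qualifying coverage strictly beyond
its cut — a configurable near-threshold fraction sits just above coverage
cuts and exactly at the inclusive 95% identity bound; every disqualifying
hit strictly below). It therefore validates decision logic, calibration and
recovery, not alignment heuristics: passing tests say nothing about aligner
behaviour, read mapping, assembly artifacts, or sequence-level homology
noise in real data.

Defaults are the study conditions at desk scale: catalogue composition
dominated by sense genes (~72% of genes; antisense, lncRNA and unknown in
study-like minority shares), 74.7% of sense genes single-isoform, 12 samples
per species (4 groups × 3 replicates), NB counts with log-normal baseline
(median 150 counts), constant dispersion 0.1 (biological CV ≈ 0.32, typical
for insect whole-head replicates), replicate effect s.d. 0.1 on the log
scale shared across transcripts within a replicate, 10% of transcripts DE
per time point with |log2FC| ~ U(1, 3), 5 opposing-direction genes, 80% of
sense genes shared between species, a 20-gene memory panel with 6
planted antisense transcripts, and 40 GO terms at density 0.08 with 3
planted enriched terms covering 80% of DE genes against a 5% background.
Gene counts are in the hundreds rather than the study's ~30k — the package's
chosen working scale for tests and the acceptance script; all rates and
thresholds are scale-free.

Two structural simplifications keep the truth layer exact: only sense genes
receive multiple isoforms (so isoform propagation can never contradict a
non-sense truth label), and random DE directions are drawn per (shared
protein, time point) so random planting cannot fabricate
opposing-direction genes — opposing pairs exist only where planted. One
global seed drives independent per-purpose streams (catalogue, counts, GO),
so stages can be regenerated independently; identical configs produce
byte-identical files.

## Numerical conventions

- Percentages in report tables: round half up, one decimal; mean lengths:
  integers, round half up. The published-style tables' printed percentages
  recompute exactly from their printed counts under these rules.
- Real-valued counts are rounded half-to-even on input.
- Coordinates are 0-based half-open internally; 1-based inclusive only in
  the BLAST-style alignment dialect.
- IRLS: max 50 iterations, tol 1e-8, no pseudocounts (the NB likelihood
  handles zeros); dispersions below 1e-12 use the Poisson likelihood.
- Empty subsets (e.g. an empty DE set in a summary or enrichment cell)
  produce empty tables, never division errors.

## Known limitations

- The DE machinery is a documented approximation of trended-dispersion NB
  GLM analysis, not a re-implementation of any specific tool; its acceptance
  surface is calibration (type-I error within [0.035, 0.065] at nominal
  0.05) and recovery (≥90% of strongly planted signal at FDR < 0.05), not
  numerical identity with any particular tool.
- Classification trusts the alignment table; it does not re-align, and
  conflicting evidence across databases is resolved purely by the sequential
  rule order and best-hit tie-breaks.
- Cross-species gene identity by shared best hit collapses paralogs that hit
  the same protein; the 1:1 restriction of the naive contrast drops genes
  with species-specific isoform mapping.
- Small non-coding RNAs are outside the length filter and never classified.
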