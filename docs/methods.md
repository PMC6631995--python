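# Methods

This note documents the models, parameter choices and numerical
conventions behind `enfragility`, and what the synthetic-world results
do and do not show about real data.

## Coordinates, masking, degenerate inputs

All internal coordinates are 0-based half-open; VCF input is the only
1-based surface and is converted on read. Repeat masking is carried
exclusively by sequence case: lowercase bases are repeat-masked, and any
k-mer or PSSM window touching a lowercase base or an `N` is skipped.
GC content is computed over A/C/G/T only (N excluded from the
denominator); an all-N sequence has no defined GC and raises
`UndefinedStatisticError`, as do statistics with empty denominators
(divergence with no alignable bases, conserved fraction of a fully
masked enhancer, HTC fraction of a TF with no hits).

## K-mer vocabularies

K-mers are counted under reverse-complement canonicalization (the
lexicographically smaller of a word and its reverse complement), which
gives (4ᵏ + 4^(k/2))/2 classes for even k — 32,896 at k = 8. Each window
of each sequence contributes one count to its canonical class; a
palindromic word is counted once per window. Enrichment of a k-mer in
enhancers against matched controls is the one-sided Fisher exact test on
the 2×2 table [this k-mer vs all other windows] × [enhancers vs
controls], computed vectorized as the hypergeometric upper tail.
Classes: `top` requires Bonferroni-corrected p ≤ α (α = 10⁻³, factor =
universe size) **and** higher window density in enhancers; `background`
is raw p > α; everything else is `neutral`. K-mers absent from both sets
have raw p = 1 and are background. Top k-mers carry weight
log₂((d_e + ε)/(d_c + ε)) with densities d = count/total windows and
ε = 1/(total enhancer + control windows); other classes have weight 0.
One vocabulary is built per (k, track) from enhancer subsequences
overlapping that track's peaks (track intervals at or above the 0.8
value quantile), plus a pooled vocabulary per k from full enhancer
sequences; the pooled k = 8 vocabulary drives candidate detection.

## Matched controls

For each enhancer, candidate windows of identical length are drawn
uniformly over the genome (O(1) per candidate via prefix sums) and
accepted when |ΔGC| ≤ 0.005, |Δrepeat| ≤ 0.01 and the window overlaps
neither an enhancer nor a previously accepted control; the budget is
10,000 draws per control, after which the deficit is filled by
mononucleotide shuffles of the enhancer itself (case travels with its
letter, so both matched statistics are preserved exactly) flagged
`shuffled`. Controls never overlapping each other is an extra guarantee
(it keeps enrichment denominators free of double counting).

## deM scoring

A substitution is a candidate deactivating mutation iff at least one
covering 8-mer flips from `top` to `background`. Candidates are
described by two signatures per (k, track):

* Δₖⱼ = max over the k covering windows of (ref-window weight −
  alt-window weight), floored at 0. The floor keeps Δ a pure
  disruption measure.
* Sₖⱼ = sum of top-window weights fully inside ±100 bp of the variant,
  excluding windows covering the variant — exclusion keeps Δ and S
  non-redundant.

The classifier is a linear SVM; the regularization constant is chosen
from {0.01, 0.1, 1, 10} by mean out-of-fold ROC AUC over a stratified
5-fold split (seeded), refit on all data. A logistic (Platt) map is
fitted on the pooled out-of-fold margins and its slope/intercept are
folded into the weight vector, so the reported score is exactly the
logistic of the (rescaled) margin and the margin still partitions
exactly as WS(Δ) + WS(S) + b. The deM threshold is the smallest observed
score t with P(negative ≥ t) ≤ FPR (default 0.01), computed on 2,000
freshly simulated negative-control variants (not the training
negatives); ties at the threshold count as deMs. A position is a deMP
iff at least one of its three candidate substitutions is a deM; deMP
density divides by the full enhancer length, including masked bases.

## Enhancer classes

Enhancers with ≥ 1 deMP are sorted by (density descending, id
ascending — deterministic tie-break); the top ⌊0.2 n⌋ are fragile, the
bottom ⌊0.2 n⌋ stable, and the ⌊0.2 n⌋ starting at offset ⌊0.4 n⌋
regular; the remainder stays unclassified. The partition depends only on
the density ranking.

## TFBS analysis

PSSMs are log₂-odds against a uniform background. Thresholds are
calibrated on neutral synthetic sequence of the configured GC so the
both-strand hit density is at most 5 per 10 kb (the smallest such score;
a matrix whose ties make the rate unattainable is rejected). Scanning
scores both strands at every unmasked position; overlapping hits are not
merged. Fold enrichment of a TF in an enhancer set over controls is
(n_e/L_e)/(n_c/L_c) with non-repetitive lengths L and a 0.5 continuity
guard on n_c only when it is zero. Homotypic clusters are maximal runs
of ≥ 3 same-TF hits spanning ≤ 1 kb (span = max end − min start);
heterotypic clusters require ≥ 3 distinct TFs in the window (the strict
reading; a lax ≥ 2-distinct variant would only relabel mixed windows),
so a homotypic window is never double-typed. Motif-relative deMP
profiles mirror the offset for minus-strand hits.

## Evolutionary and GWAS statistics

Divergence is (# diverged ∧ alignable)/(# alignable) over non-repeat
positions; SNP fraction is SNP positions over all positions; conserved
fraction is conserved-element coverage of non-repeat positions, compared
between groups with a two-sided Mann–Whitney test. Ortholog activity is
compared stable vs fragile by Fisher's exact test among enhancers with
orthologs. LD expansion adds partners with r² strictly above 0.8 within
500 kb, one round (no transitive chaining). Disease-type enrichment of
class A SNPs vs class B uses the hypergeometric upper tail with universe
A ∪ B, draws A, successes the disease's (LD-expanded) SNPs in the
universe; −log₁₀ p is reported in both directions. The universe choice
is a documented convention — it is the union of the two expanded class
sets, configurable by passing different sets.

## The synthetic world

The generator emulates the statistical structure the analysis must
recover, on one miniature chromosome (2 Mb by default, GC 0.41, 15%
repeat in runs of mean 300 bp placed outside enhancers so planted sites
are never masked):

* **Architectures.** Homotypic enhancers (default 100) plant 3–5 copies
  of one pioneer-like motif; heterotypic enhancers (100) plant one copy
  each of 3–5 distinct tissue-specific-like motifs. Enhancers are
  250–400 bp, non-overlapping, ≥ 500 bp apart. Motifs are 10 bp
  consensus strings with one controlled degenerate position (second-best
  base planted with probability 0.2) so vocabularies learn families
  rather than single strings; planting strand is random.
* **Tracks.** Two chromatin signals with gamma-Poisson
  (negative-binomial) counts per 20 bp bin: background mean 5,
  dispersion 0.3, 5× mean elevation over planted sites — overdispersed
  like ChIP-seq coverage, not Gaussian.
* **Labels.** "Deactivating" training variants disrupt a heterotypic
  (non-redundant) site; "neutral" variants are split between disruptions
  of homotypic (redundant, hence buffered) sites and off-site enhancer
  positions. This is the generative encoding of redundancy buffering: a
  linear classifier can only separate the two site-disruption types
  through the neighbourhood signature S, whose weight is larger around
  homotypic sites (same high-weight k-mers repeated nearby). Both label
  classes share the same simulated MAF distribution (Beta(0.5, 2)/2) and
  lie inside enhancers, so the matched covariates coincide exactly. The
  real negative-matching covariate (distance to nearest TSS) has no
  analog in a gene-free genome; distance to nearest enhancer stands in.
* **LD panel.** Blocks of 5 kb (scaled to the miniature genome so one
  block holds at most one enhancer) with constant r² = 0.9 within blocks
  and nothing across; 2 background SNPs per block plus 3 per enhancer.
  Disease types tag 40 SNPs each, drawn with probability 0.7 from a
  designated architecture's enhancers ("cancer" → homotypic,
  "metabolic" → heterotypic) or uniformly ("other").
* **Evolution.** Two-rate per-base substitution: 0.002 over planted
  sites and conserved elements, 0.01 elsewhere; iid alignability 0.9;
  SNPs at 0.001/0.005 with the same structure. Conserved elements cover
  whole enhancers with probability 0.6 (homotypic) vs 0.2 (heterotypic),
  which is what makes homotypic enhancers less diverged. Orthologs exist
  with probability 0.5; active with probability 0.7 (homotypic) vs 0.3
  (heterotypic).

All randomness flows from one master seed through a fixed
`SeedSequence.spawn` order (genome, tracks, variants, LD, evolution), so
identical configurations are byte-identical and adding one artifact
never perturbs another.

### What the synthetic world does not capture

Real enhancers have correlated base composition, nucleosome structure,
overlapping and degenerate motif grammars, population LD with decay and
admixture, and genes. Passing the recovery checks therefore shows the
*machinery* is correct — candidates, features, decomposition,
calibrations and statistics do what they claim under a known truth — not
that the fragile/stable biology would be recovered from any particular
real dataset. The printed real-data constants of the original analyses
(e.g. a specific score cutoff like 0.57156, or a specific top-k-mer
count) are data-bound and are deliberately not targets; the calibration
*procedures* that produced them are.

## Problem sizes and numerical choices

The default test suite runs worlds of 30–60 enhancers on 300–500 kb
genomes; the end-to-end recovery check uses 200 enhancers per
architecture on 2 Mb with 500+500 training variants, and the
control-matching check uses 200 enhancers on 5 Mb — sizes chosen so the
full suite completes in about two minutes on one core while every
statistical assertion retains comfortable power. FPR calibration uses
the explicit order-statistic rule (smallest observed score meeting the
bound; one past the maximum if no score qualifies); PSSM calibration
uses the analogous rule on unique score levels. PSSM probability models
vary information content across positions — with position-uniform
matrices the background score distribution is too coarse for a 5/10 kb
target to be attainable. Decomposition additivity is asserted at 10⁻⁹;
determinism is asserted by SHA-256 digests of the written reports.

## Known limitations

* Candidate detection is gated at k = 8 (pooled vocabulary) only;
  substitutions that disrupt binding without a top→background 8-mer flip
  are non-deMs by definition.
* The heterotypic cluster rule is the strict (≥ 3 distinct TFs) reading;
  mixed windows with exactly two TFs are untyped.
* The GWAS universe convention (union of the two expanded class sets)
  is one defensible parameterization of the hypergeometric test; others
  (e.g. all panel SNPs) would shift absolute −log₁₀ p values.
* Weight tables from external eQTL-trained models can be loaded via
  `WeightSet.load_tsv`, but reproducing any particular published weight
  set requires that model's training data.
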