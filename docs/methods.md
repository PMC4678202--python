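# Methods

## Model

For trait $y$ (length $n$) and genes $g = 1,\dots,G$ with composite-
genotype factors $Z_g$ (levels $L_g$), the working model is the fixed-
effects general linear model

$$y_i = \mu + \sum_g \beta_{g,\,z_{gi}} + \varepsilon_i,\qquad
\varepsilon_i \sim \mathrm{iid}\ N(0, \sigma^2),$$

dummy-coded against each gene's reference level, so the model contributes
$p = \sum_g (L_g - 1)$ non-intercept columns (before alias removal).
Animals are treated as unrelated; no polygenic or pedigree term is fitted
and no multiple-testing correction is applied across traits — both are
properties of the procedure being reimplemented, not oversights.

Each gene is tested with a marginal (drop-one) F-test comparing the joint
model with and without the gene's columns on the alias-pruned column set.
Marginal rather than sequential tests make the per-gene P-values invariant
to gene ordering. Backward elimination removes one gene per iteration —
the one with the largest P, strictly above the threshold (default 0.05, so
P = 0.05 is retained); ties break by smaller F, then lexicographic name.
Elimination is therefore a deterministic function of its inputs.

## Composite genotypes

A gene's SNP set is every SNP within `window` bp (default 500,000,
inclusive at both ends) of the gene body on the same chromosome, ordered
by position. Window distance is measured from the gene's start/end
coordinates, the most inclusive plain reading; alternatives are one
parameter away. SNPs falling in two overlapping neighborhoods stay in both
sets — the GLM's aliasing handling, not an ad-hoc tie-break, resolves any
resulting collinearity, and every dropped column is reported.

Genotypes are recoded to minor-allele counts: the minor allele is the one
with sample frequency < 0.5; at exactly 0.5 the coded (alt) allele is
declared minor, making the recoding idempotent. Monomorphic SNPs are
flagged and kept as all-zero columns. Missing calls are imputed to the
SNP's modal count and flagged (policy `impute`, the default — it
preserves a balanced n across genes in the joint model); `drop` excludes
the animal instead.

Composite levels observed fewer than `min_level_count` times (default 5)
pool into a single `RARE` level. Unpooled singleton levels would let the
model fit noise exactly and destabilize the F-test denominator df; the
threshold is surfaced in every report. A gene with fewer than two levels
after pooling is non-informative and excluded (and reported as such).

## Numerical implementation

Fits run on the Gram matrix: because the design is an indicator matrix,
$X'X$ is a table of level co-occurrence counts assembled directly from the
per-gene level codes, and $X'y$ a set of per-level trait sums — both
computed once per (trait, encodings) context. Every submodel visited
during elimination is a Cholesky solve on an index subset; drop-one F
statistics use the general-linear-hypothesis identity
$\beta_B'[(X'X)^{-1}_{BB}]^{-1}\beta_B = \mathrm{RSS}_{-B} - \mathrm{RSS}$.
Rank deficiency is detected by a failed or small-pivot Cholesky
(relative pivot $10^{-6}$), which triggers a greedy first-come-first-kept
column selection (incremental Cholesky, tolerance $10^{-9}$): columns are
kept in design order, so later-listed genes lose aliased columns first.
A fully aliased gene reports df1 = 0, P = 1 and is freely removable.
A numerically perfect fit reports P at the smallest positive float rather
than 0. Equality of every fit with an explicit pseudo-inverse
normal-equations solver to 1e-8 is asserted in the test suite.

## Permutation null

Pseudo-gene loci are anchored at existing SNP positions (guaranteeing
non-empty sets at a rate resembling the panel's density) drawn uniformly
without replacement. Anchors keep a full window's margin from every
candidate neighborhood, so a pseudo-locus window can never reach into one
and collate true-candidate SNPs — a null contaminated by causal SNPs is
anticonservative (without the margin, a locus anchored just outside a
causal gene's neighborhood can match or exceed the observed variance
explained). The exclusion is toggleable and the margin a parameter. `n_loci` defaults to the number of candidate genes under
test, keeping each permutation structurally matched to the observed
analysis. Per permutation the full chain (collate → encode → eliminate)
runs per trait; loci are shared across traits within a permutation.
Permutations retaining zero loci record minimum P = 1.0 (least extreme)
and zero variance explained; a permutation failing outright is re-drawn
with the re-draw count reported. Tail probabilities use the
$(r+1)/(B+1)$ estimator, which never returns zero and is honest at
$B = 1000$. The whole null is a deterministic function of (seed, B).

## qPCR module

Relative quantification is efficiency-corrected ΔCt:
ratio $= E^{\overline{C_t}_{\mathrm{ref}} - \overline{C_t}_{\mathrm{tgt}}}$
with replicate-mean Cts per cow × stage cell and default $E = 2$ (perfect
doubling); $E$ is a parameter, the standard-curve alternative is out of
scope. The ANOVA operates on the per-cell replicate-mean ratios — a
balanced cows × 3-stage layout — as a two-way additive model
(stage + cow block, no interaction), df $(2,\ 2(b-1))$; replicate-level
nesting is not modelled. Ratios are analysed untransformed by default,
with an optional log transform (ratio data are often log-analysed; the
flag exists for that reason). Pairwise stage comparisons use protected
Fisher LSD: no pair is tested unless the overall stage F-test is
significant at α; then
$\mathrm{LSD} = t_{1-\alpha/2,\,\mathrm{df_{resid}}}\sqrt{2\,\mathrm{MSE}/b}$.
An all-constant table reports F = 0, P = 1. The statsmodels OLS/ANOVA
machinery computes the decomposition; the test suite checks it against
the textbook sums-of-squares formulas.

## Synthetic data generator

The generator emulates the targeted-design study conditions: 1,546
animals; 29 candidate genes (8 SOCS-family + 21 JAK-STAT pathway names)
placed without neighborhood overlap on a 5 × 100 Mb genome; Poisson(3.4,
min 1) SNPs per ±500 kb neighborhood (≈ 98 candidate SNPs); 2,000
background SNPs outside candidate neighborhoods as material for the
random-locus null; MAF uniform on (0.05, 0.45); Hardy-Weinberg and, by
default, linkage-equilibrium genotypes. An exchangeable within-block
correlation knob (`ld_rho`, Gaussian-copula haplotype draws) exists to
probe collinearity handling, since real 50k panels have LD. Missingness
defaults to 0, configurable to 10%.

Traits are sums of per-gene additive scores (per-SNP effects drawn once
per seed per gene, signs symmetric — real combination effects go both
ways) plus Gaussian noise. Components are rescaled empirically and the
noise residualized against the causal scores, so each gene's realized
variance fraction matches its configured value essentially exactly and
the residual variance is exactly `residual_sd`² — this makes recovery
tests tight at desk scale. A trait column is a pure function of
(seed, causal configuration): traits configured identically are identical
by construction, so distinct traits should be given distinct causal maps.

The Ct generator produces a balanced cow × stage × triplicate design:
reference and target genes share a fixed baseline Ct, stage effects enter
as log2 offsets (so +1 doubles the normalized ratio), cow effects (sd
`cow_sd`, default 0 so the null is exact) shift target genes only, and
replicates differ only by measurement noise.

What the generator does **not** emulate: real bovine chromosome lengths
or SNP-chip ascertainment, pedigree/relatedness among sires (breeding
values are treated as independent observations, and whether deregression
would be appropriate is a question about real data the generator does not
answer), selection-induced allele-frequency structure, and amplification-
curve artefacts in qPCR. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the stated
model, not robustness to those real-data features.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the suite fast while
preserving the quantity under test: oracle-equivalence fits use n ≤ 200
with ≤ 4 genes (50 instances); F-test calibration uses 5,000 null
simulations at n = 200; causal-gene recovery and null retention run the
full 1,546-animal, 29-gene design (200 and 100 pipelines); permutation
calibration uses 100 replicate seeds at n = 500 with 8 candidate genes
and B = 200 (coverage of a central band is scale-free), while the
permutation power check runs 50 replicates at n = 1,546 over the 8-gene
subset with B = 200; qPCR detection uses 200 seeds (+2 log2 offset,
noise 0.3 cycles) and 500 null seeds for the uniformity check. The
acceptance script mirrors these conditions at B = 200 and 50 recovery
pipelines.

## Known limitations

- The composite-genotype factor fragments an additive signal across many
  levels (and pools part of it into `RARE`), so power per variance
  fraction is below that of an additive dosage model — a property of the
  method itself. The effect grows sharply with the SNP-set size: a gene
  drawing 7+ SNPs spreads a 10% variance fraction over so many (mostly
  rare) composite classes that its fitted factor may explain only a few
  percent, and in the extreme the gene can fail retention altogether.
  The permutation power check exhibits exactly this: replicates whose
  causal gene drew a large SNP set are the ones whose observed adjusted
  R² is not extreme against the random-locus null.
- Backward elimination inherits the usual stepwise-selection biases:
  retained-model R² is selection-inflated, which is precisely why the
  random-locus null re-runs the whole selection per permutation.
- With heavy neighborhood overlap, per-gene attribution is ambiguous;
  the pipeline reports aliasing rather than resolving it.
- The permutation null resamples loci, not phenotypes; it calibrates
  "how unusual are these candidate loci" and nothing else.
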