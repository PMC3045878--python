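# Methods

This note records the models behind `aiscreen`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions that matter for reproducing printed summary tables.

## Allelic-imbalance model

A heterozygous patient contributes four peak heights (two alleles × tumour /
normal).  The statistic is the ratio of allele ratios with the risk allele in
the numerator.  The normalisation by the normal-tissue ratio is what makes
the statistic usable on chromatogram peak heights at all: allele-specific
amplification or dye bias multiplies one allele's peaks by the same factor in
both tissues and cancels exactly (this invariance is property-tested).

*Classification.*  Thresholds (0.6, 1.67), strict inequalities, values at a
threshold balanced.  Ratio < 0.6 is loss of the **risk** allele, > 1.67 loss
of the **neutral** allele — this direction assignment is the reason the
numerator convention is fixed to the risk allele.  Note 1.67 ≠ 1/0.6 =
1.6667: the default pair is *not* exactly symmetric under allele relabelling,
so ratios in (1.6667, 1.67] classify differently than their reciprocals.  A
`reciprocal=True` mode uses (0.6, 1/0.6), which is exactly swap-antisymmetric
and is the mode the symmetry property test runs in.  The default remains the
conventional printed pair.

*Direction test.*  Two-sided exact binomial at p₀ = 1/2 on (losses of the
rarer direction, total imbalanced).  Two-sided P is the minimum-likelihood
sum — all outcomes whose point mass does not exceed that of the observed
count — which for p₀ = 1/2 equals doubling the smaller tail, capped at 1,
and returns exactly 1 for a maximally central observation.  Zero imbalanced
tumours yields P = 1 with an explicit `no_imbalance` flag rather than a test.

*Two-stage screen.*  The first `stage1_n` (default 90) evaluable pairs are
tested; the locus is extended to all pairs when the stage-1 P falls below
`trend_p`.  What counts as "a trend" is a design decision, not a statistical
constant, so `trend_p` has no default and the decision taken is recorded in
the output.  `trend_p ≥ 1` is the degenerate always-extend setting.

*Records.*  A record is evaluable only with four strictly positive heights
and two distinct alleles.  Zero/missing heights are excluded from
`n_informative` and logged; negative heights are rejected at load time as
physically impossible.  Homozygous rows are rejected at load time.

*Clinicopathology.*  Loss-of-risk vs loss-of-neutral tumours are compared
across Duke's stage (A–D) and histological grade (1–3) with a two-sided
Fisher exact test; the 2×K case is computed by full conditional enumeration
(exact, feasible at these table sizes), the 2×2 case coincides with the
hypergeometric test.

## Association model

Strictly biallelic, allele-level 2×2 tables, complete-case per SNP (missing
genotypes code "0" and drop only that sample at that SNP, so n varies by
SNP).  Repeat-length polymorphisms must be collapsed to two length classes
upstream; a third allele is an error, not a warning.

*Odds ratio orientation.*  The reported OR is for the case-enriched allele,
hence ≥ 1 regardless of whether the case MAF is above or below the control
MAF; relabelling alleles or swapping which allele is "minor" never changes
the reported value.  When the allele of interest is fixed a priori (e.g.
coverage studies of a known risk allele) `orient=False` keeps allele1 in the
numerator.

*Confidence interval.*  Woolf (logit): exp(ln OR ± z·SE), SE =
√(1/a+1/b+1/c+1/d).  Chosen because it is the standard closed-form interval
for allele-count tables and reproduces printed 2-decimal CIs from counts
reconstructed off published MAFs.  Zero cells raise a targeted error
directing the caller to the Haldane–Anscombe +0.5 correction (`continuity=
True`, flagged in results) rather than silently correcting.

*P-value.*  1-df Pearson chi-squared on the allele table, **no** continuity
correction by default (the convention that matches printed allelic-test
P-values); Yates' correction is available behind a flag.  An expected cell
below 1 logs a warning but still returns the statistic.

*Count reconstruction.*  Published tables print MAF to 3 decimals and n;
counts are rebuilt as round-half-away-from-zero(MAF·2n).  This inversion is
reliable for common alleles but not for MAFs of order 0.01, where 3-decimal
rounding spans several counts — such rows cannot be reproduced from
frequencies alone and are deliberately not asserted anywhere.

*Multiplicity.*  Bonferroni, min(1, m·p), with m supplied by the caller.

## Enhancer screen

Coordinates are 1-based inclusive in memory and in region TSVs, matching how
genomic blocks are quoted in print; BED (0-based half-open) is converted at
the IO boundary and round-trip tested.  LD regions are applied exactly as
given: a variant even 2 bp outside a printed block is excluded and surfaced
in the log, never absorbed by widening.  Element filtering is score ≥ 300
(cutoff inclusive).  A binding site must be contained in some element of the
input universe (otherwise configuration error); its variants are candidates
only when the parent element passes the filter.  One candidate row per
variant with nested annotations per overlapping site.

Alleles are stored on the + strand.  For minus-strand sites the footprint
sequence (with the allele substituted) is reverse-complemented before
matching, so callers never complement alleles themselves.  Disruption =
exactly one allele compatible (IUPAC consensus, or PWM log-odds above the
site threshold when matrices are supplied).  Whether a screen should demand
disruptiveness or mere footprint overlap is application-dependent, so both
statuses are reported and the candidate list is defined by footprint overlap.

The PWM scanner uses log₂((counts + 0.8·bg)/(total + 0.8)/bg) — the common
background-split-pseudocount convention (0.8, uniform background, both
configurable) — over both strands, reporting minus-strand hits in forward
coordinates.  It is a self-contained site predictor for fixtures and
re-screening; element *scores* are consumed as input from whatever upstream
enhancer-prediction tool produced them, and no attempt is made to recompute
them.  The JASPAR PFM parser accepts labelled (bracketed or plain) and
unlabelled four-row dialects, normalises row order to A,C,G,T, and reports
parse errors with line numbers; it is cross-checked against an independent
parser in the tests.

## Synthetic-data generator

The generator is the package's test substrate and defines its study
conditions; its defaults are fixed, not tuning knobs.

*Peak heights.*  Normal tissue is exactly diploid heterozygous.  The tumour
sample mixes tumour cells at fraction ρ (purity) carrying (c_risk,
c_neutral) allele copies with normal cells carrying (1, 1); the expected
allele dosage is ρ·c + (1−ρ), giving a noise-free AI ratio of
(ρ·c_risk + 1 − ρ)/(ρ·c_neutral + 1 − ρ).  Each of the four peaks gets
independent multiplicative lognormal noise with unit mean and CV
`noise_cv` — peaks are positive and error scales with magnitude, which is
how fluorescence measurements behave.  Purity is truncated-normal (mean
0.75, sd 0.10, clipped to [0, 1]); a quota then raises the smallest drawn
purities to 0.70 until at least `carcinoma_min_fraction` (default 0.64) of
tumours have ≥ 70% carcinoma content, mirroring the way pathology review of
such cohorts is reported without committing to a distribution.  The purity
distribution itself is a modelling choice of this package; only the
≥70%-in-64% constraint is externally given.  Defaults: 90 pairs (a typical
first-stage cohort), noise_cv 0.15, baseline 1000 fluorescence units
(arbitrary; cancels in the ratio).  An optional per-SNP amplification-bias
factor multiplies the risk-allele peaks in both tissues and must cancel in
the AI ratio (tested).

*What it does not emulate:* subclonal tumour mixtures (one clone per
sample — the ratio statistic cannot resolve subclones anyway), chromatogram
base-calling artefacts, saturation, or inter-run gain differences beyond the
lognormal term.  Passing tests therefore validate the statistics under a
clean mixture model, not the chemistry of any particular sequencer.

*Genotypes.*  Controls Hardy–Weinberg at frequency f; cases Hardy–Weinberg
at the frequency implied by the allelic OR: p_case = OR·f/(1−f) / (1 +
OR·f/(1−f)).  Monomorphic specs (f ∈ {0, 1}) are allowed only with OR = 1.
Defaults (913 cases / 821 controls, f = 0.431, OR = 1.13) are a typical
low-penetrance locus configuration.  No linkage disequilibrium between
simulated SNPs and no population structure are modelled.

*Screen fixtures.*  Slot layout with one element + one planted motif
instance + one variant per slot, in three labelled strata: 13 variants in
sites of high-scoring elements (scores in [300, 450], the first pinned at
exactly 300 to exercise the inclusive cutoff, with one variant designated as
previously genotyped for exclusion — leaving 12 candidates), 3 in sites of
low-scoring elements ([150, 300)), 4 inside elements but outside sites.
Planted alleles are the reference base plus a base outside the pattern
symbol's degeneracy set where one exists, so disruption annotation has
ground truth.

*Seeding.*  One master seed; each generator draws from its own
deterministically derived stream, so outputs are reproducible individually
and regardless of call order.  Two runs with the same seed produce
byte-identical tables.

## Numerical and display conventions

* Display: P-values, ORs and CI bounds at 2 decimals; AI ratios at 4;
  imbalance fractions as integer percent; all display rounding is
  half-away-from-zero (matching hand-rounding of printed tables, not
  banker's rounding).  Full precision lives in the JSON sidecars.
* Exact-test tie handling: outcome masses within a 1e-7 relative tolerance
  of the observed mass count as ties (guards against floating-point
  near-equality in the minimum-likelihood sums).
* Determinism: TSV/JSON writers fix column order and preserve input row
  order; manifests contain no timestamps, so identical runs are
  byte-identical.

## Validation strategy and problem sizes

Unit tests pin every statistic to independent oracles: exhaustive
enumeration for the binomial (n ≤ 12) and Fisher tests, algebraically
distinct chi-squared forms, external library routes for chi-squared/Woolf
CI/PWM scoring, and brute-force triple-loop intersection for the screen.
Replicated-simulation checks use 200 cohorts of 90 pairs for the direction
test's power and null behaviour and 500 case-control panels for Woolf CI
coverage — sizes chosen to bound the Monte-Carlo SE of the estimated rates
at a few percent while keeping the default suite quick to run.

Known limitation worth stating: at ~90 informative pairs and ~9–10%
imbalance, the exact binomial direction test runs on ≤ ~15 imbalanced
tumours and is markedly conservative (attainable size well below the nominal
5%, alternating with m's parity).  The null-calibration test therefore
checks super-uniformity and agreement with the analytically computed
attainable size of the discrete test, rather than expecting the rejection
rate to sit exactly at 5%.
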