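# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind the package, and what the synthetic-data generator does
and does not emulate.

## Exact tests and their conventions

All frequency comparisons are conditional exact tests on 2×2 tables with
rows = cohorts and columns = (mutated, wild type). Under the null of equal
frequencies, the upper-left cell a follows the central hypergeometric law on
[max(0, m−n₂), min(m, n₁)] given margins (n₁, n₂, m).

- **Two-sided rule.** The probability-mass convention: P = Σ of point
  probabilities not exceeding the observed one, with a relative tie
  tolerance of 1e-7. This is the convention of R's `fisher.test` and
  `scipy.stats.fisher_exact`, and the implementation is cross-checked
  against both an exact integer-arithmetic enumeration oracle (exhaustively,
  for all margins with n₁+n₂ ≤ 60) and scipy. Note that for identical
  proportions the two-sided P is exactly 1 while one-sided tails are
  (1 + P(X=a))/2 — both are asserted in tests.
- **Odds ratio.** The unconditional sample estimate (a·d)/(b·c), not the
  conditional MLE; zero cells give 0 or infinity (nan when both products
  vanish). This matches the coarse printed values this kind of study
  reports (OR ≈ 0.2, OR ≈ 2) and is documented in `TestResult`.
- **r×c tables.** Monte Carlo over fixed-margin tables sampled with
  Patefield's algorithm (`scipy.stats.random_table`); the estimator
  P = (1 + hits)/(iterations + 1) is add-one so P > 0; the Monte Carlo SE
  is reported. Default 10⁶ iterations. An exhaustive enumeration oracle
  exists for tiny tables and bounds the MC error in tests.
- **Stratified combined test.** Exact conditional (CMH-type): under a
  common null odds ratio of 1, the total group-1 success count S is the
  convolution of per-stratum central hypergeometric pmfs. Strata with any
  zero row or column margin carry no information under conditioning and are
  dropped (logged). One-sided P values are tails of the convolved law; the
  two-sided P uses the same probability-mass rule as the 2×2 test, chosen
  for internal consistency since the literature admits several conventions.
- **Rank-sum.** Exact enumeration when the smaller sample has ≤ 8
  observations and no ties; tie-corrected normal approximation otherwise.
  The study-scale comparison (n = 21 vs 554) is always in approximation
  territory.
- **Frequency uncertainty.** A frequency k/n is reported with the standard
  deviation of Beta(k+1, n−k+1) — the posterior under a uniform prior —
  in closed form √(ab/((a+b)²(a+b+1))).

## The power gate

The minimal achievable (optimal) Fisher P over all tables with the observed
margins is computed by evaluating the P value of every allocation at once
(sorting the pmf vector and prefix-summing, O(s log s) per margin). The
total mutated margin m is taken from the observed combined cohorts, per
gene; scanning m as well would answer a different question (the margins are
part of the observed design). The Bonferroni divisor is an input (49 for a
two-sided driver screen, 30 for a one-sided reduced-frequency screen in the
motivating design) because it comes from an upstream significance analysis
that is out of scope here. The gate is applied strictly before testing:
unpowered genes receive no P or Q value at all, which prevents reading an
uninformative comparison as a negative result.

`min_detectable_count(n₁, n₂, α)` scans m upward over the extreme table
[[0, n₁], [m, n₂−m]]; the one-sided tail P(a ≤ 0) = C(n₂,m)/C(n₁+n₂,m) is
nonincreasing in m, so the first crossing of α is well defined. At the
study margins (21 vs 554, α = 0.05) the scan returns 76. A generalisation
to a nonzero observed exposed count is available but off by default.

## Molecular subtyping

Cascade order is fixed: POLE, else MSI, else CIN/GS.

- **POLE** requires both a nonsynonymous *POLE* mutation in the exonuclease
  domain (protein positions 268–471, the standard domain definition) and
  summed POLE-signature exposure fraction (SBS10a, SBS10b, SBS14) at or
  above `signature_fraction_threshold`.
- **MSI** defers to an upstream MSI call when the annotation carries one
  (read-level MSI scoring is out of scope); otherwise the summed
  MSI-signature fraction (SBS6, SBS14, SBS15, SBS20, SBS21, SBS26, SBS44)
  decides. An explicit negative upstream call wins over signatures.
- **CIN vs GS**: fraction of the covered genome in segments with copy-ratio
  change ≤ −R₁·purity, compared against R₂. Defaults R₁ = 0.36 and
  R₂ = 0.034 (copy-ratio units and genome fraction respectively).

Open design points resolved here, switchable by `SubtypeParams`:

- *Purity normalization direction*: the effective amplitude threshold is
  R₁ × purity. A clonal deletion's apparent copy-ratio change shrinks
  proportionally with purity, so the detection threshold must shrink too;
  the divisive reading is available via `purity_scales_threshold=False`.
- *Deletions only*: the fraction counts signed deletions
  (seg_value ≤ −threshold), boundary inclusive, not |change|.
- *Signature evidence threshold*: 0.2 by default. No published value
  exists for this cutoff; 0.2 is low enough that a genuine POLE/MSI
  process (which typically dominates the spectrum) always passes and high
  enough that fitting noise does not. It is reported in every output row.

Signature exposures come from nonnegative least squares against a fixed
96-channel catalog — deterministic and exactly recovering any spectrum in
the catalog's nonnegative cone (residual < 1e-9 in tests), which is all the
cascade's presence/absence decisions require. Bayesian NMF de novo
discovery is deliberately out of scope. Exposure *fractions* are normalized
by the total SNV count, so they sum to ≤ 1. SBS96 channels use the
pyrimidine-strand convention in the standard order (six substitution types
× 16 trinucleotide flanks); purine-reference records are reverse
complemented, non-SNVs and records without context are skipped with a
logged count, and a context contradicting the reference allele is an error.

## Clonality and timing

A mutation is clonal iff CCF ≥ 0.95 (inclusive — asserted exactly at the
boundary). In WGD tumors, multiplicity ≥ 2 places a clonal mutation before
the doubling, multiplicity 1 after; non-WGD samples and mutations without
multiplicity are `not_applicable`. This multiplicity rule is a deliberate
simplification of probabilistic event-ordering frameworks.

"Early events per sample" are counted at gene level (a driver gene with ≥ 1
clonal nonsynonymous mutation = one event), the reading consistent with
small-integer per-sample counts; mutation-level counting is available via
`ClonalityParams(gene_level=False)`. The early-driver gene list is an input;
no attempt is made to re-derive it from timing models. The cohort
comparison reports medians, a two-sided rank-sum P, the same comparison
with the exposed counts shifted by +1 (asking whether the deficit exceeds
one event), and a density-histogram table with Beta-distribution SDs.

## Summaries

Burden = mutations / territory (default 37 Mb exome territory), counted
*before* the nonsynonymous filter by default since burden precedes driver
filtering; both conventions are reproducible because the filter is an
explicit separate stage. ddPCR allele fraction is
mutant/(mutant+wild-type)×100 with a strict >2% positivity cutoff (2.0%
exactly is negative). Expected background cases =
n × baseline_risk/treated_risk with defaults 0.5%/2.5% (a fivefold
absolute-risk increase over ten years): 21 × 0.2 = 4.2 ≈ 4.

## The synthetic-data generator

`SimConfig` defaults are the study conditions: 21 exposed vs 554 control
samples; *PIK3CA* at 14% vs 48% and *PIK3R1* at 0% vs 31%; subtype mix
(POLE 7%, MSI 28%, CIN 26%, GS 39%) matching the TCGA uterine-carcinoma
distribution in both cohorts; purity uniform on (0.3, 0.9); deleted-genome
fractions of 6–40% for CIN and ≤ 2% otherwise; burden 2.3 mutations/Mb
scaled ×10 for POLE and ×4 for MSI samples; WGD probability 0.25; 79% of
*PIK3CA*-mutated samples carrying a hotspot (E542K/E545K/H1047R), the ratio
implied by the published hotspot versus overall frequencies. Frequencies
for the remaining drivers (*PTEN*, *TP53*, *ARID1A*, *KRAS*, *CTNNB1*) have
no printed per-cohort values and were fixed once at typical de novo UC
levels with no exposed/control difference beyond sampling noise.

Per-sample gene indicators are independent Bernoulli draws; strata, purity,
subtype, segments, CCFs, multiplicities and trinucleotide contexts (drawn
from the sample's subtype signature mixture) all flow through one seeded
generator, so identical configs give byte-identical written fixtures.
Planted-clonal CCFs are clipped into the [0.95, 1] band: the generator
plants *clonal* mutations, so their CCFs satisfy the clonal rule by
construction and planted clonal/subclonal splits are recovered exactly;
untruncated Gaussian noise would leak ~1% of clonal draws across the
boundary and make "planted" counts ill-defined.

The bundled signature catalog is **synthetic** (seeded sparse-Dirichlet
columns over the 13 expected signature names); real COSMIC v3 profiles are
an input file in real analyses. Synthetic columns are mutually
distinguishable, which suffices for NNLS-based presence/absence decisions,
but exposure estimates on real tumors require the real catalog.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: sequencing artifacts and caller error, germline
contamination, per-gene mutation-rate/territory variation (frequencies are
specified directly), linkage between drivers (independent Bernoulli unless
a co-occurrence odds ratio is configured), subclonal population structure
beyond a two-component CCF mixture, and real signature profiles.

## Numerical choices and problem sizes

Fisher P vectors are computed from `scipy.stats.hypergeom` pmfs with a
1e-7 relative tie tolerance; the test-suite oracle re-derives them in exact
integer arithmetic (weights C(n₁,a)·C(n₂,m−a), ties decided on integers).
The exhaustive agreement sweep covers every margin with n₁+n₂ ≤ 60
(73,750 margins). Calibration checks use 2,000 simulated null tables at
the study margins; simulation-based property tests (frequency recovery,
exclusivity recovery, early-event power) use 25–100 seeds at reduced cohort
sizes chosen so each property is decided by construction or by wide
binomial margins rather than by a marginal threshold.

## Known limitations

- The stratified test's two-sided convention is one of several defensible
  choices; combined P values from other software may differ in the third
  decimal.
- Hotspot matching is by protein-change string only; indels or alternative
  annotations of the same codon are not unified.
- The WGD timing rule ignores copy-number context beyond multiplicity.
- `binarize` is per-record Python; cohorts far beyond 10⁵ mutations would
  benefit from a vectorised path.
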