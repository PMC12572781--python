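# Methods

`nuptkit` analyzes nuclear sequences of plastid origin (NUPTs): nuclear
genome segments that descend from insertions of plastid (chloroplast) DNA.
The pipeline consumes plastid-vs-nuclear local alignment hits and nuclear
annotations, and answers three questions: *when* did NUPTs arise
(continuously or in episodic bursts), *where* on the plastid genome do they
come from (donor hotspots and coldspots), and *where* in the nuclear genome
do they land (association with transposable elements, RNA genes and
structural genes).

## NUPT calling and inverted-repeat redundancy

Every 12-column tabular alignment hit (query = plastid, subject = nuclear)
is one candidate NUPT; overlapping or nested hits on the nuclear genome are
all retained, and no merging is performed. Because the two inverted repeats
(IRa/IRb) of a quadripartite plastid genome are sequence-identical, a NUPT
whose donor lies in an IR produces two hits, one per IR copy. A hit is
treated as IR-resident when at least 50% of its plastid interval falls
inside an IR; IR-resident hits at the same nuclear locus (same chromosome,
reciprocal overlap ≥ 0.9 — exact coordinate equality would be brittle to
1-bp alignment jitter) are paired across IR sides and one member of each
pair is kept by a seeded uniform draw. The operation is idempotent, never
removes a non-IR hit, and changing the seed changes only which IR copy's
plastid coordinates are recorded — never the count, nuclear coordinates,
sizes or ages.

IRs are located by a maximal exact reverse-complement repeat search
(k-mer-anchored, left-maximal extension) with a minimum length of 1,000 bp;
near-identical IRs with isolated mismatches are out of scope. The longest
single-copy segment is labeled LSC and the other SSC. Genomes without a
qualifying repeat pair are treated as non-quadripartite and skip
deduplication, with a logged notice.

## Relative ages: p-distance and JC69

A NUPT's observed divergence from its donor is the p-distance
p = mismatch/length from its alignment row. Gap columns are absent from the
numerator but counted in the denominator — the only definition computable
from standard 12-column output — so p underestimates divergence by at most
the gap fraction. Multiple hits per site are corrected with the
one-parameter Jukes–Cantor model,

    K = -(3/4) ln(1 - (4/3) p),   valid for p < 0.75,

and K serves as the relative age. The inverse map
p = (3/4)(1 - exp(-4K/3)) drives the simulator; the round trip is exact to
machine precision and is asserted to 1e-12 in the acceptance suite.

## Age-distribution models and selection

Four univariate models are fitted to the K distribution:

| model    | density                                   | free parameters |
|----------|-------------------------------------------|-----------------|
| EXP      | λ e^{-λk}                                  | 1 |
| GAUSS1   | N(μ, σ²)                                   | 2 |
| GAUSS2   | w N(μ₁, σ₁²) + (1-w) N(μ₂, σ₂²)            | 5 |
| EXPGAUSS | w Exp(λ) + (1-w) N(μ, σ²)                  | 4 |

EXP and GAUSS1 have closed-form maximum-likelihood estimates (λ = 1/mean;
sample mean and biased-ML variance). GAUSS2 and EXPGAUSS are fitted by EM:
responsibilities from the current weighted densities, then w = mean
responsibility, λ = Σr/Σ(rk), μ and σ² the responsibility-weighted mean and
variance. Convergence is declared at a relative log-likelihood change
< 1e-8 or after 1,000 iterations. The log-likelihood trajectory is recorded
and guarded at run time: any decrease beyond numerical noise raises, so
EM monotonicity is enforced for every fit everywhere.

Numerical choices: σ is floored at 1e-4 to prevent likelihood spikes on
repeated values; Gaussian components are untruncated despite K ≥ 0
(mirroring the Ks-plot mixture methodology), and the probability mass each
Gaussian places below zero is reported as a diagnostic; EM starts are
randomized per replicate (w ~ U(0.2, 0.8), Gaussian means at random data
quantiles in [0.1, 0.9], σ = sd/2, λ = 1/mean).

Selection runs 15 replicates (seeds derived as master seed + replicate
index), fits all four models in each, and takes the lowest
BIC = ν ln n − 2 lnL per replicate (ties toward fewer parameters); the
modal best across replicates is reported. Component memberships come from
the posterior w_c f_c(k) / Σ w_c' f_c'(k); the episodic contribution is the
Gaussian component's share.

The modeling surface is statsmodels-style: `NuptAgeModel(ages)` with
`.fit(kind, seed)` and `.select(n_replicates, seed)` returning results
objects that carry parameters, BIC, posteriors and a `summary()`.

## Donor hotspots and coldspots

NUPT donor coverage is counted per plastid bp (coverage of donor intervals,
not interval starts — start counting would ignore NUPT length), by default
after IR deduplication. Hotspots are positions with coverage strictly above
Q3 + 1.5·IQR, with quartiles taken by linear interpolation between order
statistics (the common statistical default; the convention is otherwise
unspecified). The strict inequality means a constant track flags nothing.
Coldspots are positions with zero coverage. Fractions are set sizes over
plastid length; across species, the hotspot/coldspot fraction can be
correlated with the nuclear plastid-DNA fraction by Kendall's tau-b and
Spearman's rho (tie-corrected, two-sided; significance at 0.05 with no
multiple-testing correction by default, Benjamini–Hochberg optional).

## Spatial association tests

All interval bookkeeping merges overlapping intervals within a set before
bp counting (union semantics), so nested annotations are not
double-counted. Promoter and terminator are the 1-kb sequences immediately
adjacent to the first and last exon of the longest isoform (greatest summed
exon length; ties to the lexicographically lowest ID), strand-aware and
clipped at chromosome ends; they may overlap neighboring genes (no
masking).

* **Expected-overlap test.** Observed overlapping bp vs the expectation
  proportional to the genome fraction the feature occupies,
  E = NUPT_bp × feature_bp / genome_bp, judged by Pearson's chi-squared
  with Yates continuity correction on the 2×2 bp table
  {NUPT, non-NUPT} × {feature, non-feature}. Treating bp as independent
  draws is exact only in the limit of very short intervals; with
  interval-scale features the statistic overstates significance, so its
  calibration is verified in the 1-bp regime at expected counts large
  enough (~125) that the continuity correction is negligible. Degenerate
  inputs (zero-bp track) yield direction "none" and p = 1 with a flag,
  not an exception.
* **Jaccard permutation test.** J = intersection_bp/union_bp pooled over
  chromosomes. The null shuffles NUPTs per chromosome while preserving
  their lengths and the multiset of inter-interval spacings (both flanking
  gaps included); p-values are two-sided, centered on the null mean,
  (1 + #extreme)/(n_perm + 1). 1,000 permutations by default.
* **Relative distance test (RDT).** Features and NUPTs are reduced to
  their centers. For each NUPT center x with flanking feature centers
  a ≤ x ≤ b, d = min(x−a, b−x)/(b−a) ∈ [0, 0.5]; centers outside the
  feature span are dropped and counted (linear chromosomes, no wrapping).
  Under independence d is uniform with mean 0.25; the signed measure
  C = (0.25 − mean(d))/0.25 is positive when NUPTs sit closer to features
  than expected. This concrete functional form (an area-deviation measure
  against the uniform null) and the two-sided permutation p-value are
  package choices exposed as options.

The suite driver runs all three tests per track at every hierarchy level
(TE class/order/superfamily, RNA class/subclass, gene parts) and reports
per-track degeneracies as flagged rows without aborting.

## The synthetic-data generator

The generator is first-class, tested code and defines the study conditions
for every verification:

* **Plastid genome** — 150 kb with 85 kb LSC and 25 kb IRs (typical
  angiosperm values); IRb is the exact reverse complement of IRa;
  ir_length 0 produces the non-quadripartite case.
* **Ages** — n_continuous draws from Exponential(λ = 20 per unit K; mean
  age 0.05) and n_episodic from Normal(μ = 0.2, σ = 0.02) truncated at 0
  by resampling (truncation affects generation only; the fitted Gaussians
  stay untruncated). Defaults: 500 + 500.
* **Sizes** — log-normal with log10 mean 2.5 and sd 0.4 (median ≈ 316 bp),
  a stand-in for the right-skewed size distributions of real catalogs; the
  family is a package choice, not a claim about real data.
* **Sequence divergence** — each inserted fragment is mutated site-wise
  with probability p(K) under JC69; hit rows are emitted directly from the
  realized substitutions as gap-free alignments (pident consistent with
  the mutation count), removing the aligner dependency while keeping K
  estimation testable end to end.
* **Donor sites** — sampled from the non-redundant plastid representation
  (LSC + IRa + SSC; the IRs are identical, so truth donors are
  canonicalized to IRa). IRa-resident donors also emit the redundant
  IRb-coordinate row a real aligner would report. Optional hotspot bias
  multiplies the sampling weight of windows overlapping a chosen interval;
  coldspot intervals exclude donors entirely.
* **Nuclear placement** — insertions are non-overlapping and uniform over
  chromosomes (two 2-Mb chromosomes by default, a desk-scale stand-in for
  full assemblies), the simplest null consistent with the independence
  hypothesis of the spatial tests; uniform placement makes gap order
  exchangeable, which is exactly the null the spacing-preserving
  permutation conditions on.
* **Annotations** — TE, RNA and gene tracks written as GFF3 with
  class/order/superfamily (or class/subclass) attributes; genes carry an
  mRNA and 1–4 exons. A track's colocalization_prob places features within
  colocalization_distance of NUPTs (cycling over insertions, so prob 1
  with count ≥ #NUPTs covers every NUPT).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: indel accumulation and fragmentation of
NUPTs, nucleotide-composition amelioration beyond JC69 substitutions,
low-complexity (dust) alignment artifacts (masking is assumed applied
upstream), TE transposition mechanics, post-insertion segmental
duplications of NUPTs, and realistic genome/annotation scale. The
per-genome NUPT fraction in simulated data (~10% at the defaults) is far
above real values because chromosome lengths are scaled down while NUPT
counts are kept large enough for stable model fits.

## Verification sizes

The acceptance properties run at: n = 3000 ages for parameter recovery
(λ̂ ∈ [9.5, 10.5]; modal EXPGAUSS with μ̂ within ±0.02), 200 random tracks
≤ 10 kb against the brute-force IQR oracle plus a 10× donor-bias hotspot
recovered ≥ 80% by position, 500 tied datasets (n ≤ 50) against O(n²)
rank-statistic oracles, 1,000 simulations for Kendall type-I error, and
500 datasets per spatial test (n_perm = 200) for calibration at α = 0.05
within the 99% binomial band. These sizes are the package's chosen
verification conditions; the full-scale defaults (1,000 permutations, 15
replicates) remain the pipeline defaults.

## Known limitations

* p-distance from tabular output cannot separate gap columns; K is a
  slight underestimate for gapped alignments.
* The IR finder requires exact reverse-complement identity; diverged IRs
  fall back to the non-quadripartite path.
* The chi-squared overlap test inherits the bp-independence assumption of
  its 2×2 table; with long intervals its p-values are anti-conservative
  and the permutation tests should be preferred.
* GAUSS2 can absorb an exponential-like bulk into a narrow near-zero
  Gaussian; model identification between GAUSS2 and EXPGAUSS is reliable
  only when the burst is well separated from the bulk.
* A wrapping (origin-spanning) LSC cannot be represented as a single
  linear interval; such rotated genomes report IR coordinates only.
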