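# Methods

This note records the models, defaults and design decisions behind
`lochgen`, and what the synthetic test-bed does and does not establish.

## The synthetic metapopulation

`lochgen.sim` emulates a system of lake-locked salmonid populations arranged
in a region → Hydrometric Area (HA) → lake → (optional ecotype) hierarchy.

**Drift.** Each SNP draws an ancestral frequency p₀ ~ Uniform(0.05, 0.95).
At every hierarchy level with intensity F the child frequency is a
Balding–Nichols draw, Beta(p(1−F)/F, (1−p)(1−F)/F), composed top-down; the
composite differentiation between two populations separating k levels below
their common ancestor is ≈ 1 − Π(1−F_level) over the independent levels.
Frequencies are clipped to [0.001, 0.999] before genotype draws so loci never
fix and the MAF filter stays exercisable. Genotypes are Binomial(2, p): the
simulator assumes random mating within populations, free recombination and no
linkage — none of the haplotype structure of real RADseq data.

**Adaptive loci.** A configurable number of loci shift their lake frequency
on the logit scale by `gea_effect` × z, where z is the lake's standardised
value of the driving climate variable (annual mean temperature, itself a
linear function of latitude plus noise). Ecotypes within a lake share the
lake's adaptive shift (environment acts at lake level) while drifting apart
at neutral loci.

**Environment.** The 19 bioclim variables reproduce the block collinearity
of real WorldClim data: a temperature block (bio1/5/6/10/11 at |ρ| > 0.7), a
tight precipitation block (bio12 driving bio13/14/16–19), quarter-mean
temperatures (bio8, bio9) only moderately tied to the annual mean, and
quasi-independent seasonality measures. Greedy pruning at |ρ| ≥ 0.7
consequently retains ~11 of 23 variables — the realistic regime in which an
RDA has substantially fewer predictors than lakes. Bathymetry (max/mean
depth, surface area, littoral %, altitude, distance to sea) is lognormal /
uniform and identical across climate scenarios.

**Missingness and replicates.** Missingness is site-structured: ~30% of
sites are fully genotyped and the rest lose calls at a beta-distributed
per-site rate with the configured mean. This mirrors reduced-representation
data, where complete-case subsets remain non-trivial even with hundreds of
individuals (i.i.d. missingness would leave essentially no complete columns).
Technical replicates duplicate an individual and resample each called
genotype to one of the other two codes with probability `error_rate`
(default 0.026, a typical RADseq replicate-discordance magnitude), so the
planted per-genotype discordance equals the error rate exactly.

**Reference regime.** `reference_config` fixes the test-bed conditions used
throughout the heavier tests: 20 unimodal lake populations (2 regions × 5
HAs × 2 lakes), 10 individuals each, 2000 SNPs, drift
{region 0.02, HA 0.05, lake 0.15} (mean configured pairwise F_ST ≈ 0.20),
and 20 planted loci at `gea_effect = 4` — a deliberately large effect, about
four times the per-lake drift noise on the logit scale, so the screen's
recall is a property of the method rather than of the signal-to-noise draw.
At survey-strength per-lake drift (F ≈ 0.25) single-lake drift mimics
environmental association often enough that no loading screen can reliably
separate planted from neutral loci; that confounding is a real feature of
strongly drifted systems, and the default `SimConfig` (lake F = 0.25,
effect 2) keeps it for studying exactly that regime.

## QC cascade

Order: presence → MAF → max H_O → first SNP per locus → HWE → depth →
replicate mismatch. Conventions, where the usual verbal rules are ambiguous:

* presence uses ≥ `min_prop` (default 0.66) within **every** population and
  across all individuals pooled; it is applied literally to populations of
  any size.
* MAF and H_O pool allele/genotype counts over all individuals.
* depth bounds are inclusive ([10, 30] retained): "< 10× or > 30×" removes
  strict violations only.
* the HWE test is the exact conditional (SNP-HWE) construction, α = 0.001,
  with removal only when rejected in > 50% of the populations typed for the
  SNP; α and the rejection rule are configurable since verbal descriptions of
  this filter rarely pin them down.
* a replicate pair's discordance is discordant calls / sites called in both;
  the overall rate is the unweighted mean over pairs; SNPs discordant in
  more than one pair are removed, then one member of each pair is dropped,
  keeping the copy with more non-missing genotypes.
* the top-F_ST cut for building neutral subsets removes exactly
  ⌈q·S⌉ SNPs ranked by per-locus θ descending, ties broken by (chrom, pos).

Every filter is idempotent and the report chain telescopes; both are enforced
by tests.

## Estimators

* **Pairwise F_ST**: Weir–Cockerham (1984) θ, ratio of averages. A
  population enters a locus only with ≥ 2 called genotypes; loci monomorphic
  across the pair are skipped. Slightly negative estimates are legitimate.
  Note the estimator is a *sampling* estimator: two literally identical
  samples give θ ≈ −1/(2n̄ − 1)-scale values, not 0; independent samples from
  one population centre on 0.
* **β (population-specific F_ST)**: matching proportions averaged over loci
  before the ratio (the hierfstat `betas` convention). Undefined and raised
  as an error when all populations are fixed and identical.
* **H_E** is 2p(1−p) without small-sample correction; **π** carries the
  n/(n−1) correction — the same distinction the standard RADseq toolchains
  report. **F_IS** = 1 − H_O/H_E per site, averaged over sites with
  H_E > 0. Private alleles count SNPs where either allele segregates in the
  focal population and is absent among called genotypes everywhere else; a
  population with no calls at a SNP counts as "absent" there.
* **PCA** mean-imputes missing dosages per SNP, centres columns and uses the
  SVD; axis signs are fixed by making the largest-magnitude loading positive.
* **Neighbour joining** is Saitou–Nei on Prevosti distances (mean |Δp| over
  complete-case loci; Nei's 1972 distance available) — the distance is a
  documented choice, as tree-building toolchains rarely state theirs. A
  negative branch length is clamped to zero with the deficit moved to the
  adjacent branch of the joined pair, preserving the joined taxa's path
  length. Bootstrap resamples loci (columns), not individuals.
* **AMOVA** treats mean-imputed individuals as points in dosage space and
  partitions variance over the nested strata with Searle's
  expected-mean-square coefficients for unbalanced three-fold designs
  (algebraically the Excoffier squared-distance formulation). Components may
  be negative and are reported as-is; percents are components over their
  sum. Significance uses label permutation at the matching level.
* **F_ST clustering** (the admixture-model surrogate): connected components
  of the graph joining pairs with θ below a threshold (equivalently single
  linkage); negative estimates are clipped to 0, and a threshold of 0 leaves
  every population its own cluster.

## RDA screen

X is standardised (ddof = 0), Y centred; conditioning covariates Z
residualise both through least squares on [1, Z]. Rank-deficient predictor
sets are pruned greedily and reported. Axis significance permutes rows of
the (conditioned) predictor block freely, n_perm = 999 by default, with
marginal per-axis comparison of eigenvalues; p = (1 + hits)/(n_perm + 1).
Candidates are SNPs with |loading z-score| > 3 on any significant axis
(union; intersection available) — the field-standard loading screen. Each
candidate's strongest predictor maximises |cor(dosage, predictor)|.
Interval annotation reports a SNP at 1-based p against a 0-based half-open
feature [s, e) expanded by window w when s − w < p ≤ e + w, edges inclusive;
relative position is 0 inside the unexpanded feature.

## Turnover model and offset

A reimplementation of the gradient-forest idea, not a port: per SNP,
`n_trees` = 250 regression trees on bootstrap samples of lakes, unlimited
depth, minimum leaf 2, ⌈v/3⌉ predictors per split. Each split contributes
its impurity reduction at the threshold location; a SNP's profile is
normalised, weighted by its out-of-bag R² (non-positive R² contributes
nothing), binned into 50 equal-width bins per predictor over the observed
range and accumulated over SNPs into cumulative-importance step functions
(0 at the range minimum, non-decreasing). Transformation clamps values
outside the fitted range to the boundary; offsets are Euclidean distances in
transformed space and therefore satisfy the metric axioms exactly. The
low-variation filter drops SNPs whose minor-allele frequency takes ≤ 5
distinct values across populations, distinctness judged after rounding to
6 decimals (an equality rule needs a floating-point convention). One offset
per lake: ecotypes sharing a lake share its climate and hence its offset.

Because only the ensemble size of the original gradient-forest analysis is
ever stated, absolute offset magnitudes are not comparable to published
values; identities (zero under zero displacement, monotonicity in single-
variable displacement, rank agreement with planted shifts from a common
baseline) are what the tests pin down.

## Sensitivity scores and conservation units

Sensitivity bins are lower-inclusive (the verbal "10–30 m" means [10, 30)):
depth < 10 → 4, [10, 30) → 3, [30, 100) → 2, ≥ 100 → 1; area < 10 ha → 3,
[10, 30) → 2, ≥ 30 → 1; altitude < 10 m → 4, [10, 50) → 3, [50, 200) → 2,
≥ 200 → 1; composite = sum ∈ [3, 11].

Delineation merges populations by (i) great-circle lake distance < 20 km
**and** pairwise F_ST below a gene-flow threshold (default 0.05, the
magnitude seen between a refuge population and its source; proximity alone
never merges, since nearby but differentiated lakes are distinct units),
(ii) documented translocation links, (iii) documented shared-history groups.
Haversine distance stands in for river-network distance, which is not
available as data. Ecotype status, sole-HA status and the explicit links are
metadata inputs, not inferred — they come from prior literature in any real
application, and inference would conflate evidence layers. ESU elevation
applies when any member is ecotype-flagged or sole-HA; both criteria are
recorded when both hold. The engine is deterministic and order-independent.

The packaged delineation metadata reproduces the published classification of
the 58 Scottish populations using explicit links only (no F_ST matrix ships
with the package, so the proximity rule is inactive there).

## Problem sizes and test design

The test-bed runs at 20 populations × 2000 SNPs (reference simulation),
≤ 40 individuals × ≤ 200 SNPs for oracle comparisons, 250 trees × ~20 SNPs
for turnover fits, and 49–199 permutations/bootstraps in sampled tests —
sizes chosen so the full suite completes in well under a minute while keeping
Monte-Carlo bands (±0.05 on mean F_ST, 3 SE on error rates, ρ > 0.9 rank
agreements) meaningful. Estimator correctness is always established against
independent brute-force implementations at small n, never against the
implementation itself.

## Known limitations

* No linkage, LD pruning, or coalescent genealogies; bootstrap over loci
  assumes exchangeable sites.
* The simulator's environment is stationary in time except for the supplied
  displacement vectors; no within-lake (aquatic vs atmospheric) mismatch is
  modelled.
* The RDA screen's recall is regime-dependent: under very strong per-lake
  drift, neutral loci mimic environmental association and recall degrades —
  a property of the method class, not of this implementation.
* AMOVA uses genotype (dosage) distances; toolchains working from
  allele-frequency sums of squares will differ in small samples.
* Real-data scale results (tens of thousands of SNPs, 64 wild populations)
  are represented here only by the packaged summary tables; sequence-level
  reprocessing is out of scope.
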