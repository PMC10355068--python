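# Methods

This note documents the models and procedures implemented in `gmeb`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and rarefaction

Counts are non-negative integers, samples in rows, taxa in columns, always;
readers transpose on detection against metadata sample ids. Missing
taxonomic ranks carry the literal sentinel `unclassified`, so filters and
aggregation have a testable invariant instead of ad-hoc empty strings.

Rarefaction draws one multivariate-hypergeometric sample per well (without
replacement, seeded): a single draw, not an average over draws. The shipped
pipeline default depth is 23,976 reads — a common national-survey
convention — and is overridable; desk-scale configurations use much
smaller depths. Samples below depth are dropped and reported.

## Diversity and biogeography

* Shannon `H = -Σ p ln p` over nonzero proportions, natural log.
* Faith's PD is the branch length of the minimal subtree spanning the
  sample's tips **including the path to the root**. This is a convention
  choice (some tools stop at the tips' most recent common ancestor); it is
  fixed, documented, and covered by an exact unit test
  (`((A:1,B:1):1)` with both tips present gives PD = 3).
* Beta diversity is Bray–Curtis on counts; "community similarity" in the
  distance–decay analysis means `1 - BC`.
* The distance–decay relationship (DDR) is an OLS fit of `ln S` on `ln d`
  over unordered pairs, natural logs, with pairs closer than 1 m or with
  zero similarity excluded (their count is reported — the exclusion rule
  is explicit rather than silent). Distances are haversine great-circle
  distances with Earth radius 6371 km. Significance comes from a Mantel
  test (Pearson on vectorized triangles, row/column permutations, default
  999, one-sided for positive association, seed mandatory).
* The latitudinal diversity gradient (LDG) is fitted both linearly
  (Pearson r reported) and quadratically; for negative curvature the peak
  latitude `-b/2a` is reported.

## Core taxa, preference tests, biomarker screen

Core taxa: occurrence frequency strictly above 50% of samples AND mean
relative abundance strictly above 0.01%; regionally rare taxa fall
strictly below 0.001% mean relative abundance. Thresholds are parameters.
Occurrence counts presence (count > 0) after rarefaction.

Group preference uses the two-sided Wilcoxon rank-sum test per taxon on
relative abundances, with the exact null distribution when groups are
small and untied (so complete separation at n = 10 + 10 yields
p = 2/C(20,10) exactly), BH or Bonferroni adjustment, and the
higher-median group as the preferred habitat when significant.

The biomarker screen is deliberately simpler than LDA-effect-size
pipelines: Kruskal–Wallis per taxon across ≥ 2 groups, BH adjustment, an
enriched-group mean-abundance floor (default 0.5%), and a log10
mean-ratio effect used only for ranking. It produces the ranked
biomarker list the GMCI needs without re-deriving discriminant-analysis
internals.

## Co-occurrence networks and keystones

Networks are built at genus level within a sample stratum (e.g. a
well-depth bin): genera below 0.01% mean relative abundance removed, all
remaining pairs tested with Spearman correlation (average ranks on ties;
t-approximation for n ≥ 10, seeded permutation test below), p-values
BH-adjusted **within the stratum's own family of pairs**, and edges kept
when |rho| > 0.6 and adjusted P < 0.001. Isolated nodes are dropped, and
the edge invariants are re-asserted post hoc.

Topology: average degree, average shortest path over the largest connected
component, average clustering, density, greedy-modularity communities
(deterministic), and the fraction of negative edges. Closeness is computed
within each component; betweenness is normalized.

Keystones are nodes jointly at high degree, high closeness and low
betweenness. The direction of the criterion is from the co-occurrence
literature; the cutoffs are this package's calibration: degree and
closeness at or above their 80th percentile and betweenness at or below
its 50th percentile, with discrete (observed-value) quantiles so that ties
are inclusive — in a clique of identical nodes, all qualify. All three
quantiles are parameters.

Spearman networks on relative abundances are compositional; no
centered-log-ratio or SparCC-style correction is applied. This is a known
limitation shared with most survey practice.

## Rank-abundance models and the neutral ZSM

Six models are compared per sample on the identical abundance vector.
The five niche-based models are fitted by maximizing the Poisson
log-likelihood of the observed rank abundances given the model curve
(the GLM-style convention of standard RAD-fitting software; fits were
checked against `vegan::radfit` during development):

* preemption: `E(n_r) = N α(1-α)^{r-1} / (1-(1-α)^S)`, k = 1
* broken stick: `E(n_r) = (N/S) Σ_{k=r}^{S} 1/k`, k = 0
* log-normal: `E(n_r) = exp(μ + σ Φ⁻¹((S-r+0.5)/S))`, k = 2
* Zipf: `E(n_r) = N p₁ r^{-γ}`, k = 2
* Zipf–Mandelbrot: `E(n_r) = N c (r+β)^{-γ}`, k = 3

Optimization is bounded L-BFGS-B with five spread starts and tolerance
1e-10; for models with a free multiplicative scale the Poisson score
equation ties the fitted total to N automatically.

The zero-sum multinomial (ZSM) log-likelihood is the exact Etienne
sampling formula in (θ, m), with the `K(D, A)` coefficients computed by
log-space convolution of per-species Stirling-number polynomials and the
likelihood maximized numerically over (θ, I), `I = m(J-1)/(1-m)`. The
implementation is validated against the closed-form two-individual
probability and against direct simulation of the neutral sequential
construction (empirical configuration frequencies at J = 8 match the
exact likelihoods within Monte-Carlo error).

**Cross-model AIC comparability.** The Etienne formula is the probability
of the *unordered* abundance configuration, whereas the Poisson fits score
the *rank-ordered* vector. Comparing them raw inflates the ZSM by the
log-multiplicity of the configuration (≈ `log(S!/Π Φ_j!)`), enough to make
the neutral model win even on data generated from the broken-stick model.
The package therefore converts the ZSM likelihood to the ordered-vector
scale by subtracting that multiplicity before computing AIC. Parameter
estimates (θ, m) are unaffected. With the correction, samples generated
from the geometric series and from the broken stick are AIC-classified to
their generating models in ≥ 90% of replicates, and neutral verdicts are
rare on niche-structured data — consistent with published groundwater
surveys reporting only a few percent of ZSM-best samples.

Samples larger than `zsm_max_n` (default 1000) are first rarefied —
seeded, and applied to **all** models so AICs remain comparable. AIC ties
within 1e-6 go to the model with fewer parameters. A sample is classified
neutrally assembled iff the ZSM is AIC-best.

## Niche breadth

Levins breadth `B_j = 1/Σ_i P_ij²` with `P_ij` the proportion of taxon
j's total found in habitat i; habitats default to individual samples (an
option pools samples by geo-zone). Community-level habitat niche breadth
and mean niche breadth are the sum and the average of B over the taxa
present in a sample. B is scale-dependent across uneven sequencing
depths, so community summaries should be computed on rarefied tables.

## Normalized stochasticity ratio

For each within-group pair, observed dissimilarity D (Bray–Curtis by
default; Jaccard available) is compared with the expectation E under a
null model. The default "PF" null preserves each sample's richness,
draws which taxa occur with inclusion probabilities exactly proportional
to regional occurrence frequency (randomized systematic
probability-proportional-to-size sampling), and assigns reads
multinomially in proportion to regional mean relative abundance, with one
guaranteed read per occupied taxon. Null abundances are drawn, not set
deterministically: a deterministic assignment would make null pairs
artificially similar and bias the ratio downward under neutral assembly.

With C = 1-D and E_C = 1-E, the pair's stochasticity ratio is
`ST = E_C/C` when the pair is more similar than expected and `ST = E/D`
otherwise; it is normalized to `NST = (ST - ST_det)/(1 - ST_det)` with
`ST_det` = E_C or E respectively, so NST is 0 when the community is as
structured as it can be relative to the null and 1 when observation
matches the null expectation. Group means are reported in percent with
50% as the deterministic/stochastic boundary. Degenerate pairs (E of 0 or
1, or D = 0 on the dissimilar branch) are skipped with a warning.

The external NST R implementation offers many null algorithms and
normalizations and the combination used in any given survey is rarely
fully specified; numeric equality with that package is therefore not a
goal — the implementation here is documented exactly, and its behavioral
properties (direction under neutral vs filtered assembly, 0–100% range,
anti-monotonicity in filter strength) are what the tests pin down. A
phylogenetic variant (betaMNTD with tip-label shuffling) is provided
behind the same contract and tested for range and determinism only.

## GMCI

The Groundwater Microbial Community Index follows the observed/expected
multimetric-index tradition (cf. invertebrate community indices):

1. **Baseline**: undisturbed samples (newly constructed wells) from a
   habitat comparable to the test sites (default matcher: same water type
   and geo-zone).
2. **Candidate indicators**: Shannon (and Faith PD when a tree is
   present) always; dominator taxa (core phyla/genera), key species
   (network keystones) and biomarkers at genus level, subject to
   occurrence ≥ 20% and mean relative abundance ≥ 0.5% in the baseline.
3. **Calibration** (seeded 60/40 split of baseline and impacted sets):
   expectation = median of the calibration baseline (median, for
   robustness to skewed abundances); the alarm O/E ratio maximizes
   (accuracy - error) on the calibration split over the observed O/E
   grid, ties to the more conservative (larger) ratio. O/E is
   two-sided by default (deviation on either side of 1 can alarm);
   one-sided indicators are supported.
4. **Vetting and weights**: an indicator survives if its holdout accuracy
   is ≥ 0.5, its holdout error ≤ 0.5, **and** its holdout flag-rate
   difference beats chance (one-sided Fisher exact test, BH-adjusted
   across candidates, α = 0.05). The significance screen is essential:
   threshold-only vetting passes chance-level indicators whenever the
   impact effect is absent, whereas with the screen a zero-effect
   calibration refuses outright — the index fails loudly instead of
   certifying noise. Weights are holdout accuracies normalized to sum 1.

A sample's score per indicator is `s_i = |ln(O_i/E_i)| / |ln(alarm_i)|`
(counted only on the alarmed side for one-sided indicators; capped at 10
when O = 0), and `GMCI = Σ w_i s_i`. The normalization makes GMCI = 1.0
exactly the all-alarms boundary, so the alarm threshold of 1.0 is a
construction, not a tuned constant. Evaluation reports accuracy (flagged
impacted / impacted) and error (flagged baseline / baseline).

## Synthetic survey generator

The generator is an explicit stand-in for national-survey data — no
generative model is available for the real thing — and encodes the
statistical structure the analyses assume:

* regional pool: lognormal abundances (meanlog 0, sdlog 1.5) over 300
  taxa in 12 synthetic phyla; the dominant phylum's read share is
  calibrated to 0.52 on realized per-site expectations (fixed-point
  rescaling — calibrating the pool alone is not enough once niche
  filtering redistributes reads);
* sites: uniform over lat 20–52° N, lon 80–130° E, depth 5–100 m; seven
  longitude-binned geo-zones; ~70% phreatic wells;
* environment: 2 latent axes = linear lat/lon trend + spatially
  correlated Gaussian noise with correlation `exp(-0.002 d_km)`; taxa
  carry Gaussian niche optima; the filter exponent grows linearly with
  depth times `depth_filter_strength`, so diversity declines with depth
  and nearby sites share communities (distance decay);
* a shallow-water clade (15% of taxa) declines as `exp(-0.02 · depth)`;
* the unimodal LDG is imposed as a carrying-capacity multiplier
  `exp(-(lat-40)²/2·10²)` on realized site richness (top-weighted taxa
  retained);
* counts: one multinomial draw per site at 30,000 reads; tree: random
  ultrametric binary coalescent with clades matching phylum labels;
* neutral mode switches every niche term off — all sites draw from the
  shared pool — for stochasticity and neutral-model tests;
* impact treatment: expected community mixed with a contaminant pool at
  weight `composition_shift`, then flattened by exponent
  `1/(1+diversity_boost)` (raising evenness and hence diversity), and
  redrawn at the original sequencing effort.

What it does **not** emulate: hydrogeochemical covariates, sequencing
error and chimeras, overdispersion beyond multinomial sampling,
compositional biases of PCR, temporal dynamics, or the real survey's
taxon inventory. Tests passing on this generator show the methods recover
known structure under the stated noise model — not that any particular
real aquifer behaves this way.

### "High filter strength"

The filter exponent is `strength × depth/100 m`, so low-strength settings
barely filter shallow wells. The strongly-filtered deterministic condition
used in the assembly tests sets strength 8, which keeps the exponent near
or above 1 across the whole depth range; typical resulting NST means
(20–40%) sit in the range reported for real pristine groundwater.

## Problem sizes and determinism

Shipped test and demo configurations run at desk scale: tens of wells,
pools of 100–300 taxa, thousands of reads per sample, 200 null draws for
NST, 50 replicates per RAD recovery condition, ZSM vectors capped at
1000 reads. Every random stage takes an explicit seed; the pipeline fans
one master seed out to stages by a fixed counter scheme and writes a
manifest with seeds, a parameter hash and output checksums, so a rerun
with the same config is bit-for-bit identical.

## Known limitations

* Spearman co-occurrence on relative abundances is compositional (see
  above); edges are associations, not interactions.
* The Poisson rank likelihood treats ranked abundances as independent
  observations; it is the standard convention, not a generative truth.
* NST is null-model-dependent by construction; report the null algorithm
  alongside any NST number.
* GMCI calibration assumes the impacted training set is representative of
  the impacts to be detected; indicators are vetted marginally, so
  strongly correlated indicators share weight rather than adding
  information.
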