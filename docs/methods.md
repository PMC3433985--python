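# Methods

This note documents the models implemented in `landlock`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open. The running system is an island drainage network
in which an amphidromous source goby (labelled `BR` throughout) is panmictic
across rivers — its larvae pass through the sea — while landlocked
populations (`YB…`) above waterfalls complete their life cycle in fresh
water and evolve independently.

## The waterfall clock

Waterfalls form where a resistant caprock overlies weaker rock; differential
erosion builds vertical height at an approximately constant rate *E* (m/yr).
A population landlocked when its waterfall became impassable has therefore
been isolated for *t = h/E* years. Isolation leaves a molecular record:
mtDNA distance between the landlocked population and the source pool grows
with the divergence-scale substitution rate *R*, so across waterfalls of
different heights

    D = b + C·h,   C = R/E.

The clock module fits this line by OLS (with the slope *F*-test), converts
the slope with **E = R/C**, and dates every fall as *h/E*. Key choices:

* **Units.** Heights in m; *R* entered as percent per Myr and converted to
  substitutions/site/year (3.8%/Myr → 3.8·10⁻⁸/yr); distances are
  substitutions/site; *E* reported in m/yr and mm/yr; ages rounded only on
  output. *R* is a configuration value, not a constant.
* **Exclusions.** A population that reached its site by downstream drift
  (e.g. a site between two waterfalls) carries its parent population's
  divergence, not its own isolation age. Such populations are excluded by an
  explicit caller-supplied flag — identifying them is biological reasoning,
  not an algorithm.
* **Intercept.** The fitted intercept estimates the standing diversity a
  founder lineage carries across the waterfall (see the generator below);
  it is reported, not forced through zero.
* **Plausibility band.** Independent geomorphology (regional relief of the
  island) puts bedrock erosion at 0.3–1.0 mm/yr; `sanity_check_erosion`
  flags a calibrated rate outside this band.
* Confidence intervals on ages by error propagation are deliberately out of
  scope.

## Distances

`gendist` implements the TN93 closed form from the observed purine
transition, pyrimidine transition, and transversion proportions, with base
frequencies estimated per pair from the two sequences pooled (the common
pairwise convention; table-wide frequencies are an option). Among-site rate
variation uses the continuous gamma analogue of each logarithm,
−ln w → a(w^(−1/a) − 1), with shape a = 0.14 — the shape selected for this
alignment by model selection in the original analysis. The "six rate
categories" phrasing attached to that selection belongs to likelihood tree
search, which is out of scope here; the continuous form is the standard one
for distance corrections. A non-positive logarithm argument marks the pair
saturated: the distance is NaN-flagged, excluded from group means with a
warning, never raised as an exception.

Group summaries are arithmetic means of pairwise distances (between-group
mean; within-group diversity over unordered pairs). At shape 0.14 the
correction is strongly convex, so single-pair estimates are noisy at short
distances; the tests verify the estimator is mean-unbiased at the study's
alignment length by simulation, and the clock's acceptance property is
phrased on the median over replicate systems for this reason.

AMOVA (below) conventionally uses the plain TN93 distance, the group means
the gamma-corrected one; both are switchable everywhere.

## AMOVA

Two-level analysis of molecular variance on individual sequences: sums of
squared pairwise distances partitioned into among- and within-population
components with the standard unequal-size coefficient
n′ = (N − Σn²/N)/(P−1); φ_ST = σ²_a/(σ²_a+σ²_w); a negative among
component is clamped to zero and flagged. Significance is by permuting
individuals among populations with sizes fixed, p = (1+#{φ ≥ φ_obs})/(B+1)
with B = 10,000 by default, seedable; an exhaustive mode enumerates all
distinct assignments for small problems and is used as a test oracle. With
zero total variance φ is reported as undefined (NaN) rather than 0.

## Parsimony network

Haplotypes (identical sequences after alignment-wide removal of gapped or
ambiguous sites) are joined level by level in order of increasing mutational
step count. Within a level, a link is added when the two haplotypes lay in
different components *at the start of the level* — the standard
minimum-spanning-network construction. This drops links that merely
duplicate a path already built at a cheaper level, while retaining all
equally parsimonious alternatives discovered at the same level
(reticulations, e.g. a one-step triangle). Multi-step links record
steps − 1 inferred unsampled intermediates. Components are never merged by
links above the connection limit.

The **connection limit** is the largest step count *j* whose probability of
being free of superimposed change still reaches the requested confidence
(0.95 by default). We compute that probability as the chance that *j*
substitutions scattered uniformly and independently over the *m* alignment
sites occupy *j* distinct sites — the falling-factorial product
Π_{i<j}(1 − i/m). This geometric collision term dominates the probability
that the observed differences equal the true substitution count; richer
population-genetic corrections exist, but over the regimes used here they
move the limit by at most a step or two and no downstream number depends on
it. At 2086 sites and 95% the limit is 15 steps.

On synthetic data the landlocked populations sit on the network periphery.
The test phrases this as *peripherality*: a population's private haplotypes
form a connected subgraph whose removal leaves the rest of the network
intact. The stricter "exactly one attaching edge" phrasing fails more often
for an uninteresting reason — equally parsimonious parallel attachments
created by homoplasy at gamma shape 0.14 — which the reticulation-retaining
construction keeps by design.

## Morphology

Nine characters scored 0 / 0.5 / 1 per fish; sexes analysed strictly
separately (several characters are dimorphic). Species comparisons use a
Mann–Whitney U test per character per sex — 18 tests, Bonferroni threshold
0.05/18 ≈ 0.0028. Because the 0.5 scores create ties, the exact test is an
explicit enumeration of all C(n₁+n₂, n₁) assignments of the pooled
mid-ranked values (used whenever both groups have ≤ 10 fish); larger groups
fall back to the normal approximation with tie correction. A character
constant in both groups is flagged untestable with p = 1.

Clustering is Ward on Euclidean distances over the nine scores. The default
variant is Ward.D2 (squared dissimilarities inside the Lance–Williams
update — what `scipy.cluster.hierarchy.linkage` computes and what the test
oracle pins by exhaustive agglomeration); the historical unsquared variant
("D") is available because the classic clustering routines were ambiguous
on this point. The 2-cluster cut is reported with its purity against
species labels.

Morphology-vs-genetics: for each landlocked fish, the mean Euclidean
distance to all same-sex source fish; averaged per population; regressed on
the population's genetic distance from the source (one regression per sex,
Bonferroni 0.05/2). Body size comparisons use the pooled-variance two-sample
*t* reconstructed from summary statistics (n, mean, SD), df = n₁+n₂−2.

## Habitat models

Occupancy is logistic regression of presence/absence on ten site factors
(waterfall-below-site dummy plus nine continuous measures). The landlocked
species occurs only above waterfalls, so the likelihood is perfectly
separated and ordinary ML diverges; fits use Firth's Jeffreys-prior
penalisation (score modified by the half-leverage term
h_i(½ − p_i)), Newton iterations with step-halving, convergence at
max|score| < 10⁻⁸ or 100 iterations. Continuous predictors are z-scored
internally for conditioning; coefficients and SEs are mapped back to the
original scale. AIC uses the penalised log-likelihood (the fit criterion);
plain-likelihood AIC is an option. Model choice fits all 2¹⁰ subsets
exhaustively; ties break toward fewer parameters, then lexicographic
predictor order; individual fit failures are recorded and skipped.
Discrimination is the rank-statistic AUC with ties counted one half.

Species richness is a Poisson log-link GLMM with a Gaussian random intercept
per river system. The marginal likelihood integrates the random effect by
adaptive Gauss–Hermite quadrature: per river, nodes are centred at the
conditional mode and scaled by the curvature there (8 nodes by default;
agreement with 64-node and non-adaptive high-order quadrature is tested to
10⁻⁶). The orchestrated pipeline restricts the richness predictor pool to
{waterfall, water depth, pebble size} — exhaustively refitting a GLMM 1024
times is disproportionate in a routine run — while the full all-subsets
machinery remains available and is exercised for the logistic models.

Environmental comparability above vs below falls is a two-group MANOVA:
Wilks Λ = det(W)/det(T) with Rao's exact two-group F transformation,
F = ((1−Λ)/Λ)(n−p−1)/p on (p, n−p−1) df.

## The synthetic generator

The generator's role is to produce datasets with the statistical structure
the analysis assumes, with recorded ground truth, so parameter-recovery
closes the loop. What it emulates, and how:

* **Source pool.** A star genealogy: each of 20 pool individuals hangs off
  a common ancestor on a branch of exponential depth with mean half the
  target diversity, so the expected mean pairwise distance equals the
  configured 0.00184. A star, not a full coalescent, because every
  downstream statistic here consumes distances, not topologies.
* **Mutation.** Finite-sites TN93 with stationary frequencies
  (0.28, 0.30, 0.15, 0.27), transition factors κ₁ = 15 (purine) and κ₂ = 30
  (pyrimidine) — typical fish mtDNA values — and per-site gamma(0.14) rate
  multipliers drawn once per system and shared by every branch, matching
  the rate model the distance estimator corrects for. Branches are
  simulated exactly via the spectral form of the transition matrix (one
  categorical draw per site per branch), so multiple hits arise naturally.
* **Landlocking.** Each waterfall's population is founded by one pool
  lineage (with its own exponential depth — the standing variation carried
  across the fall) plus an isolation branch of expected length R·t with
  t = h/E_true; members add small within-population branches
  (mean pairwise 0.0004, a free parameter — the field data publish no
  within-population figure). The expected source-to-population distance is
  therefore (pool diversity + half the within-population term) + R·t: the
  clock line, with the intercept interpretable as standing variation, which
  is how the field study reads its own intercept.
* **Morphology.** Landlocked fish shift every character toward the
  all-present profile by baseline 0.5 plus slope·D/3 (nine characters make
  the profile distance three times the per-character shift, so regression
  recovers the configured slope, default 100). The baseline is the shared
  landlocked phenotype — the parallel-evolution signature that makes the
  species fully separable regardless of divergence time; the
  distance-proportional part is the finer-scale divergence. Latent scores
  get Gaussian noise (SD 0.1) and snap to {0, 0.5, 1}.
* **Habitat.** 30 sites over 11 rivers, alternating above/below falls;
  continuous factors from plausible lognormal/uniform ranges; presence from
  a logistic model (intercept −2.5, waterfall +5, river width −1 on the
  z-scale — presence above falls is near-certain and very rare below,
  reproducing the separation that motivates the Firth fit); richness
  Poisson with waterfall effect −1.3 and river random intercept SD 0.3.
* **Determinism.** One master seed; named `SeedSequence` sub-streams per
  component; identical seeds give bit-identical datasets.

What the generator does **not** emulate: migration between landlocked
populations, selection, recombination, demographic size changes, shared
coalescent structure inside the pool, and sequencing error. Passing
recovery tests therefore show the *inference chain* is correct under its
own assumptions — not that those assumptions hold in any particular river.

### Noise structure and the recovery criterion

The dominant per-replicate noise in the clock chain is the founder lineage's
exponential depth (SD ≈ 0.0009 per population, a third of the clock signal's
range), plus Poisson substitution noise — at 0.67 mm/yr even the tallest
fall's branch expects only ~7 substitutions over 2086 sites, and two of the
dated falls expect less than one (the generator warns). Replicate slopes
scatter accordingly (single-replicate r² is typically 0.4–0.7), while the
mean slope and intercept are unbiased. Recovery is therefore assessed on
the **median over 50 replicate systems**, which lands within 15% of the true
0.67 mm/yr; the corresponding test and the acceptance script run exactly
that study (about half a minute on one CPU).

## Numerical and degenerate-input conventions

Saturated distance pairs: flagged NaN, excluded from means with a warning.
Zero-variance AMOVA: φ undefined, permutation test skipped. Negative
variance components: clamped, flagged. Ward ties: scipy's internal order
(the oracle fixture avoids ties, where the order is not unique). All-subsets
ties: fewer parameters, then lexicographic. GLMM σ is bounded at 0 and
optimised by Nelder–Mead with a polish restart; single-cluster data reduce
to the plain GLM. U-test enumeration switches to the tie-corrected normal
approximation above 10 per group. Haplotype ids are assigned in first-
occurrence order; network pair processing is lexicographic within a step
level — all outputs are deterministic given inputs and seed.
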