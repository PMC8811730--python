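# Methods

`phenoclust` turns raw fermentation sampling tables into *reference
phenotypes* — cluster centroids of biomass-specific rate vectors — and runs
the downstream analyses that make those references useful: conditionality
screening, carbon/ATP balancing, and mixture decomposition of time courses.
This note records the model, the numerical choices, and what the synthetic
test bed does and does not establish.

## The phenotype model

A cultivation is sampled at times `t_j` for biomass `c_1` [g/L] and up to
ten compounds `c_D` [mmol/L] (substrates glucose and glycerol; products
1,3-propanediol, ethanol, butanol, lactate, formate, acetate, butyrate and
2-oxobutyrate — the eleven dimensions of the built-in compound registry,
with molar masses, carbon counts and substrate-level-phosphorylation ATP
stoichiometries).  The phenotype at `t_j` is the vector

    a_j = (mu, r_2, ..., r_m)',     r_D = (1/c_1) dc_D/dt   [mmol/(g h)]

with consumption negative and `mu` [1/h] the specific growth rate.

**Rate estimation.**  Each compound's series is interpolated with the
shape-preserving PCHIP polynomial (no overshoot between samples, exact at
the samples); the derivative at `t_j` is a centered difference of the
interpolant with half-step `grid_step` (default 0.1 h, clamped inside the
measured range).  `mu` is the slope of an ordinary least-squares line
through `ln c_1` over the window spanning the two neighbouring samples — an
exponential fit on raw points, matching the locality of the finite
difference.  Vectors exist only at interior sampling times; the first and
last sample have no centered stencil.  Vectors at non-positive biomass are
dropped and logged.  Fed-batch columns recorded as cumulative consumed
amount are differentiated the same way and negated to the consumption
convention; their "concentration" is never used for concentration binning.

**Trimming.**  Because `r_D ~ 1/c_1`, low-biomass points blow up.  Before
k-means clustering, per-dimension empirical percentile bands (default
3rd/97th, linear interpolation between order statistics) are computed over
all vectors pooled across experiments; a vector is removed when *any*
dimension leaves its band.  This any-violation rule is the strictest
reading of per-compound trimming and best damps the low-biomass artifacts;
with 11 dimensions it typically removes 30–40 % of vectors at 3/97.

## Clustering

Vectors are z-scored per dimension with the sample standard deviation
(denominator n−1); a zero-spread dimension is a hard error naming the
column.  Two dissimilarities are supported: squared Euclidean distance
(`sed`) and cosine distance (`cd`, `1 − cos θ`).  Cosine groups phenotypes
by the *direction* of their rate pattern, which is usually what "same
metabolism, different intensity" means; it cannot, by construction,
separate phenotypes that differ only in magnitude along a common direction.

k-means is hand-written Lloyd iteration with k-means++ seeding (candidate
sampled proportionally to its dissimilarity to the nearest chosen center),
best-of-`replicates` restarts, assignment ties to the lowest cluster index,
and empty clusters repaired by reseeding with the farthest point.  Under
`cd` the update is spherical k-means: inputs are unit-normalized and the
centroid is the renormalized mean of assigned unit vectors.  The
per-iteration objective is recorded and is non-increasing; all randomness
flows through one integer seed.  On unit vectors `1 − cos θ = ‖u − v‖²/2`,
so cosine k-means and SED k-means on normalized data coincide on separable
data — a cross-check exercised in the tests.

DBSCAN (neighbourhood radius ε in the chosen dissimilarity, minimum
neighbour count defaulting to twice the dimensionality, i.e. 22 for the
11-dimension registry) delegates to scikit-learn with the `sqeuclidean` or
`cosine` metric; clusters are renumbered by first appearance and the sweep
helper tabulates the two screening diagnostics (fraction of points
clustered, fraction of clustered points in cluster 1).

The number of clusters is screened with silhouette (either metric), the
Gap statistic (uniform reference over the per-dimension z-range, B = 50
seeded draws, one-standard-error rule, single k-means replicate per k),
and Davies–Bouldin / Calinski–Harabasz (Euclidean criteria, `sed` only).

Whatever produced the partition, each cluster's reference phenotype ζ is
the per-dimension **median of the raw (un-normalized) vectors** assigned to
it — robust to the heavy-tailed rate errors that survive trimming.

## Conditionality

For cluster CL and condition `cond` (a tag value, or a concentration range
`[a, a+step)` with `a = floor(c/step)·step`, steps from
{1, 5, 10, 20, 50, 100} mmol/L, biomass default 0.05 g/L),

    delta = log10[ (n_CL,cond / n_CL) / (n_cond / n) ]

is over-representation when positive and undefined (reported as such)
whenever a count is zero.  DBSCAN noise and, for concentration conditions,
fed-batch-cumulative vectors are excluded from both populations.  The
statistic is descriptive; no multiple-testing machinery is attached, and a
pure cluster shows "undefined" rather than −∞ for the absent condition.

## Carbon and ATP balancing

The theoretical CO2 rate of a reference phenotype counts one pyruvate
decarboxylation per ethanol and acetate, two per butanol, and (default) two
per butyrate — butyrate condenses two acetyl-CoA; the coefficient is
configurable to 1 for the single-decarboxylation convention — minus one per
formate (formate is the undecarboxylated C1).  Carbon recovery is

    R_C = 100 · [ 4·ζ_mu·1000/101.1 + Σ_products n_C·ζ + r_CO2 ]
              / Σ_substrates n_C·|ζ|        [%]

with the biomass monomer C4H7O2N (101.1 g/mol) and the 1000 converting the
gram-based growth rate to mmol carbon.  No substrate uptake ⇒ not
computable (reported).  The ATP production rate from substrate-level
phosphorylation is `q_ATP = Σ s_ATP/D · ζ_D` over products with defined
stoichiometry.

Across clusters, `q_ATP = slope · mu + q_m` is fitted by unweighted OLS
over the clusters whose R_C is computable and within a threshold (default
19 percentage points) of 100 %.  The biomass yield on ATP is `Y = 1/slope`
with a delta-method standard error; its 95 % confidence set is the
reciprocal image of the t-based slope CI (Fieller-type).  This set has
exact coverage and degenerates honestly to two unbounded rays when the
slope is not significantly different from zero — the delta interval has no
such guarantee, which matters because with realistic growth rates
(mu ≤ ~0.35 1/h) a shallow planted line leaves the slope weakly identified.
Note the units: with `q_ATP` in mmol/(g h), a yield printed in g/mol
corresponds to a fitted slope of 1000/Y; `fit_atp_regression` reports the
literal reciprocal of the slope it fits.  A non-positive slope is flagged
"not physical" with diagnostics.  The reported band around the fitted line
is the pointwise 95 % OLS confidence band (not a prediction band).

## Superposition decomposition

Reference centroids and a query vector are rescaled per dimension to
[0, 1] with min/max pooled over centroids **and** query (a flag switches to
centroid-only scaling; queries may then leave [0, 1] and are not clipped);
zero-spread dimensions are dropped with a warning.  The non-negative
least-squares problem `min ‖A**x − a**‖², x ≥ 0` is solved with the
deterministic active-set algorithm; coefficients are rendered as
percentages `100·x/Σx` (undefined when every coefficient is zero, in which
case RSS = ‖a**‖²).  For time courses the *proportion* traces (not the raw
coefficients) are smoothed with a Gaussian-weighted moving average over a
centered 5-point window, σ = (window−1)/5 = 0.8 index units, edge weights
renormalized, and re-normalized to sum to 100.  Duplicated (near-identical)
centroids make the split between them arbitrary; only their summed
proportion is meaningful, and the tests pin exactly that contract.

## The synthetic test bed

The generator inverts the rate definitions — `dc_1/dt = mu·c_1`,
`dc_D/dt = r_D·c_1` — under a schedule of piecewise-constant (optionally
blended) archetypes, integrated with RK4 at step ≤ 0.01 h, sampled at
configured times, and corrupted with multiplicative lognormal noise
(default σ = 0.02, i.e. ~2 % relative error, the scale-proportional
behaviour of HPLC/OD measurements; keeps values non-negative).  A substrate
driven below zero triggers exhaustion: all rates switch to zero thereafter.

Archetypes are built carbon-closed — the substrate uptake is solved from
the product slate plus theoretical CO2, so true R_C is exactly 100 %.  The
default library spans the clostridial spectrum: a 1,3-PDO/acetate producer
(mu 0.10), a butanol-dominated solventogenic phenotype (mu 0.17), a
fast-growing acidogenic phenotype (mu 0.25, with a trace of 2-oxobutyrate
so every registry dimension has spread), a glucose-fed mixed-acid phenotype
(mu 0.12), and a near-dormant state (mu 0.01).

Default campaign design, chosen once to mirror a realistic batch campaign:
initial biomass uniform 0.05–0.15 g/L, glycerol 250–600 mM, glucose
100–200 mM where used; 4–15 quasi-regular samples (±20 % jitter) over
8–16 h, with the run truncated shortly before substrate exhaustion (a real
batch ends at depletion); 40 % of runs switch archetype once mid-run; the
butanol archetype occurs only in BES-tagged runs so tag conditionality is
testable.  Ground truth records the planted rates and an archetype label
per sampling time; a point whose centered stencil spans a switch or an
exhaustion has no single true phenotype and is labelled `mixed` (excluded
from label-recovery scoring).

**What the test bed shows — and does not.**  Closed-loop recovery is
excellent where the information exists: noise-free, planted rates return
with ~0.1–0.4 % median relative error, and at σ = 0.02 the product rates
and mu return with a few percent; cosine k-means at the true k recovers the
planted labels with ARI ≈ 1, planted tag associations reappear in the
log-deviation statistic, and a planted mid-batch phenotype switch is
detected by the decomposition within one sampling interval.  Substrate
uptake rates, in contrast, are *physically* noise-limited: 2 % of a
multi-hundred-mM residual pool (±5–12 mM per sample) exceeds the hourly
consumption increment at sub-g/L biomass (~1–8 mM), so centered-difference
substrate slopes — and everything downstream of them, notably per-cluster
carbon recovery — are unreliable at realistic noise.  The pooled median
rate error at σ = 0.02 is therefore ~7 %, not a few percent, and noisy
pipeline centroids show carbon recoveries far outside [95, 105] % even
though every planted archetype is exactly carbon-closed.  This mirrors the
wide carbon-recovery spread seen on real fermentation panels and is the
reason the carbon-recovery gate of the ATP regression exists at all.
Pipeline-level carbon closure is therefore verified noise-free, and the
planted-energetics regression test groups vectors by planted label (the
line archetypes are collinear in z-space, beyond what direction-based
clustering can resolve) with the recovery gate disabled.

The simulator holds rates biomass-specific and piecewise-constant — ground
truth *is* a phenotype vector — rather than modelling kinetics, inhibition,
pH or gas phases; real data will violate piecewise-constancy, so passing
tests establish the correctness of the estimator/cluster/balance chain,
not the adequacy of the phenotype abstraction for any particular organism.

## Reproducibility and defaults

Every stochastic operation takes one integer seed; CLI runs write a YAML
manifest with command, parameters, seed, input SHA-256 digests, package
version and timestamp.  Defaults: `grid_step` 0.1 h, trim 3/97, k-means
replicates 20 for final models (1 inside k-screening), DBSCAN `np_min`
2·m, carbon-recovery threshold 19 points, butyrate CO2 coefficient 2,
smoothing window 5.  Problem sizes in tests and the acceptance script (20
simulated experiments, ≈150 vectors, 200-replicate Monte Carlo) keep the
whole suite under a minute while leaving every statistic several standard
errors of headroom.
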