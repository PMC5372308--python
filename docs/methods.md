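# Methods

## The integrated differential-expression test

Each study is a features × samples matrix of log₂ intensities with a
two-class (tumour/normal) sample annotation.  Studies are assumed already
summarized and log₂-normalized; the pipeline performs no background
correction, quantile normalization or batch correction.  Probe identifiers
are mapped to a canonical miRNA namespace (unmapped probes dropped and
counted; multi-probe groups collapsed by the probe mean, with a
maximum-variance alternative), studies are restricted to their common
features, and features are filtered by cross-study rank: per study, rank
features ascending by mean, average the ranks, drop the lowest
`mean_filter_frac`; repeat on the survivors with per-study SDs and
`sd_filter_frac`.  The kept count is `ceil((1−frac)·n)` at each step, so the
filter can never empty the dataset; boundary ties are resolved by feature-ID
lexicographic order for determinism.  Defaults are 0.10/0.10 with 300
permutations and α = 0.05.  Whether filtering precedes or follows the
cross-study intersection is a free choice; this pipeline intersects first,
then filters.

Per study, the moderated t adds a fudge constant s₀ to the denominator of
the pooled-variance t.  s₀ defaults to the median of the study's per-feature
standard-error terms (`fudge_quantile = 0.5`); at s₀ = 0 the statistic
reduces exactly to Student's pooled t, and for constant data with s₀ = 0 it
is undefined (NaN from the scalar API; the vectorized permutation path
prices such features at p = 1).

Permutation null: labels permute within each study only, preserving
additive study effects; each study draws an independent permutation stream
from the run seed, shared across its features.  A statistic's p-value is
its rank within the pooled set that contains the observed statistic itself
— {t_obs, t*₁…t*_B} in sampling mode, or the full set of distinct label
assignments (which contains the identity) in enumeration mode, entered with
a warning whenever B reaches the assignment count.  This is the
(1 + count)/(B + 1) estimator: strictly positive, and exactly
discrete-uniform under the null because observed and permuted statistics
are priced by the same rule against the same pool.  Statistics are rounded
to 10 decimals before tail counting so that exact permutation ties (e.g.
complementary assignments, equal in magnitude by symmetry) are not broken
by float round-off.  Consequently p ≥ 1/(B+1): with B = 300 and ~1000
features the smallest attainable BH q at 50 true positives is
(1/301)·1000/50 ≈ 0.066 — FDR-corrected discovery at q < 0.05 on that scale
requires B ≈ 1000, which the tests use for power scenarios; B = 300 remains
the protocol default for raw-α analysis.

Fisher combination uses the classical S = Σₖ −2·ln pₖ (the scale constant
and log base are irrelevant under a permutation reference).  S_obs is
priced against S*_b assembled from the same permutation indices across
studies.  One-sided p-value sets are combined separately for the up and
down tails; a feature is called `up` when the combined up-tail p < α, the
down-tail is not, **and** the fixed-effect pooled SMD is positive
(symmetrically for `down`); features significant in any combined sense but
failing those coherence requirements are `inconsistent`, and everything
else is `ns` (the direction column labels every feature, so a
not-significant token is needed alongside up/down/inconsistent).

Effect sizes: per study, Hedges' g = J·(x̄₁−x̄₂)/s_p with
J = 1 − 3/(4(n₁+n₂) − 9) and variance v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂));
pooling by inverse-variance fixed effects and DerSimonian–Laird random
effects (τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), I² = max(0, (Q−df)/Q)·100,
95% CIs at ±1.96·se).  The Fisher-significant list, the effect-size list
(random-effects CI excluding zero) and their intersection are all emitted,
since a single reconciliation rule between the two routes is not uniquely
determined.

## Downstream stages

**Risk score.** Ordinary least squares of the 0/1 class indicator on the
log₂ marker panel with intercept ("linear regression", not logistic —
logistic is available in principle but the linear form is the reported
convention); the fitted linear predictor is the score, and its in-sample
Mann–Whitney AUC (ties counted half) is attached.  In-sample AUC is what is
reported; it is optimistically biased and labelled as such.  A singular
design is rejected naming the collinear markers.

**Survival.** Median dichotomization uses "≥ median → high" (so all
median-tied subjects are high; group imbalance is bounded by twice the tie
count).  Kaplan–Meier with Greenwood variance; two-group log-rank with the
hypergeometric variance form; Cox regression maximizes the Breslow partial
likelihood by Newton–Raphson from β = 0, converging at max |score| < 1e-8
or relative log-likelihood change < 1e-10, capped at 50 iterations, with
monotone likelihood flagged at |β| > 20 and SEs from the inverse observed
information.  Breslow tie handling keeps the classical identity "score test
at β = 0 = log-rank χ²" exact on tie-free data.  Multivariate models follow
the clinical-table convention: univariate Wald screen at α, then forward
(smallest in-model Wald p < p_enter, name as tie-break) / backward
(drop any p > p_remove) stepwise iteration to a fixed point, skipping
candidates that make the design singular.

**Targets and enrichment.** Consensus = genes present in ≥ `min_sources`
prediction sources (default all sources, i.e. strict intersection), with
exact Venn-region counts for every source combination.  Enrichment is the
one-sided hypergeometric tail P(X ≥ k) over a stated universe — the
universe defaults to the union of the database's sets, and an explicit
universe file should be supplied whenever one is known, since p depends
strongly on N.  The `significant` flag uses the raw p < 0.05 rule; BH q is
reported alongside.  An EASE-style adjustment is deliberately not the
default.

**Quantification utilities.** Relative qPCR expression 2^(−ΔΔCt) from four
explicit Ct values, and caliper xenograft volume L·W²/2 (warns, but
computes, when width exceeds length).

## The synthetic-data generator

`simulate_meta_dataset` draws, for feature j in study k, control values
Normal(μ_j + b_k, σ_j²) and case values shifted by δ_jk·σ_j, with
δ_jk = g_j + Normal(0, τ²) for planted features and 0 otherwise — effects
planted in per-σ units so realized Hedges' g is comparable across features,
and between-study heterogeneity entering exactly as the random-effects
model assumes, which keeps parameter recovery well-posed.  Defaults: 7
studies of 30+30 samples (the inclusion rule of the emulated compendium, at
desk scale), 1000 features, 50 DE at |g| = 1.5 half up, baselines
Uniform(6, 12) log₂, study shifts Normal(0, 0.5²), feature SDs
Uniform(0.3, 1.2), τ = 0.2.  The shift and SD magnitudes are declared
defaults, not estimates.  Survival cohorts use exponential event times with
hazard `baseline_rate·exp(x·β)` and independent exponential censoring
(defaults 0.05 and 0.03 events/month over 240 subjects: median follow-up
near a year, ~60% events).  Target sources are jittered copies of a planted
core; pathway databases are uniform random sets with one optional planted
set.  All generators are pure functions of (spec, seed) and always return
ground truth.

What the generator does **not** emulate: platform-specific probe chemistry,
miRNA isoform structure, heavy-tailed or correlated noise, informative
censoring, covariate-dependent missingness.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every artefact of real microarray or registry
data.

## Problem sizes and numerical checks

The test suite exercises the integrated test at 5 studies × (20+20)
samples × 1000 features with B = 200 (null calibration) and B = 1000
(power/recovery); effect pooling at 200 replicates of 5 × (30+30); Cox
recovery at n = 2000 and stepwise selection over 100 cohorts of n = 500
with six candidates; AUC exactness over 1000 random instances (n ≤ 50);
hypergeometric tails exhaustively for all N ≤ 25.  Independent oracles:
exhaustive label enumeration for permutation p-values, all-pairs counting
for AUC, closed-form inverse-variance algebra for pooling, hand
product-limit/2×2-table computations for KM and log-rank, combinatorial
enumeration for hypergeometric tails, and lifelines as a cross-check for
KM and Cox.

## Known limitations

- DerSimonian–Laird CIs undercover slightly with few studies (measured
  ~92–95% at K = 5, τ = 0.2); no Knapp–Hartung adjustment is implemented.
- Direction calls at raw α admit the nominal per-tail false-positive rate;
  use the BH q column for discovery lists.
- The log-rank χ² reference is asymptotic; at small n (≈60) the rejection
  rate at 0.05 runs a point or two above nominal.
- Permutation p-value resolution is 1/(B+1); choose B with the intended
  multiplicity correction in mind (see above).
- In-sample AUC of a fitted panel is optimistic; the label-permutation null
  of a *fixed* score (mean AUC 0.5) is the honest reference, and no
  cross-validated AUC is computed by default.
- Paired tumour/normal linkage (`pair_id`) is carried by the formats but
  the default analysis treats classes as independent groups.
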