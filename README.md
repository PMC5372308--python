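# mirmeta

Integrated meta-analysis of miRNA differential expression across several
tumour/normal microarray cohorts, with the downstream stages that turn the
integrated signature into candidate biomarkers: diagnostic risk scoring
(ROC/AUC), prognosis (Kaplan–Meier, log-rank, Cox with stepwise covariate
selection), and miRNA target-set consensus with pathway over-representation.
A first-class synthetic-data module generates multi-study expression
compendia, censored survival cohorts and target/pathway databases with known
ground truth, so the entire pipeline is testable end to end without any
external download.

## The statistics at the core

Each study contributes per-feature **moderated t-statistics**

&nbsp;&nbsp;&nbsp;&nbsp;t̃ = (x̄₁ − x̄₂) / (s_p·√(1/n₁ + 1/n₂) + s₀),

where s_p is the pooled within-group SD and the fudge constant s₀ (the
median per-feature standard error of the study, SAM convention) stabilizes
low-variance features.  Significance is referenced to a **within-study
label-permutation null**; p-values use the rank of the observed statistic in
the pooled permutation set, (1 + #{|t*| ≥ |t̃|})/(B + 1), which is strictly
positive and exactly discrete-uniform under the null (full enumeration
replaces sampling when B reaches the number of distinct label assignments).
Per-study p-values are combined by **Fisher's statistic** S = Σₖ −2·ln pₖ,
itself priced against the combined statistics of the same permutations, with
Benjamini–Hochberg correction across features and one-sided p-value sets
combined separately to classify features as up- or downregulated.

In parallel each feature's per-study **Hedges' g** (standardized mean
difference with small-sample correction) is pooled by inverse-variance
weighting under fixed-effects and DerSimonian–Laird **random-effects**
models, with Q, τ² and I² heterogeneity statistics and 95% CIs — the forest
plot content for any feature of interest.

Downstream: an OLS risk score `score = β₀ + Σⱼ βⱼ·E_j` over a marker panel
(E_j = log₂ expression) with Mann–Whitney AUC; median dichotomization
(≥ median → high), product-limit survival curves with Greenwood variance,
the two-group log-rank test, and Newton–Raphson Cox regression (Breslow
ties) with a univariate Wald screen followed by stepwise selection;
consensus target lists over prediction sources with full Venn-region
counts; and hypergeometric over-representation P(X ≥ k) against a stated
gene universe.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 17).  `python analysis/01_simulate_cohorts.py` writes seven
cohorts of 30 tumour + 30 normal samples over 1000 miRNAs with 50 planted
DE features at |g| = 1.5, a 240-subject survival cohort, and the target and
pathway databases.  Then `python analysis/02_meta_analysis.py` prints:

```
feature funnel: input=1000 -> mean_filter=900 -> sd_filter=810
direction calls at alpha=0.05: 54 up, 56 down, 11 inconsistent
ground truth: 50 planted (45 survive the filters); 45 correctly called with
matching direction; 65 calls elsewhere
```

The funnel mirrors the protocol's 10% mean and SD rank filters; every
planted feature that survives filtering is recovered with the correct
direction, and the raw-α calls elsewhere are the expected ~5%-per-tail
background (the BH q column in `results/meta_de/meta_de_results.tsv` is the
multiplicity-corrected list).  Stage 03 builds the 4-miRNA risk-score panel
(panel AUC 0.974 vs 0.80–0.91 for single markers), stage 04 reproduces the
Table-2 style survival analysis (log-rank χ² = 31.9, p = 1.6e-08; stepwise
keeps exactly the planted marker, HR 2.6), and stage 05 recovers the
consensus target list and flags the planted pathway
(11/30 genes, p = 1.2e-13).

The same stages are exposed as a CLI (`mirmeta simulate | meta-de |
biomarker | survival | enrich`); reruns with the same `--seed` produce
byte-identical outputs.

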