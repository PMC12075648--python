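# Methods

This document records the statistical model behind each pipeline stage, the
tunable parameters and their defaults, what the synthetic-cohort generator
does and does not emulate, and the numerical and design decisions baked into
the implementation.

## 1. Data model

The analysis unit is a cohort of *n* persons. Person *i* carries a binary
condition profile **x**ᵢ ∈ {0,1}ᵖ over *p* long-term conditions, demographic
covariates (age in years, sex, ethnicity, country, deprivation decile), a
baseline flag for the outcome already being present, and follow-up data
(time in years, event type ∈ {outcome, death, censored}).

Persons with **x**ᵢ = **0** form the *reference group*. They are excluded
from clustering (a cluster of "no conditions" is not a multimorbidity
cluster) but retained as the baseline stratum of the survival model and in
the denominator of cohort prevalences. `ConditionMatrix` enforces this
partition: every clustered row has at least one condition.

## 2. Clustering

All four methods operate on the matching (simple-matching / Hamming count)
dissimilarity d(**x**, **y**) = Σⱼ 1[xⱼ ≠ yⱼ], the natural metric for binary
profiles: it avoids treating 0/1 as magnitudes.

**k-modes** alternates assignment of each person to the nearest of k modes
with recomputation of each mode as the per-column majority of its members.
Ties in the majority vote resolve to 0 (absence is the prior state for any
condition). Initialisation is Cao's deterministic density method by default
(`init="cao"`); Huang (frequency-weighted sampling) and uniform random
initialisations are available and are used for seeded repeats, since Cao is
deterministic and therefore yields no replicate variability. A cluster that
empties during iteration is reseeded with the point farthest from its mode.
The objective (total matching distance to assigned modes) is recorded per
iteration and is non-increasing.

**PAM k-medoids** uses the classical BUILD + SWAP algorithm on the full
pairwise dissimilarity matrix: BUILD greedily picks medoids that most reduce
total cost; SWAP repeatedly applies the best-improving (medoid, non-medoid)
exchange until no exchange improves the objective. The pairwise matrix is
computed in row blocks (block size 2,048) to bound peak memory; blocking is
exactly equal to the full computation. PAM is deterministic given the data.

**Latent class analysis (LCA)** fits a mixture of Bernoulli products,
P(**x**) = Σₖ πₖ Πⱼ θₖⱼ^xⱼ (1−θₖⱼ)^(1−xⱼ), by EM. The E-step works in the
log domain via logsumexp; item probabilities are clamped to
[10⁻⁶, 1−10⁻⁶] so a cluster can never assign zero likelihood to an observed
profile; EM stops when |Δ log L| < 10⁻⁸ or after 500 iterations. Five random
restarts are run by default and the best log-likelihood kept (k = 1 has a
closed form from column counts and needs no EM). Hard labels are the maximum
a-posteriori classes. BIC = −2 log L + [(k−1) + k·p] ln n.

**AHC** is a native Lance–Williams agglomeration (average linkage by
default; complete linkage and Ward on the binary vectors treated as
Euclidean are variants). When several pairs are tied at the minimal height,
the pair with the lowest row-major index merges first — a fixed, documented
tie rule. Cutting the merge list at k clusters uses union-find with labels
ordered by first appearance. This replaces `scipy.cluster.hierarchy` because
scipy's tie-breaking on the many exactly-tied integer distances that binary
data produce is implementation-defined, and its `maxclust` criterion can
return fewer than k clusters under ties. The native version is deterministic
and O(n³) in the worst case (~6 s at n = 2,500); for much larger cohorts,
cluster a subsample or prefer the partitional methods.

`run_repeats` runs seeded repeats for the stochastic methods (k-modes with
Huang/random init, LCA) and a single run with a "deterministic" note for PAM
and AHC.

## 3. Validity metrics and model selection

Three internal validity metrics are computed per fitted model:

- **Calinski–Harabasz** (higher better): between/within dispersion ratio on
  the 0/1 matrix treated as Euclidean; +∞ sentinel when within-dispersion is
  zero (perfectly duplicated clusters).
- **Davies–Bouldin** (lower better): default `euclidean_binary` variant
  matches the standard definition; a `matching` variant uses L1 distance to
  the cluster centroid. +∞ when two centroids coincide.
- **Silhouette** (higher better): mean of (b−a)/max(a,b) under matching
  dissimilarity (internally the Hamming fraction — silhouette is invariant
  to uniform scaling); singleton members contribute 0. Above 20,000 rows the
  metric is evaluated on a seeded subsample of 10,000 rows, since the
  computation is O(n²).

Repeats of one method at one k are aggregated as mean ± sample standard
deviation (n−1 denominator). The number of clusters k is chosen per method:
a scree elbow (the k whose point lies farthest, in perpendicular distance,
from the chord joining the first and last scree points) for the three
objective-based methods, and minimum BIC for LCA (ties resolve to the
smaller k — parsimony). A flat or linear scree has no elbow; the smallest k
is returned with a warning, and the full scree table is always written so a
human can override.

The cross-method selection rule ranks methods by mean metric rank
(Calinski–Harabasz and silhouette descending, Davies–Bouldin ascending),
records singleton-cluster pathologies in the rationale, then picks the
single run with the highest Calinski–Harabasz within the winning method. The
rule is pluggable: any callable from reports to a `SelectionResult` can be
passed.

## 4. Cluster characterisation (ARF)

For cluster *c* and condition *j*:

ARF(c, j) = prevalence of j in c ÷ prevalence of j in the whole cohort.

The cohort denominator includes zero-condition persons (they are part of the
population whose prevalence is being compared against), so cohort counts and
size can be passed separately from the clustered matrix. ARF is undefined
when the cohort prevalence is zero; such cells are flagged
(`arf_defined = False`) rather than divided.

Inference per cell is a two-sided Fisher exact test on the 2×2 table
(in-cluster vs rest-of-cohort) × (condition present vs absent), using the
point-probability definition (sum of hypergeometric outcomes no more likely
than the observed one, the `scipy.stats.fisher_exact` two-sided rule).
Bonferroni correction uses family size m = (number of clusters) × (number of
conditions) per cohort — the full grid actually tested, not only the cells
reported.

The bubble heatmap shows only significant cells; bubble magnitude is
|log₂ ARF| rounded *up* to the next half step and capped at 2.5 (an ARF of 0
maps to the cap). Over-representation is drawn red, under-representation
blue. SVG output fixes matplotlib's `svg.hashsalt`, so identical inputs give
byte-identical files.

## 5. Survival analysis

The outcome model is a cause-specific Cox proportional-hazards regression
fitted with lifelines (`CoxPHFitter`, Efron tie handling): deaths are
censored at the death time, so hazard ratios are cause-specific, not
subdistribution (Fine–Gray) ratios. Cluster membership enters as dummy
variables with the zero-condition REFERENCE group as the omitted baseline,
whose hazard ratio is exactly 1 by construction. Default adjustment
covariates are age, sex, ethnicity, country and deprivation decile;
categorical covariates are dummy-coded with the first level dropped, and
constant columns are dropped rather than passed to the optimiser.

Persons with the outcome already present at baseline and persons with
missing covariates are excluded *before* fitting, with exact accounting:
n_input = n_used + n_excluded_prior_outcome + n_excluded_missing. A cluster
with no events cannot support an estimate; it is excluded from the fit and
reported in `non_estimable` with `NaN` estimates rather than a spurious
number. Confidence intervals are Wald intervals on the log hazard ratio.
`build_survival_cohort` validates the partition: a labelled person must
carry ≥ 1 condition and every conditioned person must be labelled.

`hr_vs_burden_summary` tabulates, per cluster, size, mean/quartile condition
counts and the fitted hazard ratio, with an optional error-bar scatter —
the "does more morbidity mean more hazard?" view.

## 6. Synthetic-cohort generator

### What it emulates

- Latent-class comorbidity structure: each conditioned person draws a class
  from `class_weights` and a profile of independent Bernoullis from that
  class's probability row. Classes with distinct high-probability condition
  blocks produce the planted clusters every recovery test relies on.
- A `zero_condition_fraction` reference group (latent class −1, profile
  forced to zero).
- Conditioned persons are guaranteed ≥ 1 condition: all-zero draws are
  resampled up to 100 times, then the generator fails loudly (this only
  happens when the class profile makes all-zero overwhelmingly likely, which
  is a spec problem, not noise).
- Competing risks: independent exponential times for outcome
  (rate = `baseline_rate`·exp(class log-HR)) and death (rate =
  `death_rate`), administratively censored at `censor_time`; the earliest
  wins. Because the hazards are proportional and constant by construction,
  planted hazard ratios are exactly the Cox estimand.
- Demographics: truncated-normal age, categorical sex/ethnicity/country/
  deprivation; `age_shift_per_class` adds class-dependent mean age as a
  confounding hook; `missing_fraction` blanks covariates at random;
  `prior_outcome_fraction` marks baseline outcomes for exclusion tests.

### What it does not emulate

- Conditions are independent *within* a class; real comorbidity has residual
  within-class correlation.
- Hazards are exponential (constant over time); no frailty,
  non-proportionality, or time-varying condition onset — conditions are
  fixed at baseline.
- Covariates (except the optional age shift) are independent of class, so
  real-world confounding structure is mostly absent by default.
- No measurement error in condition ascertainment and no informative
  censoring.

### Key defaults

| Parameter | Default | Rationale |
|---|---|---|
| `age_mean`, `age_sd`, range | 57, 8, [37, 73] | middle-aged volunteer cohort |
| `female_fraction` | 0.54 | typical volunteer-cohort skew |
| `baseline_rate` | 0.01 /yr | ~10% 10-year cumulative outcome incidence in the reference group |
| `death_rate` | 0.005 /yr | competing mortality half the outcome rate |
| `censor_time` | 10 yr | fixed administrative follow-up |
| demo spec | 4 classes × 5-condition blocks, p = 20, block prob 0.6, background 0.05 | separable but not trivial planted structure |
| demo `zero_condition_fraction` | 0.15 | a substantial reference group |
| demo class hazard ratios | 1.3, 1.6, 2.0, 2.4 | monotone burden-hazard gradient |

## 7. Numerical choices and determinism

- All randomness flows through `numpy.random.default_rng(seed)`; derived
  seeds stay below 2³¹. Identical spec/config + seed reproduces every value
  (cohorts bit-for-bit, pipeline artefacts value-identical; covered by
  tests).
- Fixed tie rules everywhere a tie can occur: mode ties → 0, BIC ties →
  smaller k, AHC merge ties → lowest row-major pair, elbow of a flat scree →
  smallest k with a warning.
- LCA: log-domain E-step (logsumexp), probability clamp 10⁻⁶, |Δ log L| <
  10⁻⁸ convergence, multiple restarts against local optima.
- Silhouette subsampling threshold 20,000 / size 10,000, seeded.
- Fisher p-values are clipped to (0, 1]; Bonferroni refuses a family smaller
  than the number of tests it is handed.
- Cox: Efron ties (appropriate for the heavily tied event times a yearly
  scale produces), lifelines defaults otherwise.

## 8. Design decisions

- **Native k-modes / PAM / LCA / AHC** rather than third-party clustering
  packages: none of the required variants (matching dissimilarity, the tie
  rules above) is available in the preinstalled stack, and small-instance
  brute-force oracles in the test suite verify the implementations
  end-to-end. Metrics with a trusted reference (Calinski–Harabasz,
  silhouette) go through scikit-learn; Davies–Bouldin is native because the
  matching variant is not expressible there, and it is tested against
  scikit-learn in the Euclidean case.
- **Cause-specific, not subdistribution, hazards**: the scientific question
  is etiological (does cluster membership raise the outcome hazard among
  those still alive), for which censoring at death is the standard choice.
- **Bonferroni rather than FDR**: conservative, simple, and matches the
  exploratory bubble-map use where a false highlight is worse than a missed
  one; the raw p-values are always in the table for re-adjustment.
- **Bubble size as discretised |log₂ ARF|**: half-step bins with a cap keep
  extreme enrichments from dominating the figure while preserving ordering.
- **Library + thin CLI**: every capability is a plain importable function;
  the `mmclust` command wraps them for file-based use without hiding any
  option that matters.

## 9. Limitations

- AHC is O(n³) time / O(n²) memory; practical to a few thousand persons.
- Internal validity metrics on binary data reward compact, balanced
  clusters; they can disagree with epidemiological usefulness, which is why
  the selection rationale and full metric tables are always emitted rather
  than a silent argmax.
- Deterministic Cao-initialised k-modes has no replicate variability and can
  land in a local optimum on moderately separated data; the pipeline's
  seeded repeats mitigate but do not eliminate this.
- The Cox model assumes proportional hazards and baseline-fixed cluster
  membership; no time-varying covariates or left truncation are supported.
- The generator's independence assumptions (Section 6) mean that pipeline
  behaviour on real cohorts with correlated conditions, informative
  censoring, or stronger confounding is not certified by the test suite.
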