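# mmclust

Cluster analysis of multimorbidity — the co-occurrence of multiple long-term
health conditions — and its consequences for a subsequent health outcome such
as depression.

Epidemiological cohorts increasingly record, for each person, a binary profile
over dozens of long-term conditions. Two questions follow: do conditions
co-occur in reproducible *clusters* of people, and do people in different
clusters face different hazards of a later outcome? `mmclust` implements that
workflow end to end for researchers and biostatisticians:

1. **Clustering** binary condition profiles with four methods suited to
   categorical data: k-modes, PAM k-medoids, latent class analysis (LCA), and
   agglomerative hierarchical clustering (AHC).
2. **Model selection** across methods and numbers of clusters via internal
   validity metrics (Calinski–Harabasz, Davies–Bouldin, silhouette), scree
   elbows for the partitional methods and BIC for LCA.
3. **Cluster characterisation** with the adjusted relative frequency (ARF)
   statistic plus two-sided Fisher exact tests under Bonferroni correction,
   visualised as a bubble heatmap.
4. **Survival analysis**: cause-specific Cox proportional-hazards models of
   the subsequent outcome, with persons carrying *no* conditions as the
   reference group (hazard ratio fixed at 1) and death treated as censoring.
5. A **synthetic-cohort generator** — a latent-class Bernoulli mixture with
   competing-risk event times — that provides planted ground truth for every
   stage, so each estimate can be checked against a known answer.

## Model sketch

Each person *i* has a binary vector **x**ᵢ ∈ {0,1}ᵖ over *p* conditions.
k-modes and k-medoids minimise total matching dissimilarity
d(**x**, **y**) = Σⱼ 1[xⱼ ≠ yⱼ] to cluster modes/medoids; AHC merges by
average linkage on the same dissimilarity; LCA fits the mixture
P(**x**) = Σₖ πₖ Πⱼ θₖⱼ^xⱼ (1−θₖⱼ)^(1−xⱼ) by EM and assigns each person to
the most probable class. For cluster *c* and condition *j*,
ARF = prevalence of *j* in *c* ÷ prevalence of *j* in the whole cohort
(including zero-condition persons). The survival stage fits
λᵢ(t) = λ₀(t) · exp(β·cluster(i) + γ·covariates(i)) for the outcome, with
death censored at the death time (cause-specific formulation) and the
zero-condition group as baseline.

## Worked example

`examples/` contains one short narrative script per capability. Running
`python examples/02_cluster_and_select.py` (simulate a planted four-class
cohort of 2,000 clustered persons, fit all four methods at k = 4, select the
best) prints:

```
method    ARI vs truth        CH      DB  silhouette
kmodes           0.398     262.1   1.831       0.268
kmedoids         0.903     344.7   1.575       0.392
lca              0.888     345.2   1.558       0.392
ahc              0.605     191.4   1.875       0.255

selected method: lca at k=4
```

LCA and k-medoids recover the planted classes closely; the selection rule
picks LCA by mean metric rank. (Single deterministic k-modes/AHC runs can
land in local optima at this moderate class separation, which is why the full
pipeline runs several seeded repeats per method.)

`python examples/04_survival_hazards.py` fits the cause-specific Cox model on
a 20,000-person cohort with planted hazard ratios 1.3/1.6/2.0/2.4 and prints:

```
cluster         n  events     HR           95% CI  true HR
REFERENCE    2908     299   1.00     [1.00, 1.00]     1.00
0            3929     552   1.40     [1.21, 1.61]     1.30
1            4157     716   1.75     [1.53, 2.01]     1.60
2            3984     843   2.20     [1.93, 2.51]     2.00
3            4006     966   2.55     [2.24, 2.90]     2.40
```

Every confidence interval brackets its planted truth.

The whole workflow in one call (`examples/05_full_pipeline.py`, or
`mmclust run-all --config pipeline.yaml` from the shell) writes a validity
report, selection record, cluster labels, ARF table, bubble heatmap, survival
fit and hazard-vs-burden summary per stratum, plus a run manifest; rerunning
with the same configuration and seed reproduces every value exactly.

## Command-line interface

```bash
mmclust simulate --spec cohort.yaml --out cohort_dir/
mmclust cluster  --conditions conditions.csv --method kmodes --k 4 --out models/
mmclust select   --conditions conditions.csv --models models/ --out selection.json
mmclust represent --conditions conditions.csv --labels labels.csv --out arf/
mmclust survive  --cohort cohort_dir/ --labels labels.csv --out survival/
mmclust run-all  --config pipeline.yaml --out results/
```

Validation errors exit with code 2, computational failures with code 3.

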