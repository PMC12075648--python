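"""Cluster binary condition profiles with four methods and pick the best model.

Runs k-modes, PAM k-medoids, latent class analysis (LCA) and agglomerative
hierarchical clustering (AHC) at the same k, evaluates each partition with
three validity metrics, and applies the default rank-aggregation selection
rule. On this planted four-class cohort LCA and k-medoids recover the truth
closely; a single deterministic k-modes or AHC run can land in a local
optimum at this moderate class separation, which is why the full pipeline
runs several seeded repeats per method and selects among all runs.
"""

from sklearn.metrics import adjusted_rand_score

from mmclust import (
    ConditionMatrix,
    ahc_fit,
    default_demo_spec,
    evaluate_model,
    kmedoids_fit,
    kmodes_fit,
    lca_fit,
    select_best,
    simulate_cohort,
)

cohort = simulate_cohort(default_demo_spec(seed=1, n_persons=2000))
values, persons = cohort.clustered_subset()
X = ConditionMatrix(values, cohort.condition_names, persons["person_id"].tolist())
truth = persons["true_class"].to_numpy()

k = 4
models = {
    "kmodes": kmodes_fit(X, k, init="cao"),
    "kmedoids": kmedoids_fit(X, k),
    "lca": lca_fit(X, k, seed=0),
    "ahc": ahc_fit(X, k),
}

print(f"{'method':<9} {'ARI vs truth':>12} {'CH':>9} {'DB':>7} {'silhouette':>11}")
reports = {}
for name, model in models.items():
    report = evaluate_model(X, model)
    reports[name] = report
    print(
        f"{name:<9} {adjusted_rand_score(truth, model.labels):>12.3f} "
        f"{report.calinski_harabasz:>9.1f} {report.davies_bouldin:>7.3f} "
        f"{report.silhouette:>11.3f}"
    )

result = select_best(list(reports.values()))
print()
print(f"selected method: {result.chosen_method} at k={result.chosen_k}")
print(f"mean metric ranks: {result.rationale['method_mean_ranks']}")
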