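"""Characterise clusters with adjusted relative frequencies (ARF).

For every (cluster, condition) pair the ARF is the condition's prevalence in
the cluster divided by its prevalence in the whole cohort: ARF > 1 means the
condition is over-represented. A two-sided Fisher exact test with Bonferroni
correction (family = clusters x conditions) flags significant pairs, and a
bubble heatmap shows them with bubble size proportional to |log2 ARF|.
"""

from pathlib import Path

from mmclust import (
    ConditionMatrix,
    bubble_heatmap,
    compute_arf,
    default_demo_spec,
    kmodes_fit,
    simulate_cohort,
)

cohort = simulate_cohort(default_demo_spec(seed=1, n_persons=2000))
values, persons = cohort.clustered_subset()
X = ConditionMatrix(values, cohort.condition_names, persons["person_id"].tolist())

model = kmodes_fit(X, 4, init="cao")

# The ARF denominator is the full cohort, including zero-condition persons.
counts = {name: int(c) for name, c in
          zip(cohort.condition_names, cohort.condition_matrix.sum(axis=0))}
table = compute_arf(
    X, model.labels, cohort_counts=counts, cohort_size=len(cohort.persons)
)

sig = table[table["significant"]].sort_values("arf", ascending=False)
print(f"tested pairs:               {len(table)}")
print(f"Bonferroni family size:     {model.k * len(X.condition_names)}")
print(f"significant after correction: {len(sig)} "
      f"({(sig['direction'] == 'over').sum()} over, "
      f"{(sig['direction'] == 'under').sum()} under)")
print()
print("strongest over-represented conditions per cluster:")
top = (sig[sig["direction"] == "over"]
       .groupby("cluster", group_keys=False)
       .head(3))
print(top[["cluster", "condition", "cluster_prevalence", "cohort_prevalence",
           "arf", "p_adjusted"]].to_string(index=False))

out = Path("scratch_outputs")
out.mkdir(exist_ok=True)
bubble_heatmap(table, out / "bubble_heatmap.svg")
print(f"\nbubble heatmap written to {out / 'bubble_heatmap.svg'}")
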