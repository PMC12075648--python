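"""Over/under-representation of conditions within clusters.

The adjusted relative frequency (ARF) of a condition in a cluster is the
prevalence of the condition in the cluster divided by its prevalence in the
whole cohort. ARF = 1 means the condition occurs at the cohort rate; values
above/below 1 mark over-/under-representation. Because it divides by cohort
prevalence, the ARF puts generally rare and generally common conditions on
the same scale.

Significance of each cluster x condition cell is assessed with a two-sided
Fisher exact test on the 2x2 table (in-cluster vs rest-of-cohort) x
(condition present vs absent), Bonferroni-corrected across all tests in the
cohort (clusters x conditions, the conservative family). The cohort
denominator may include zero-condition persons, so it can exceed the
clustered population.

Significant cells are drawn on a bubble heatmap: bubble area encodes an
ordinal magnitude (|log2 ARF| binned to half-steps, capped at 2.5), with
separate colours for over- and under-representation.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from mmclust.clustering import ConditionMatrix

logger = logging.getLogger(__name__)

BUBBLE_CAP = 2.5


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided by point-probability summation: the p-value sums the
    hypergeometric probabilities of every table with the same margins whose
    point probability does not exceed that of the observed table (relative
    float ties tolerated at ~1e-7).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table counts must be non-negative integers")
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: each p mapped to min(1, m * p)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size and (np.any(ps < 0) or np.any(ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(ps):
        raise ValueError("family size m must cover every test performed")
    return [float(min(1.0, m * p)) for p in ps]


def bubble_transform(arf: float) -> float:
    """Ordinal bubble magnitude: |log2 ARF| rounded up to half-steps.

    ARF = 1 maps to 0 (no bubble); ARF of 2 and 1/2 map to the same
    magnitude with opposite directions; the scale caps at 2.5 (ARF beyond
    ~5.7-fold). Monotone non-decreasing in |log2 ARF|.
    """
    if arf is None or not np.isfinite(arf) or arf < 0:
        raise ValueError("arf must be a finite non-negative number")
    if arf == 0:
        return BUBBLE_CAP
    mag = abs(math.log2(arf))
    if mag == 0:
        return 0.0
    return float(min(BUBBLE_CAP, math.ceil(mag * 2 - 1e-12) / 2))


def compute_arf(
    X: ConditionMatrix,
    labels,
    cohort_counts: Mapping[str, int] | None = None,
    cohort_size: int | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """ARF table: one row per (cluster, condition) with exact-test inference.

    ``cohort_counts``/``cohort_size`` give the per-condition counts and the
    denominator for the whole cohort, which may include zero-condition
    persons not present in ``X``; by default the clustered population itself
    is the cohort. Conditions absent from the whole cohort get an undefined
    ARF (``arf_defined`` False) rather than a division by zero.

    Columns: cluster, condition, n_in_cluster_with_condition, cluster_size,
    cohort_count_with_condition, cohort_size, cluster_prevalence,
    cohort_prevalence, arf, arf_defined, direction, p_raw, p_adjusted,
    significant, bubble_magnitude.
    """
    labels = np.asarray(labels)
    if labels.shape != (X.n_persons,):
        raise ValueError("labels must partition the rows of X")
    clusters = np.unique(labels)
    names = X.condition_names
    data = X.values

    clustered_counts = {
        name: int(data[:, j].sum()) for j, name in enumerate(names)
    }
    if cohort_counts is None:
        cohort_counts = clustered_counts
        cohort_size = X.n_persons
    else:
        missing = [n for n in names if n not in cohort_counts]
        if missing:
            raise ValueError(f"cohort_counts missing conditions: {missing[:5]}")
        if cohort_size is None:
            raise ValueError("cohort_size is required with explicit cohort_counts")
        if cohort_size < X.n_persons:
            raise ValueError("cohort_size cannot be smaller than the clustered n")

    m = family_size if family_size is not None else len(clusters) * len(names)
    rows = []
    for cl in clusters:
        in_cluster = labels == cl
        size = int(in_cluster.sum())
        cond_counts = data[in_cluster].sum(axis=0)
        for j, name in enumerate(names):
            a = int(cond_counts[j])
            n_cohort = int(cohort_counts[name])
            cluster_prev = a / size
            cohort_prev = n_cohort / cohort_size
            defined = cohort_prev > 0
            arf = cluster_prev / cohort_prev if defined else np.nan
            if not defined or arf == 1.0:
                direction = "none"
            else:
                direction = "over" if arf > 1.0 else "under"
            # 2x2: (in cluster / rest of cohort) x (condition present / absent)
            b = size - a
            c = n_cohort - a
            d = (cohort_size - size) - c
            p_raw = fisher_exact_two_sided(a, b, c, d)
            p_adj = min(1.0, m * p_raw)
            rows.append(
                {
                    "cluster": cl,
                    "condition": name,
                    "n_in_cluster_with_condition": a,
                    "cluster_size": size,
                    "cohort_count_with_condition": n_cohort,
                    "cohort_size": cohort_size,
                    "cluster_prevalence": cluster_prev,
                    "cohort_prevalence": cohort_prev,
                    "arf": arf,
                    "arf_defined": defined,
                    "direction": direction,
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "significant": bool(defined and p_adj < alpha),
                    "bubble_magnitude": bubble_transform(arf) if defined else np.nan,
                }
            )
    return pd.DataFrame(rows)


def bubble_heatmap(
    table: pd.DataFrame,
    out_path: str | Path,
    condition_order: Sequence[str] | None = None,
    over_color: str = "#c0392b",
    under_color: str = "#2e6da4",
) -> Path:
    """Bubble heatmap of significant over/under-represented conditions.

    Conditions on the y axis (alphabetical unless ``condition_order`` gives a
    clinical grouping), clusters on the x axis; bubble area encodes the
    ordinal magnitude, colour the direction; only significant cells are
    drawn. SVG output is byte-stable for fixed inputs and library versions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    conditions = (
        list(condition_order)
        if condition_order is not None
        else sorted(table["condition"].unique())
    )
    clusters = sorted(table["cluster"].unique())
    cond_idx = {c: i for i, c in enumerate(conditions)}
    clus_idx = {c: i for i, c in enumerate(clusters)}
    sig = table[table["significant"] & table["arf_defined"]]

    fig_h = max(3.0, 0.28 * len(conditions) + 1.5)
    fig_w = max(4.0, 0.9 * len(clusters) + 2.5)
    with plt.rc_context({"svg.hashsalt": "mmclust"}):
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
        for _, row in sig.sort_values(["condition", "cluster"]).iterrows():
            mag = row["bubble_magnitude"]
            if mag <= 0:
                continue
            ax.scatter(
                clus_idx[row["cluster"]],
                cond_idx[row["condition"]],
                s=60.0 * mag,
                color=over_color if row["direction"] == "over" else under_color,
                alpha=0.85,
                edgecolors="none",
            )
        ax.set_xticks(range(len(clusters)))
        ax.set_xticklabels([f"cluster {c}" for c in clusters], rotation=45, ha="right")
        ax.set_yticks(range(len(conditions)))
        ax.set_yticklabels(conditions, fontsize=7)
        ax.set_xlim(-0.5, len(clusters) - 0.5)
        ax.set_ylim(-0.5, len(conditions) - 0.5)
        ax.invert_yaxis()
        ax.set_title("Condition over/under-representation by cluster")
        fig.tight_layout()
        fig.savefig(out_path, metadata={"Date": None} if out_path.suffix == ".svg" else None)
        plt.close(fig)
    return out_path
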