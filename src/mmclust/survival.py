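"""Cluster-conditional time-to-event analysis with a no-condition reference.

Cause-specific Cox proportional hazards for the outcome of interest
(subsequent depression in the motivating application), with death as a
competing risk handled by censoring at death time (the cause-specific
formulation). Cluster membership enters as a categorical covariate with the
zero-condition reference group as baseline; models adjust for baseline age
(continuous) and for sex, ethnicity, country and deprivation decile
(categorical). Persons with the outcome already present at baseline are
excluded, as are persons missing any adjustment covariate; both exclusions
are counted so that n_input = n_used + n_prior_outcome + n_missing exactly.

Hazard ratios are exp(coef) with Wald 95% confidence intervals on the
log-hazard scale; event-time ties use the Efron approximation (the
lifelines default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

logger = logging.getLogger(__name__)

REFERENCE = "REFERENCE"
DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "country", "deprivation_decile")
CATEGORICAL_COVARIATES = ("sex", "ethnicity", "country", "deprivation_decile")


class SurvivalDataError(ValueError):
    pass


@dataclass
class SurvivalFit:
    """Per-cluster hazard ratios plus the full covariate table and accounting."""

    cluster_table: pd.DataFrame  # cluster, n, events, hazard_ratio, ci_low, ci_high
    covariate_table: pd.DataFrame
    n_used: int
    n_events: int
    n_excluded_prior_outcome: int
    n_excluded_missing: int
    non_estimable: list = field(default_factory=list)

    def hazard_ratio(self, cluster) -> float:
        row = self.cluster_table.loc[self.cluster_table["cluster"] == cluster]
        if row.empty:
            raise KeyError(f"no cluster {cluster!r} in fit")
        return float(row["hazard_ratio"].iloc[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_table": self.cluster_table.to_dict(orient="records"),
            "covariate_table": self.covariate_table.reset_index().to_dict(
                orient="records"
            ),
            "n_used": self.n_used,
            "n_events": self.n_events,
            "n_excluded_prior_outcome": self.n_excluded_prior_outcome,
            "n_excluded_missing": self.n_excluded_missing,
            "non_estimable": self.non_estimable,
        }
        Path(path).write_text(json.dumps(payload, default=str))


def build_survival_cohort(
    persons: pd.DataFrame,
    condition_matrix: np.ndarray,
    labels: Mapping[str, int] | pd.Series,
    baseline_outcome_flags: Sequence[bool] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the analysis table: cluster label (or REFERENCE), covariates,
    follow-up time and event type, with exclusion accounting.

    ``labels`` maps person_id -> cluster for every person with at least one
    condition; zero-condition persons must be absent from ``labels`` and are
    assigned the REFERENCE group. A person with conditions but no label is a
    partition violation and raises. Persons flagged as having the outcome at
    baseline are dropped (counted), then rows missing any requested covariate
    are dropped (counted).

    Returns ``(records, accounting)`` where accounting holds n_input, n_used,
    n_excluded_prior_outcome, n_excluded_missing.
    """
    persons = persons.reset_index(drop=True)
    n_input = len(persons)
    condition_counts = np.asarray(condition_matrix).sum(axis=1)
    if len(condition_counts) != n_input:
        raise SurvivalDataError("condition_matrix rows must match persons")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()

    if baseline_outcome_flags is None:
        baseline_outcome_flags = (
            persons["prior_outcome"].to_numpy().astype(bool)
            if "prior_outcome" in persons
            else np.zeros(n_input, dtype=bool)
        )
    prior = np.asarray(baseline_outcome_flags, dtype=bool)

    cluster_col = []
    for pid, n_cond in zip(persons["person_id"], condition_counts):
        if n_cond == 0:
            if pid in labels:
                raise SurvivalDataError(
                    f"zero-condition person {pid} must not carry a cluster label"
                )
            cluster_col.append(REFERENCE)
        else:
            if pid not in labels:
                raise SurvivalDataError(
                    f"person {pid} has conditions but no cluster label "
                    "(partition violated)"
                )
            cluster_col.append(int(labels[pid]))
    df = persons.copy()
    df["cluster"] = cluster_col
    df["n_conditions"] = condition_counts

    df = df.loc[~prior]
    n_prior = int(prior.sum())

    missing = df[list(covariates)].isna().any(axis=1)
    n_missing = int(missing.sum())
    df = df.loc[~missing].copy()

    if (df["event_time"] <= 0).any():
        raise SurvivalDataError("follow-up time must be positive")
    bad = ~df["event_type"].isin(["outcome", "death", "censored"])
    if bad.any():
        raise SurvivalDataError("event_type must be outcome, death or censored")

    accounting = {
        "n_input": n_input,
        "n_used": len(df),
        "n_excluded_prior_outcome": n_prior,
        "n_excluded_missing": n_missing,
    }
    assert accounting["n_input"] == (
        accounting["n_used"] + n_prior + n_missing
    )
    return df.reset_index(drop=True), accounting


def fit_cause_specific_cox(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    accounting: dict | None = None,
) -> SurvivalFit:
    """Cause-specific Cox model for the outcome, deaths censored at death time.

    Cluster membership is categorical with the REFERENCE group as baseline
    (its hazard ratio is identically 1 and not estimated). A cluster with no
    outcome events is reported as non-estimable with a diagnostic rather
    than fitted.
    """
    if REFERENCE not in set(records["cluster"].astype(str)):
        raise SurvivalDataError("REFERENCE group is empty; model needs a baseline")
    df = records.copy()
    df["cluster"] = df["cluster"].astype(str)
    df["event_observed"] = (df["event_type"] == "outcome").astype(int)

    events_by_cluster = df.groupby("cluster")["event_observed"].sum()
    non_estimable = [
        c for c, e in events_by_cluster.items() if e == 0 and c != REFERENCE
    ]
    if non_estimable:
        logger.warning(
            "clusters with zero outcome events reported non-estimable: %s",
            non_estimable,
        )
    fit_df = df[~df["cluster"].isin(non_estimable)].copy()

    design = pd.DataFrame(
        {"time": fit_df["event_time"].astype(float), "event": fit_df["event_observed"]}
    )
    cluster_levels = [
        c for c in sorted(fit_df["cluster"].unique(), key=str) if c != REFERENCE
    ]
    for level in cluster_levels:
        design[f"cluster_{level}"] = (fit_df["cluster"] == level).astype(float)
    for cov in covariates:
        if cov not in fit_df:
            raise SurvivalDataError(f"missing covariate column {cov!r}")
        if cov in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(
                fit_df[cov].astype(str), prefix=cov, drop_first=True, dtype=float
            )
            design = pd.concat([design, dummies], axis=1)
        else:
            design[cov] = fit_df[cov].astype(float)
    # drop constant columns (single-level categoricals cannot be estimated)
    constant = [
        c for c in design.columns
        if c not in ("time", "event") and design[c].nunique() <= 1
    ]
    design = design.drop(columns=constant)

    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    summary = cph.summary

    rows = []
    counts = df.groupby("cluster").agg(
        n=("event_observed", "size"), events=("event_observed", "sum")
    )
    rows.append(
        {
            "cluster": REFERENCE,
            "n": int(counts.loc[REFERENCE, "n"]),
            "events": int(counts.loc[REFERENCE, "events"]),
            "hazard_ratio": 1.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "estimable": True,
        }
    )
    for level in cluster_levels:
        name = f"cluster_{level}"
        rows.append(
            {
                "cluster": level,
                "n": int(counts.loc[level, "n"]),
                "events": int(counts.loc[level, "events"]),
                "hazard_ratio": float(summary.loc[name, "exp(coef)"]),
                "ci_low": float(summary.loc[name, "exp(coef) lower 95%"]),
                "ci_high": float(summary.loc[name, "exp(coef) upper 95%"]),
                "estimable": True,
            }
        )
    for level in non_estimable:
        rows.append(
            {
                "cluster": level,
                "n": int(counts.loc[level, "n"]) if level in counts.index else 0,
                "events": 0,
                "hazard_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "estimable": False,
            }
        )
    cluster_table = pd.DataFrame(rows)
    acc = accounting or {}
    return SurvivalFit(
        cluster_table=cluster_table,
        covariate_table=summary.loc[
            [c for c in summary.index if not c.startswith("cluster_")]
        ],
        n_used=int(len(fit_df)),
        n_events=int(fit_df["event_observed"].sum()),
        n_excluded_prior_outcome=int(acc.get("n_excluded_prior_outcome", 0)),
        n_excluded_missing=int(acc.get("n_excluded_missing", 0)),
        non_estimable=non_estimable,
    )


def hr_vs_burden_summary(
    fit: SurvivalFit,
    records: pd.DataFrame,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-cluster condition burden vs hazard ratio, with an optional scatter.

    For every cluster (including REFERENCE, anchored at mean burden 0 and
    hazard ratio 1) the table reports the mean number of conditions, its
    quartiles and interquartile range, cluster size and share, and the
    hazard ratio with its confidence interval. ``out_path`` draws hazard
    ratio against mean burden with CI error bars.
    """
    df = records.copy()
    df["cluster"] = df["cluster"].astype(str)
    rows = []
    total = len(df)
    for _, hr_row in fit.cluster_table.iterrows():
        cl = str(hr_row["cluster"])
        member = df.loc[df["cluster"] == cl, "n_conditions"]
        if member.empty:
            continue
        q1, q2, q3 = np.percentile(member, [25, 50, 75])
        rows.append(
            {
                "cluster": cl,
                "n": int(len(member)),
                "pct_of_cohort": 100.0 * len(member) / total,
                "mean_conditions": float(member.mean()),
                "q1_conditions": float(q1),
                "median_conditions": float(q2),
                "q3_conditions": float(q3),
                "iqr_conditions": float(q3 - q1),
                "hazard_ratio": hr_row["hazard_ratio"],
                "ci_low": hr_row["ci_low"],
                "ci_high": hr_row["ci_high"],
            }
        )
    table = pd.DataFrame(rows)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        with plt.rc_context({"svg.hashsalt": "mmclust"}):
            fig, ax = plt.subplots(figsize=(6, 4.5))
            est = table.dropna(subset=["hazard_ratio"])
            yerr = np.stack(
                [
                    est["hazard_ratio"] - est["ci_low"],
                    est["ci_high"] - est["hazard_ratio"],
                ]
            )
            ax.errorbar(
                est["mean_conditions"], est["hazard_ratio"], yerr=yerr,
                fmt="o", capsize=3, color="#34495e",
            )
            ax.axhline(1.0, color="grey", lw=0.8, ls="--")
            ax.set_xlabel("mean conditions per participant in cluster")
            ax.set_ylabel("hazard ratio vs no-condition reference")
            ax.set_title("Outcome hazard by cluster condition burden")
            fig.tight_layout()
            fig.savefig(out_path)
            plt.close(fig)
    return table
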