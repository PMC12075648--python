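"""End-to-end orchestration: simulate -> cluster -> select -> represent -> survive.

A :class:`PipelineConfig` (built in code or loaded from YAML) names the
cohort source (a synthetic-cohort spec or CSV paths), the strata to analyse
(generic covariate filters with optional per-stratum condition exclusions,
so a whole/women/men design is one config), the clustering methods and
k-grid, repeat counts and seeds, the enrichment alpha, and survival options.

For each stratum the pipeline writes a validity report (method comparison
table), the selection trace, the ARF table and bubble heatmap, a cluster
size/burden summary, and the survival fit with its burden-vs-hazard table
and plot, plus one machine-readable run manifest recording versions, seeds
and a config hash. Strata are analysed independently: adding or removing a
stratum leaves the others' results unchanged. Any stage failure aborts with
the stage name; partial outputs persist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mmclust import __version__
from mmclust.clustering import (
    ClusterModel,
    ConditionMatrix,
    ahc_fit,
    ahc_linkage,
    kmedoids_fit,
    lca_fit,
    run_repeats,
)
from mmclust.model_selection import (
    aggregate_repeats,
    bic_select,
    evaluate_model,
    scree_elbow,
    select_best,
)
from mmclust.representation import bubble_heatmap, compute_arf
from mmclust.survival import (
    build_survival_cohort,
    fit_cause_specific_cox,
    hr_vs_burden_summary,
)
from mmclust.synthetic_cohort import (
    CohortSpec,
    SyntheticCohort,
    default_demo_spec,
    read_cohort,
    simulate_cohort,
    spec_from_dict,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class StratumConfig:
    """A covariate-defined subpopulation with optional condition exclusions."""

    name: str = "whole"
    filters: dict = field(default_factory=dict)  # column -> required value
    exclude_conditions: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    cohort_spec: CohortSpec | None = None
    cohort_dir: str | None = None
    strata: list = field(default_factory=lambda: [StratumConfig()])
    methods: list = field(default_factory=lambda: ["kmodes", "kmedoids", "lca", "ahc"])
    k_grid: list = field(default_factory=lambda: list(range(2, 9)))
    n_repeats: int = 5
    seed: int = 0
    alpha: float = 0.05
    selection_rule: str = "default"
    survival_covariates: list = field(
        default_factory=lambda: ["age", "sex", "ethnicity", "country",
                                 "deprivation_decile"]
    )
    make_plots: bool = True
    out_dir: str = "mmclust_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        spec = raw.pop("cohort_spec", None)
        strata = [
            StratumConfig(**s) if isinstance(s, dict) else s
            for s in raw.pop("strata", [{}])
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(
            cohort_spec=spec_from_dict(spec) if isinstance(spec, dict) else spec,
            strata=strata,
            **raw,
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_demo_config(seed: int = 0, out_dir: str = "mmclust_output",
                        n_persons: int = 3000) -> PipelineConfig:
    """A small single-stratum configuration that runs end-to-end in minutes."""
    return PipelineConfig(
        cohort_spec=default_demo_spec(seed=seed, n_persons=n_persons),
        strata=[StratumConfig(name="whole")],
        methods=["kmodes", "kmedoids", "lca", "ahc"],
        k_grid=list(range(2, 7)),
        n_repeats=5,
        seed=seed,
        out_dir=out_dir,
    )


def _load_cohort(config: PipelineConfig) -> SyntheticCohort:
    if config.cohort_spec is not None:
        return simulate_cohort(config.cohort_spec)
    if config.cohort_dir is not None:
        return read_cohort(config.cohort_dir)
    raise ValueError("config needs either cohort_spec or cohort_dir")


def _stratum_frame(cohort: SyntheticCohort, stratum: StratumConfig):
    persons = cohort.persons.reset_index(drop=True)
    mask = np.ones(len(persons), dtype=bool)
    for col, value in stratum.filters.items():
        if col not in persons:
            raise ValueError(f"stratum filter column {col!r} not in persons table")
        mask &= (persons[col] == value).to_numpy()
    keep_conditions = [
        (j, name)
        for j, name in enumerate(cohort.condition_names)
        if name not in set(stratum.exclude_conditions)
    ]
    unknown = set(stratum.exclude_conditions) - set(cohort.condition_names)
    if unknown:
        raise ValueError(f"excluded conditions not in condition list: {sorted(unknown)}")
    cols = [j for j, _ in keep_conditions]
    names = [name for _, name in keep_conditions]
    X_all = cohort.condition_matrix[mask][:, cols]
    sub_persons = persons.loc[mask].reset_index(drop=True)
    return sub_persons, X_all, names


def _select_k(method: str, X: ConditionMatrix, k_grid, seed: int) -> int:
    """Per-method cluster-number heuristic: scree elbow on the clustering cost
    for k-modes, k-medoids and AHC; minimal BIC for LCA."""
    if method == "lca":
        models = {
            k: lca_fit(X, k, n_starts=2, seed=seed + k) for k in k_grid
        }
        return bic_select(models)
    costs = {}
    merges = ahc_linkage(X) if method == "ahc" else None
    for k in k_grid:
        if method == "kmodes":
            m = run_repeats("kmodes", X, k, n_repeats=1, seeds=[seed])[0]
        elif method == "kmedoids":
            m = kmedoids_fit(X, k)
        elif method == "ahc":
            m = ahc_fit(X, k, merges=merges)
        else:
            raise ValueError(f"unknown method {method!r}")
        costs[k] = m.objective
    return scree_elbow(costs)


def _fit_stratum_models(
    config: PipelineConfig, X: ConditionMatrix, stratum_seed: int
) -> tuple[list[ClusterModel], list, dict]:
    models: list[ClusterModel] = []
    reports = []
    chosen_k: dict[str, int] = {}
    for method in config.methods:
        k = _select_k(method, X, config.k_grid, stratum_seed)
        chosen_k[method] = k
        seeds = [stratum_seed + 1000 * i for i in range(config.n_repeats)]
        fitted = run_repeats(method, X, k, n_repeats=config.n_repeats, seeds=seeds)
        for m in fitted:
            models.append(m)
            reports.append(evaluate_model(X, m, silhouette_seed=stratum_seed))
    return models, reports, chosen_k


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every stratum; returns the result bundle.

    The bundle maps stratum name -> dict with keys ``validity`` (DataFrame),
    ``selection``, ``model`` (the chosen ClusterModel), ``arf`` (DataFrame),
    ``survival`` (SurvivalFit), ``burden`` (DataFrame); plus a top-level
    ``manifest``. All artefacts are also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        cohort = _load_cohort(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    results: dict = {}
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "strata": {},
        "timings_s": {},
    }
    for stratum in config.strata:
        sdir = out / stratum.name
        sdir.mkdir(parents=True, exist_ok=True)
        stratum_seed = config.seed
        t_str = time.time()
        stage = f"{stratum.name}:prepare"
        try:
            persons, X_all, names = _stratum_frame(cohort, stratum)
            has_cond = X_all.sum(axis=1) > 0
            X = ConditionMatrix(
                X_all[has_cond],
                names,
                persons.loc[has_cond, "person_id"].tolist(),
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"{stratum.name}:cluster"
        try:
            models, reports, chosen_k = _fit_stratum_models(config, X, stratum_seed)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"{stratum.name}:select"
        try:
            validity_rows = []
            for method in config.methods:
                method_reports = [r for r in reports if r.method == method]
                agg = aggregate_repeats(method_reports)
                validity_rows.append(
                    {
                        "method": method,
                        "k": agg.k,
                        "calinski_harabasz": agg.calinski_harabasz,
                        "ch_sd": agg.ch_sd,
                        "davies_bouldin": agg.davies_bouldin,
                        "db_sd": agg.db_sd,
                        "silhouette": agg.silhouette,
                        "sil_sd": agg.sil_sd,
                        "n_singleton_clusters": agg.n_singleton_clusters,
                        "median_cluster_size": agg.median_cluster_size,
                        "min_cluster_size": agg.min_cluster_size,
                        "max_cluster_size": agg.max_cluster_size,
                        "n_repeats": len(method_reports),
                    }
                )
            validity = pd.DataFrame(validity_rows)
            validity.to_csv(sdir / "validity_report.csv", index=False)
            selection = select_best(reports, rule=config.selection_rule)
            chosen = next(
                m
                for m, r in zip(models, reports)
                if r.method == selection.chosen_method
                and r.seed == selection.chosen_seed
                and r.k == selection.chosen_k
            )
            (sdir / "selection.json").write_text(
                json.dumps(
                    {
                        "chosen_method": selection.chosen_method,
                        "chosen_k": selection.chosen_k,
                        "chosen_seed": selection.chosen_seed,
                        "k_by_method": chosen_k,
                        "rationale": selection.rationale,
                    },
                    default=_json_default,
                    indent=2,
                )
            )
            chosen.to_json(sdir / f"model_{chosen.method}_k{chosen.k}.json")
            chosen.labels_frame(X.person_ids).to_csv(
                sdir / "cluster_labels.csv", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"{stratum.name}:represent"
        try:
            cohort_counts = {
                name: int(X_all[:, j].sum()) for j, name in enumerate(names)
            }
            arf = compute_arf(
                X,
                chosen.labels,
                cohort_counts=cohort_counts,
                cohort_size=len(persons),
                alpha=config.alpha,
            )
            arf.to_csv(sdir / "arf_table.csv", index=False)
            if config.make_plots:
                bubble_heatmap(arf, sdir / "bubble_heatmap.svg")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"{stratum.name}:survive"
        try:
            labels_map = dict(zip(X.person_ids, chosen.labels.tolist()))
            records, accounting = build_survival_cohort(
                persons,
                X_all,
                labels_map,
                covariates=config.survival_covariates,
            )
            fit = fit_cause_specific_cox(
                records, covariates=config.survival_covariates,
                accounting=accounting,
            )
            fit.to_json(sdir / "survival_fit.json")
            burden = hr_vs_burden_summary(
                fit,
                records,
                out_path=(sdir / "hr_vs_burden.svg") if config.make_plots else None,
            )
            burden.to_csv(sdir / "cluster_summary.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        results[stratum.name] = {
            "validity": validity,
            "selection": selection,
            "model": chosen,
            "arf": arf,
            "survival": fit,
            "burden": burden,
            "accounting": accounting,
        }
        manifest["strata"][stratum.name] = {
            "n_persons": len(persons),
            "n_clustered": X.n_persons,
            "chosen_method": selection.chosen_method,
            "chosen_k": selection.chosen_k,
            "k_by_method": chosen_k,
            "accounting": accounting,
        }
        manifest["timings_s"][stratum.name] = round(time.time() - t_str, 3)

    manifest["timings_s"]["total"] = round(time.time() - t0, 3)
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, default=_json_default, indent=2)
    )
    results["manifest"] = manifest
    return results
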