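"""Synthetic cohort generator with planted latent-class structure.

Emulates the statistical shape of a large population-cohort multimorbidity
dataset: a persons x conditions binary matrix drawn from a latent-class
Bernoulli mixture, a zero-condition reference subgroup, demographic
covariates (age, sex, five-category ethnicity, three-category country,
deprivation decile), and follow-up outcomes generated under cause-specific
proportional hazards with death as an independent competing event.

The latent-class mixture is chosen deliberately: it is the generative model
that latent class analysis assumes and that distance-based categorical
clustering can recover, so planted-truth recovery is a meaningful test of
every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ETHNICITY_LEVELS = ("Black", "Mixed", "South Asian", "White", "Other")
COUNTRY_LEVELS = ("England", "Wales", "Scotland")
EVENT_TYPES = ("outcome", "death", "censored")

_RESAMPLE_CAP = 100


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions for the demographic covariates.

    Ages are drawn from a normal distribution truncated to [age_min, age_max],
    the range of a middle-aged volunteer cohort. Ethnicity, country and
    deprivation decile are categorical draws; the defaults reflect a
    predominantly white UK population with England dominant. By default
    covariates are independent of the latent condition class;
    ``age_shift_per_class`` adds ``shift * class_index`` years to the mean age
    of each class, a confounding hook for adjustment tests.
    ``missing_fraction`` marks that share of persons as missing ethnicity,
    country and deprivation (jointly), emulating incomplete records.
    """

    age_mean: float = 57.0
    age_sd: float = 8.0
    age_min: float = 37.0
    age_max: float = 73.0
    female_fraction: float = 0.54
    ethnicity_probs: tuple[float, ...] = (0.016, 0.006, 0.020, 0.942, 0.016)
    country_probs: tuple[float, ...] = (0.885, 0.041, 0.074)
    age_shift_per_class: float = 0.0
    missing_fraction: float = 0.0


@dataclass(frozen=True)
class HazardSpec:
    """Cause-specific exponential hazards for the follow-up outcome.

    The outcome hazard for a person in latent class k is
    ``baseline_rate * exp(class_log_hrs[k])``; the zero-condition reference
    group has log hazard ratio exactly 0. Death is an independent competing
    exponential with rate ``death_rate``; everyone still at risk at
    ``censor_time`` (years) is administratively censored.
    """

    baseline_rate: float = 0.01
    class_log_hrs: tuple[float, ...] = ()
    death_rate: float = 0.005
    censor_time: float = 10.0


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort.

    ``class_condition_probs`` is a K x p matrix of Bernoulli probabilities;
    ``class_weights`` must sum to one. ``zero_condition_fraction`` of persons
    are assigned no conditions and latent class -1 (the reference group);
    every other person is guaranteed at least one condition (all-zero draws
    are resampled). ``prior_outcome_fraction`` marks persons as already having
    the outcome at baseline, for exclusion-accounting tests downstream.
    """

    n_persons: int
    n_conditions: int
    class_weights: tuple[float, ...]
    class_condition_probs: tuple[tuple[float, ...], ...]
    zero_condition_fraction: float = 0.15
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    hazards: HazardSpec = field(default_factory=HazardSpec)
    prior_outcome_fraction: float = 0.0
    condition_names: tuple[str, ...] | None = None
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    def validate(self) -> None:
        if self.n_persons < 0:
            raise CohortSpecError("n_persons must be non-negative")
        if self.n_conditions <= 0:
            raise CohortSpecError("n_conditions must be positive")
        w = np.asarray(self.class_weights, dtype=float)
        if w.size == 0:
            raise CohortSpecError("class_weights must be non-empty")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise CohortSpecError(
                "class_weights must be non-negative and sum to 1 within 1e-12"
            )
        probs = np.asarray(self.class_condition_probs, dtype=float)
        if probs.shape != (self.n_classes, self.n_conditions):
            raise CohortSpecError(
                "class_condition_probs must have shape (n_classes, n_conditions); "
                f"got {probs.shape}"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise CohortSpecError("class_condition_probs entries must lie in [0, 1]")
        if not 0 <= self.zero_condition_fraction <= 1:
            raise CohortSpecError("zero_condition_fraction must lie in [0, 1]")
        if not 0 <= self.prior_outcome_fraction < 1:
            raise CohortSpecError("prior_outcome_fraction must lie in [0, 1)")
        hz = self.hazards
        if len(hz.class_log_hrs) != self.n_classes:
            raise CohortSpecError(
                "hazards.class_log_hrs must give one log hazard ratio per class"
            )
        if hz.baseline_rate < 0 or hz.death_rate < 0 or hz.censor_time <= 0:
            raise CohortSpecError(
                "hazards rates must be non-negative and censor_time positive"
            )
        cv = self.covariates
        for name, p in (("ethnicity_probs", cv.ethnicity_probs),
                        ("country_probs", cv.country_probs)):
            arr = np.asarray(p, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise CohortSpecError(f"covariates.{name} must be a probability vector")
        if len(cv.ethnicity_probs) != len(ETHNICITY_LEVELS):
            raise CohortSpecError("covariates.ethnicity_probs needs 5 categories")
        if len(cv.country_probs) != len(COUNTRY_LEVELS):
            raise CohortSpecError("covariates.country_probs needs 3 categories")
        if not 0 <= cv.female_fraction <= 1 or not 0 <= cv.missing_fraction < 1:
            raise CohortSpecError(
                "covariates.female_fraction in [0,1], missing_fraction in [0,1)"
            )

    def condition_labels(self) -> list[str]:
        if self.condition_names is not None:
            if len(self.condition_names) != self.n_conditions:
                raise CohortSpecError("condition_names length must equal n_conditions")
            return list(self.condition_names)
        width = len(str(self.n_conditions))
        return [f"condition_{i + 1:0{width}d}" for i in range(self.n_conditions)]


@dataclass
class SyntheticCohort:
    """A simulated cohort: condition matrix, latent truth, covariates, outcomes.

    ``true_class`` is -1 for zero-condition (reference) persons. ``persons``
    holds one row per person: id, age, sex, ethnicity, country,
    deprivation_decile, prior_outcome, event_time, event_type, true_class.
    """

    condition_matrix: np.ndarray
    condition_names: list[str]
    persons: pd.DataFrame

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def true_class(self) -> np.ndarray:
        return self.persons["true_class"].to_numpy()

    def clustered_subset(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Rows for persons with at least one condition (the clustering population)."""
        mask = self.persons["true_class"].to_numpy() >= 0
        return self.condition_matrix[mask], self.persons.loc[mask]


def _draw_truncated_normal(rng, n, mean, sd, lo, hi):
    if sd <= 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    # redraw tails; truncation range is wide so this converges fast
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``; bit-identical for identical spec + seed.

    Persons are first split into the zero-condition reference group and the
    conditioned group; conditioned persons receive a latent class from
    ``class_weights`` and a Bernoulli condition row from their class profile,
    resampling rows that come out all-zero (at most 100 attempts per row).
    Event times come from independent cause-specific exponential hazards; the
    earliest of outcome time, death time and administrative censoring wins.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_persons, spec.n_conditions, spec.n_classes

    is_reference = rng.random(n) < spec.zero_condition_fraction
    true_class = np.full(n, -1, dtype=int)
    n_cond = int((~is_reference).sum())
    if n_cond:
        true_class[~is_reference] = rng.choice(k, size=n_cond, p=spec.class_weights)

    probs = np.asarray(spec.class_condition_probs, dtype=float)
    X = np.zeros((n, p), dtype=np.int8)
    idx_cond = np.flatnonzero(~is_reference)
    if idx_cond.size:
        row_p = probs[true_class[idx_cond]]
        draws = (rng.random((idx_cond.size, p)) < row_p).astype(np.int8)
        zero_rows = np.flatnonzero(draws.sum(axis=1) == 0)
        for local in zero_rows:
            for attempt in range(_RESAMPLE_CAP):
                redraw = (rng.random(p) < row_p[local]).astype(np.int8)
                if redraw.any():
                    draws[local] = redraw
                    break
            else:
                raise CohortSpecError(
                    "could not draw a non-empty condition row within "
                    f"{_RESAMPLE_CAP} attempts; class profile is too sparse"
                )
        X[idx_cond] = draws

    cv = spec.covariates
    age = _draw_truncated_normal(
        rng, n, cv.age_mean, cv.age_sd, cv.age_min, cv.age_max
    )
    if cv.age_shift_per_class:
        age = np.clip(
            age + cv.age_shift_per_class * np.maximum(true_class, 0),
            cv.age_min, cv.age_max,
        )
    sex = np.where(rng.random(n) < cv.female_fraction, "female", "male")
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=cv.ethnicity_probs)
    country = rng.choice(COUNTRY_LEVELS, size=n, p=cv.country_probs)
    deprivation = rng.integers(1, 11, size=n)

    hz = spec.hazards
    log_hr = np.zeros(n)
    has_class = true_class >= 0
    if k and has_class.any():
        log_hr[has_class] = np.asarray(hz.class_log_hrs)[true_class[has_class]]
    outcome_rate = hz.baseline_rate * np.exp(log_hr)
    with np.errstate(divide="ignore"):
        t_outcome = np.where(
            outcome_rate > 0, rng.exponential(1.0, n) / np.maximum(outcome_rate, 1e-300),
            np.inf,
        )
        t_death = np.where(
            hz.death_rate > 0, rng.exponential(1.0, n) / max(hz.death_rate, 1e-300),
            np.inf,
        )
    t_censor = np.full(n, hz.censor_time)
    stacked = np.stack([t_outcome, t_death, t_censor])
    which = stacked.argmin(axis=0)
    event_time = stacked[which, np.arange(n)]
    event_type = np.array(EVENT_TYPES)[which]

    prior_outcome = rng.random(n) < spec.prior_outcome_fraction

    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "country": country,
            "deprivation_decile": deprivation,
            "prior_outcome": prior_outcome.astype(int),
            "event_time": event_time,
            "event_type": event_type,
            "true_class": true_class,
        }
    )
    if cv.missing_fraction > 0:
        miss = rng.random(n) < cv.missing_fraction
        persons.loc[miss, ["ethnicity", "country"]] = pd.NA
        persons.loc[miss, "deprivation_decile"] = pd.NA
        persons["deprivation_decile"] = persons["deprivation_decile"].astype("Int64")

    return SyntheticCohort(
        condition_matrix=X,
        condition_names=spec.condition_labels(),
        persons=persons,
    )


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> dict[str, Path]:
    """Write ``persons.csv`` and ``conditions.csv`` under ``path``.

    Round-trips losslessly through :func:`read_cohort` (condition matrix
    exactly; floats to CSV precision of repr).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    persons_path = out / "persons.csv"
    conditions_path = out / "conditions.csv"
    cohort.persons.to_csv(persons_path, index=False)
    cond = pd.DataFrame(cohort.condition_matrix, columns=cohort.condition_names)
    cond.insert(0, "person_id", cohort.persons["person_id"].to_numpy())
    cond.to_csv(conditions_path, index=False)
    return {"persons": persons_path, "conditions": conditions_path}


def read_cohort(path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    out = Path(path)
    persons = pd.read_csv(
        out / "persons.csv",
        dtype={"person_id": str},
    )
    if persons.empty:
        persons = persons.astype(
            {"true_class": int} if "true_class" in persons else {}
        )
    if "deprivation_decile" in persons.columns:
        persons["deprivation_decile"] = persons["deprivation_decile"].astype("Int64")
    cond = pd.read_csv(out / "conditions.csv", dtype={"person_id": str})
    names = [c for c in cond.columns if c != "person_id"]
    X = cond[names].to_numpy(dtype=np.int8) if len(cond) else np.zeros(
        (0, len(names)), dtype=np.int8
    )
    return SyntheticCohort(condition_matrix=X, condition_names=names, persons=persons)


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (YAML/JSON config)."""
    d = dict(d)
    cov = d.pop("covariates", {}) or {}
    hz = d.pop("hazards", {}) or {}
    known_cov = {f.name for f in dataclasses.fields(CovariateSpec)}
    known_hz = {f.name for f in dataclasses.fields(HazardSpec)}
    bad = (set(cov) - known_cov) | (set(hz) - known_hz)
    if bad:
        raise CohortSpecError(f"unknown spec fields: {sorted(bad)}")
    if "ethnicity_probs" in cov:
        cov["ethnicity_probs"] = tuple(cov["ethnicity_probs"])
    if "country_probs" in cov:
        cov["country_probs"] = tuple(cov["country_probs"])
    if "class_log_hrs" in hz:
        hz["class_log_hrs"] = tuple(hz["class_log_hrs"])
    d["class_weights"] = tuple(d["class_weights"])
    d["class_condition_probs"] = tuple(
        tuple(row) for row in d["class_condition_probs"]
    )
    if d.get("condition_names") is not None:
        d["condition_names"] = tuple(d["condition_names"])
    known = {f.name for f in dataclasses.fields(CohortSpec)}
    bad = set(d) - known
    if bad:
        raise CohortSpecError(f"unknown spec fields: {sorted(bad)}")
    return CohortSpec(
        covariates=CovariateSpec(**cov), hazards=HazardSpec(**hz), **d
    )


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def default_demo_spec(seed: int = 0, n_persons: int = 4000) -> CohortSpec:
    """A small four-class cohort used by the examples and the demo pipeline.

    Four latent classes with block-structured condition profiles (own block
    probability 0.6, background 0.05) over 20 conditions, a 15% zero-condition
    reference group, and outcome log hazard ratios increasing with the
    typical condition burden of the class.
    """
    n_classes, p, block = 4, 20, 5
    probs = np.full((n_classes, p), 0.05)
    for c in range(n_classes):
        probs[c, c * block:(c + 1) * block] = 0.6
    return CohortSpec(
        n_persons=n_persons,
        n_conditions=p,
        class_weights=(0.25, 0.25, 0.25, 0.25),
        class_condition_probs=tuple(tuple(row) for row in probs),
        zero_condition_fraction=0.15,
        hazards=HazardSpec(
            baseline_rate=0.012,
            class_log_hrs=(np.log(1.3), np.log(1.6), np.log(2.0), np.log(2.4)),
            death_rate=0.005,
            censor_time=10.0,
        ),
        prior_outcome_fraction=0.05,
        covariates=CovariateSpec(missing_fraction=0.005),
        seed=seed,
    )
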