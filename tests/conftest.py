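import numpy as np
import pytest

from mmclust.clustering import ConditionMatrix
from mmclust.synthetic_cohort import CohortSpec, HazardSpec, simulate_cohort


def random_condition_matrix(rng, n, p, density=0.4):
    """Random binary matrix with every row non-empty (resample empty rows)."""
    X = (rng.random((n, p)) < density).astype(np.int8)
    for i in np.flatnonzero(X.sum(axis=1) == 0):
        X[i, rng.integers(p)] = 1
    return ConditionMatrix(
        X, [f"c{j}" for j in range(p)], [f"P{i}" for i in range(n)]
    )


def block_spec(
    n,
    block_p=0.8,
    background_p=0.05,
    n_classes=4,
    block=5,
    seed=0,
    zero_fraction=0.0,
    class_log_hrs=None,
    **kwargs,
):
    """Planted block-structured latent-class cohort spec: class c carries its
    own block of conditions at ``block_p``, everything else at ``background_p``."""
    p = n_classes * block
    probs = np.full((n_classes, p), background_p)
    for c in range(n_classes):
        probs[c, c * block : (c + 1) * block] = block_p
    if class_log_hrs is None:
        class_log_hrs = (0.0,) * n_classes
    return CohortSpec(
        n_persons=n,
        n_conditions=p,
        class_weights=(1.0 / n_classes,) * n_classes,
        class_condition_probs=tuple(tuple(row) for row in probs),
        zero_condition_fraction=zero_fraction,
        hazards=HazardSpec(class_log_hrs=tuple(class_log_hrs), **kwargs.pop("hazards", {})),
        seed=seed,
        **kwargs,
    )


def planted_matrix(n, seed=0, **kwargs):
    """Planted cohort as (ConditionMatrix, true labels)."""
    cohort = simulate_cohort(block_spec(n, seed=seed, **kwargs))
    X, persons = cohort.clustered_subset()
    cm = ConditionMatrix(X, cohort.condition_names, persons["person_id"].tolist())
    return cm, persons["true_class"].to_numpy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return random_condition_matrix(rng, 30, 8)
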