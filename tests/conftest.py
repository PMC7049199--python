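import numpy as np
import pytest

from exohub import (
    SimulationConfig,
    build_genotype_matrix,
    filter_calls,
    simulate_cohorts,
)

# small, fast scenario for unit tests (consistent gene bookkeeping:
# 2 * disc + noise == total)
SMALL = dict(
    n_cases_per_class=60,
    n_genes_total=60,
    n_discriminative_genes_per_class=15,
    n_hub_genes_per_class=4,
    n_noise_genes=30,
    variants_per_gene=(2, 3),
)

FAST_HYPER = {"n_estimators": 80, "max_depth": 3, "learning_rate": 0.2}


@pytest.fixture(scope="session")
def small_cohort():
    calls, truth = simulate_cohorts(SimulationConfig(seed=11, **SMALL))
    return calls, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    calls, truth = small_cohort
    labels = dict(zip(truth.sample_ids, truth.class_labels))
    return build_genotype_matrix(filter_calls(calls), truth.sample_ids, labels), truth


def toy_genotype_matrix():
    """3 samples x 4 variants hand-enumerable matrix."""
    from exohub import GenotypeMatrix

    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        variant_ids=["1:10:A:C", "1:20:G:T", "2:30:C:A", "2:40:T:G"],
        values=np.array([[1, 0, 2, 0], [0, 1, 0, 0], [0, 0, 1, 1]]),
        labels=np.array(["ASD", "SCZ", "ASD"]),
        variant_to_gene={
            "1:10:A:C": "GA",
            "1:20:G:T": "GA",
            "2:30:C:A": "GB",
            "2:40:T:G": "GB",
        },
    )
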