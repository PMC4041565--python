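import numpy as np
import pandas as pd
import pytest

import irclust as ir
from irclust.cohort import CLINICAL_FEATURES


def make_cohort(rows):
    """Build a Cohort from (id, family, age, bmi, *clinical) tuples."""
    data = [dict(zip(("id", "family_id", "age", "bmi") + CLINICAL_FEATURES, r)) for r in rows]
    return ir.Cohort(pd.DataFrame(data))


@pytest.fixture
def small_cohort():
    """Six individuals in three families with hand-set measurements."""
    clin = lambda base: tuple(base + 10.0 * j for j in range(9))
    rows = [
        ("a1", "f1", 45.0, 22.0) + clin(80.0),
        ("a2", "f1", 50.0, 25.0) + clin(90.0),
        ("b1", "f2", 55.0, 28.0) + clin(100.0),
        ("b2", "f2", 60.0, 24.0) + clin(110.0),
        ("b3", "f2", 40.0, 26.0) + clin(120.0),
        ("c1", "f3", 52.0, 23.0) + clin(130.0),
    ]
    return make_cohort(rows)


@pytest.fixture(scope="session")
def default_cohort_truth():
    """One default-condition synthetic cohort shared across tests."""
    return ir.generate_cohort(seed=42)


@pytest.fixture(scope="session")
def default_residuals(default_cohort_truth):
    cohort, _ = default_cohort_truth
    return ir.fit_residuals(cohort)


@pytest.fixture(scope="session")
def snp_pipeline(default_cohort_truth):
    """Filtered + imputed genotypes, dendrogram, and true-label assignment."""
    cohort, truth = default_cohort_truth
    genotypes = ir.generate_genotypes(cohort, truth, seed=42)
    retained, report = ir.filter_snps(genotypes, 400)
    retained, dropped = ir.filter_individuals(retained, 110)
    imputed = ir.impute_genotypes(retained, seed=42)
    distances = ir.mi_distance_matrix(imputed)
    dendrogram = ir.cluster_snps(distances)
    assignment = ir.Assignment(truth.labels.loc[imputed.ids])
    return {
        "genotypes": genotypes,
        "report": report,
        "dropped": dropped,
        "imputed": imputed,
        "distances": distances,
        "dendrogram": dendrogram,
        "assignment": assignment,
        "truth": truth,
        "cohort": cohort,
    }
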