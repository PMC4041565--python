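"""Conditional permutation test for familiality of cluster membership.

Whether the insulin-resistant cluster aggregates in sibships is tested
conditionally on three observed quantities: the sibship-size composition,
the total number of individuals N, and the cluster-1 size n1.  Under the
null, exactly n1 of the N individuals are assigned to cluster 1 uniformly at
random.  For a family of size k the chance that it is represented in
cluster 1 is then hypergeometric:

    P(family of size k has >= 1 member in C1) = 1 - C(N-k, n1) / C(N, n1),

so the expected number of size-k families represented is f_k times that.
The Monte-Carlo test statistic is the total number of families of size >= 2
represented in cluster 1, with a two-sided add-one p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Assignment, Cohort
from .errors import ParameterError

# sizes below 2 carry no familiality information
MIN_INFORMATIVE_SIZE = 2


@dataclass
class FamilySizeTable:
    """Sibship-size composition: size k -> number of families f_k."""

    counts: dict[int, int]

    @property
    def n_families(self) -> int:
        return sum(self.counts.values())

    @property
    def n_individuals(self) -> int:
        return sum(k * f for k, f in self.counts.items())

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "FamilySizeTable":
        return cls(cohort.size_histogram())


def count_families(
    assignment: Assignment, cohort: Cohort, cluster: int
) -> dict[int, int]:
    """NF(cluster, k): size-k families with at least one member in the cluster."""
    if cluster not in assignment.cluster_sizes():
        raise ParameterError(f"cluster label {cluster} absent from assignment")
    labels = assignment.labels_for(cohort.ids)
    fam = cohort.family_ids
    sizes = pd.Series(fam).value_counts()
    hit = pd.Series(fam)[labels == cluster].unique()
    out: dict[int, int] = {int(k): 0 for k in sizes.unique()}
    for f in hit:
        out[int(sizes[f])] += 1
    return dict(sorted(out.items()))


def expected_under_null(table: FamilySizeTable, n1: int) -> dict[int, float]:
    """Closed-form expected NF(C1, k) under random assignment of n1 to C1."""
    n = table.n_individuals
    if not 0 <= n1 <= n:
        raise ParameterError(f"n1={n1} outside [0, {n}]")
    out: dict[int, float] = {}
    denom = math.comb(n, n1)
    for k, fk in sorted(table.counts.items()):
        p_missed = math.comb(n - k, n1) / denom if n - k >= n1 else 0.0
        out[k] = fk * (1.0 - p_missed)
    return out


@dataclass
class FamilialityReport:
    """Observed vs null-expected represented-family counts, by sibship size."""

    rows: pd.DataFrame  # columns: size, n_families, observed, expected
    observed_total: int
    expected_total: float
    p_value: float
    n_perm: int

    def __str__(self) -> str:
        lines = [self.rows.to_string(index=False)]
        lines.append(
            f"total observed {self.observed_total}, expected "
            f"{self.expected_total:.2f}; two-sided p = {self.p_value:.4g} "
            f"({self.n_perm} permutations)"
        )
        return "\n".join(lines)


def _nf_total(fam_index: np.ndarray, informative: np.ndarray, in_c1: np.ndarray) -> int:
    """Number of informative families with >= 1 selected member."""
    hit = np.zeros(informative.shape[0], dtype=bool)
    hit_fams = np.unique(fam_index[in_c1])
    hit[hit_fams] = True
    return int(np.sum(hit & informative))


def familiality_pvalue(
    assignment: Assignment,
    cohort: Cohort,
    n_perm: int,
    seed: int,
) -> tuple[float, FamilialityReport]:
    """Monte-Carlo conditional permutation test for two clusters.

    Returns the two-sided add-one p-value (doubling rule) and the
    Table-shaped report of observed vs closed-form expected counts for
    sibship sizes >= 2.
    """
    if assignment.k != 2:
        raise ParameterError("familiality test is defined for exactly two clusters")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    labels = assignment.labels_for(cohort.ids)
    n1 = int(np.sum(labels == 1))
    n = cohort.n
    fams, fam_index = np.unique(cohort.family_ids, return_inverse=True)
    fam_sizes = np.bincount(fam_index)
    informative = fam_sizes >= MIN_INFORMATIVE_SIZE

    observed_by_size = count_families(assignment, cohort, 1)
    table = FamilySizeTable.from_cohort(cohort)
    expected_by_size = expected_under_null(table, n1)
    obs_total = sum(v for k, v in observed_by_size.items() if k >= MIN_INFORMATIVE_SIZE)
    exp_total = sum(v for k, v in expected_by_size.items() if k >= MIN_INFORMATIVE_SIZE)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    in_c1 = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        in_c1[:] = False
        in_c1[rng.choice(n, size=n1, replace=False)] = True
        null[b] = _nf_total(fam_index, informative, in_c1)
    lower = (np.sum(null <= obs_total) + 1) / (n_perm + 1)
    upper = (np.sum(null >= obs_total) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(lower, upper))

    sizes = sorted(k for k in table.counts if k >= MIN_INFORMATIVE_SIZE)
    rows = pd.DataFrame(
        {
            "size": sizes,
            "n_families": [table.counts[k] for k in sizes],
            "observed": [observed_by_size.get(k, 0) for k in sizes],
            "expected": [expected_by_size[k] for k in sizes],
        }
    )
    report = FamilialityReport(
        rows=rows,
        observed_total=obs_total,
        expected_total=exp_total,
        p_value=p,
        n_perm=n_perm,
    )
    return p, report
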