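"""Between-cluster comparison of the clinical measures on their original scale.

Clustering is done on residuals, but summaries add the fitted values back so
means and standard deviations are on the measurement scale (age and BMI are
reported directly).  Differences are quantified three ways: the
Behrens-Fisher-Welch t (unpooled variances), a pooled-t permutation test
conditional on the observed cluster sizes, and the Wilcoxon rank-sum test —
the latter two repeated over sibship-bootstrap replicates, reporting the
fraction of replicates rejecting at a given level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import draw_bootstrap
from .cohort import CLINICAL_FEATURES, Assignment, Cohort
from .errors import ConsistencyError, DomainError, ParameterError
from .regressors import ResidualMatrix

logger = logging.getLogger(__name__)


def welch_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Behrens-Fisher-Welch t: (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2).

    Sample standard deviations use the n-1 denominator.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    se = np.sqrt(s1**2 / n1 + s2**2 / n2)
    if se == 0:
        raise DomainError("both standard deviations are zero; t is undefined")
    return float((m1 - m2) / se)


@dataclass
class ClusterSummary:
    """Per-feature cluster means/sds on the original scale, with Welch t."""

    table: pd.DataFrame  # feature, mean1, sd1, mean2, sd2, t
    n1: int
    n2: int


def summarize_clusters(
    cohort: Cohort, residuals: ResidualMatrix, assignment: Assignment
) -> ClusterSummary:
    """Cluster-wise summary of age, BMI and the reconstructed features."""
    if assignment.k != 2:
        raise ParameterError("summary is defined for exactly two clusters")
    ids = cohort.ids
    if list(residuals.residuals.index) != ids:
        raise ConsistencyError("residual matrix is not aligned with the cohort")
    recon = residuals.residuals + residuals.fitted
    observed = cohort.clinical_matrix()
    if not np.allclose(recon.to_numpy(), observed.to_numpy(), atol=1e-8):
        raise ConsistencyError("residual + fitted does not reproduce the observed data")

    labels = assignment.labels_for(ids)
    data = pd.concat(
        [
            pd.DataFrame({"Age": cohort.ages, "BMI": cohort.bmis}, index=observed.index),
            recon,
        ],
        axis=1,
    )
    n1 = int(np.sum(labels == 1))
    n2 = int(np.sum(labels == 2))
    if n1 < 2 or n2 < 2:
        raise DomainError("a cluster has fewer than 2 members; sd undefined")
    g1 = data[labels == 1]
    g2 = data[labels == 2]
    rows = []
    for feat in data.columns:
        m1, s1 = float(g1[feat].mean()), float(g1[feat].std(ddof=1))
        m2, s2 = float(g2[feat].mean()), float(g2[feat].std(ddof=1))
        rows.append(
            {
                "feature": feat,
                "mean1": m1,
                "sd1": s1,
                "mean2": m2,
                "sd2": s2,
                "t": welch_t(m1, s1, n1, m2, s2, n2),
            }
        )
    return ClusterSummary(table=pd.DataFrame(rows), n1=n1, n2=n2)


@dataclass
class TestSuiteResult:
    """Per-feature rejection fractions over bootstrap replicates."""

    perm_t_rejection: pd.Series  # fraction of replicates with permutation p < alpha
    wilcoxon_rejection: pd.Series
    alpha: float
    n_boot: int
    n_perm: int
    n_skipped: int


def _pooled_t(x: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Pooled-variance t per column for group masks g1 vs ~g1."""
    n1 = g1.sum()
    n2 = (~g1).sum()
    m1 = x[g1].mean(axis=0)
    m2 = x[~g1].mean(axis=0)
    v1 = x[g1].var(axis=0, ddof=1)
    v2 = x[~g1].var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def bootstrap_permutation_suite(
    cohort: Cohort,
    residuals: ResidualMatrix,
    assignment: Assignment,
    n_boot: int = 100,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> TestSuiteResult:
    """Permutation pooled-t and Wilcoxon tests over sibship-bootstrap replicates.

    The permutation null re-divides the *source* cohort's subjects into two
    groups of the observed cluster sizes and propagates the division to the
    replicate through each row's source individual.  Permuting replicate rows
    directly would ignore that bootstrap copies of one person are tied and
    badly inflate the rejection rate.  Per-feature add-one two-sided p-values
    are compared to ``alpha`` and the fraction of rejecting replicates is
    reported per feature.
    """
    ids = cohort.ids
    labels_src = pd.Series(assignment.labels_for(ids), index=ids)
    recon = residuals.residuals + residuals.fitted
    features = pd.concat(
        [
            pd.DataFrame({"Age": cohort.ages, "BMI": cohort.bmis}, index=recon.index),
            recon,
        ],
        axis=1,
    )
    feature_names = list(features.columns)
    n_source = cohort.n
    n1_source = int((labels_src == 1).sum())
    id_pos = {i: k for k, i in enumerate(ids)}
    reject_t = np.zeros(len(feature_names))
    reject_w = np.zeros(len(feature_names))
    n_used = 0
    n_skipped = 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        rep = draw_bootstrap(cohort, rng)
        src = rep.source_ids
        src_idx = np.array([id_pos[i] for i in src])
        x = features.loc[src].to_numpy()
        lab = labels_src.loc[src].to_numpy()
        g1 = lab == 1
        if g1.sum() < 2 or (~g1).sum() < 2:
            n_skipped += 1
            logger.info("suite replicate %d skipped: degenerate cluster sizes", b)
            continue
        t_obs = np.abs(_pooled_t(x, g1))
        exceed = np.zeros(len(feature_names))
        source_mask = np.zeros(n_source, dtype=bool)
        for _ in range(n_perm):
            source_mask[:] = False
            source_mask[rng.choice(n_source, size=n1_source, replace=False)] = True
            g = source_mask[src_idx]
            if g.sum() < 2 or (~g).sum() < 2:
                exceed += 1.0  # degenerate division counts as extreme
                continue
            exceed += np.abs(_pooled_t(x, g)) >= t_obs
        p_t = (exceed + 1) / (n_perm + 1)
        reject_t += p_t < alpha
        for j in range(len(feature_names)):
            p_w = stats.mannwhitneyu(
                x[g1, j], x[~g1, j], alternative="two-sided"
            ).pvalue
            reject_w[j] += p_w < alpha
        n_used += 1
    if n_used == 0:
        raise DomainError("no usable bootstrap replicates")
    return TestSuiteResult(
        perm_t_rejection=pd.Series(reject_t / n_used, index=feature_names),
        wilcoxon_rejection=pd.Series(reject_w / n_used, index=feature_names),
        alpha=alpha,
        n_boot=n_boot,
        n_perm=n_perm,
        n_skipped=n_skipped,
    )
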