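"""SNP filtering, imputation, mutual-information clustering, and selection.

Genotypes are major-allele counts in {0,1,2}.  The pipeline drops SNPs that
are constant or genotyped in too few individuals (default 400), drops
individuals with too many missing calls (default more than 110), imputes the
remaining gaps with per-SNP classification trees, measures SNP-SNP
redundancy by the mutual information of their 3x3 contingency table, grows
an average-linkage dendrogram on an MI-derived distance, and selects one
representative SNP per dendrogram node — the member most informative about
cluster membership — at a cut chosen by cross-validated classification
accuracy.

Mutual information defaults to base-2 logarithms (bits) but the base is
configurable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import Assignment, GenotypeMatrix
from .errors import ConsistencyError, DegenerateLabelsError, DomainError, ParameterError

logger = logging.getLogger(__name__)


# -- mutual information ------------------------------------------------------


def mutual_information(table: np.ndarray, base: float = 2.0) -> float:
    """I(X;Y) of a contingency table of counts, in log-``base`` units.

    I = sum_ij p_ij log(p_ij / (p_i. p_.j)) with 0 log 0 = 0; non-negative,
    zero exactly when the table is an outer product of its margins.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise DomainError("contingency table must be 2-d with non-negative counts")
    total = t.sum()
    if total == 0:
        raise DomainError("contingency table has no counts")
    p = t / total
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (pr * pc)), 0.0)
    return float(max(terms.sum(), 0.0) / np.log(base))


def entropy(counts: np.ndarray, base: float = 2.0) -> float:
    c = np.asarray(counts, dtype=float)
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def pair_table(x: np.ndarray, y: np.ndarray, levels: int = 3) -> np.ndarray:
    """levels x levels joint count table of two coded vectors."""
    joint = levels * x.astype(int) + y.astype(int)
    return np.bincount(joint, minlength=levels * levels).reshape(levels, levels)


# -- filters -----------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    n_constant: int
    n_undergenotyped: int
    n_retained: int
    dropped_constant: list[str]
    dropped_undergenotyped: list[str]


def filter_snps(
    genotypes: GenotypeMatrix, min_genotyped: int = 400
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop constant SNPs, then SNPs genotyped in fewer than ``min_genotyped``."""
    if min_genotyped < 1:
        raise ParameterError("min_genotyped must be >= 1")
    df = genotypes.frame
    constant = [c for c in df.columns if df[c].dropna().nunique() <= 1]
    rest = df.drop(columns=constant)
    under = [
        c for c in rest.columns if int(rest[c].notna().sum()) < min_genotyped
    ]
    retained = rest.drop(columns=under)
    report = FilterReport(
        n_input=df.shape[1],
        n_constant=len(constant),
        n_undergenotyped=len(under),
        n_retained=retained.shape[1],
        dropped_constant=constant,
        dropped_undergenotyped=under,
    )
    logger.info(
        "filter_snps: %d in -> %d constant, %d under-genotyped (<%d), %d retained",
        report.n_input, report.n_constant, report.n_undergenotyped,
        min_genotyped, report.n_retained,
    )
    return GenotypeMatrix(retained), report


def filter_individuals(
    genotypes: GenotypeMatrix, max_missing: int = 110
) -> tuple[GenotypeMatrix, pd.Index]:
    """Drop individuals with more than ``max_missing`` missing calls."""
    if max_missing < 0:
        raise ParameterError("max_missing must be >= 0")
    miss = genotypes.missing_per_individual()
    dropped = miss.index[miss > max_missing]
    kept = genotypes.frame.drop(index=dropped)
    logger.info(
        "filter_individuals: dropped %d of %d individuals (> %d missing)",
        len(dropped), len(miss), max_missing,
    )
    return GenotypeMatrix(kept), dropped


# -- imputation --------------------------------------------------------------


def impute_genotypes(genotypes: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls with per-SNP classification trees.

    For each SNP with missing entries, a depth-limited tree is trained on the
    individuals observed for that SNP, using all other SNPs (mode-filled) as
    predictors, and predicts the missing entries.  Observed entries are
    preserved exactly; SNPs with no usable training rows fall back to the
    modal genotype (logged).
    """
    df = genotypes.frame
    # mode-filled predictor matrix (modes ignore missing entries)
    modes = df.mode(axis=0, dropna=True).iloc[0]
    modes = modes.fillna(0.0)
    filled = df.fillna(modes)
    out = df.copy()
    rng = np.random.default_rng(seed)
    for col in df.columns:
        target = df[col]
        mask = target.isna()
        if not mask.any():
            continue
        obs = ~mask
        y = target[obs].astype(int)
        if y.nunique() < 2 or obs.sum() == 0:
            out.loc[mask, col] = float(modes[col])
            logger.info("impute_genotypes: modal fallback for %s", col)
            continue
        Xtr = filled.loc[obs].drop(columns=col)
        tree = DecisionTreeClassifier(
            max_depth=5, random_state=int(rng.integers(2**31))
        )
        tree.fit(Xtr.to_numpy(), y.to_numpy())
        pred = tree.predict(filled.loc[mask].drop(columns=col).to_numpy())
        out.loc[mask, col] = pred.astype(float)
    return GenotypeMatrix(out)


# -- SNP-SNP distances and dendrogram ---------------------------------------


def mi_distance_matrix(genotypes: GenotypeMatrix, base: float = 2.0) -> pd.DataFrame:
    """1 - I(X;Y)/min(H(X), H(Y)) for every SNP pair; zero diagonal."""
    if not genotypes.is_complete():
        raise ConsistencyError("distance matrix requires a complete (imputed) matrix")
    df = genotypes.frame
    G = df.to_numpy().astype(int)
    m = G.shape[1]
    ent = np.empty(m)
    for j in range(m):
        ent[j] = entropy(np.bincount(G[:, j], minlength=3), base)
    if np.any(ent == 0):
        bad = df.columns[np.where(ent == 0)[0][0]]
        raise ConsistencyError(
            f"constant SNP {bad!r} reached the distance stage; filter first"
        )
    dist = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        t = pair_table(G[:, i], G[:, j])
        nmi = mutual_information(t, base) / min(ent[i], ent[j])
        dist[i, j] = dist[j, i] = 1.0 - min(nmi, 1.0)
    return pd.DataFrame(dist, index=df.columns, columns=df.columns)


@dataclass
class SNPDendrogram:
    """Average-linkage merge tree over SNPs (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    leaves: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, height: float) -> dict[int, list[str]]:
        """Partition the leaves by merging everything below ``height``."""
        labels = fcluster(self.linkage_matrix, height, criterion="distance")
        groups: dict[int, list[str]] = {}
        for name, lab in zip(self.leaves, labels):
            groups.setdefault(int(lab), []).append(name)
        return groups

    def cut_clusters(self, n_clusters: int) -> dict[int, list[str]]:
        """Partition the leaves into ``n_clusters`` groups."""
        labels = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        groups: dict[int, list[str]] = {}
        for name, lab in zip(self.leaves, labels):
            groups.setdefault(int(lab), []).append(name)
        return groups


def cluster_snps(distances: pd.DataFrame) -> SNPDendrogram:
    """Standard average-linkage agglomeration on an MI distance matrix."""
    if distances.shape[0] < 2:
        raise ParameterError("need at least 2 SNPs to build a dendrogram")
    if not np.allclose(distances.to_numpy(), distances.to_numpy().T, atol=1e-12):
        raise ConsistencyError("distance matrix must be symmetric")
    z = linkage(squareform(distances.to_numpy(), checks=False), method="average")
    return SNPDendrogram(linkage_matrix=z, leaves=list(distances.columns))


# -- representative selection ------------------------------------------------


def snp_label_mi(
    genotypes: GenotypeMatrix, labels: Assignment, base: float = 2.0
) -> pd.Series:
    """MI between each SNP (3 levels) and the 2-level cluster label, in bits."""
    y = labels.labels_for(genotypes.ids) - 1
    G = genotypes.frame.to_numpy().astype(int)
    out = {}
    for j, name in enumerate(genotypes.snps):
        t = np.bincount(2 * G[:, j] + y, minlength=6).reshape(3, 2)
        out[name] = mutual_information(t, base)
    return pd.Series(out)


@dataclass
class RepresentativeSelection:
    representatives: list[str]
    cut_height: float
    cv_accuracy: float
    mi_with_label: pd.Series  # MI of every retained SNP with the label
    accuracy_by_cut: pd.Series  # candidate cut height -> CV accuracy


#: Candidate similarity-threshold cuts: redundancy (1 - normalized MI) below
#: the cut is collapsed into one node.  The grid spans normalized-MI
#: similarity thresholds 0.9 down to 0.1; a cut at or above 1 would declare
#: mutually uninformative SNPs redundant and is deliberately excluded.
DEFAULT_CUT_HEIGHTS: tuple[float, ...] = (
    0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
)


def select_representatives(
    dendrogram: SNPDendrogram,
    genotypes: GenotypeMatrix,
    labels: Assignment,
    n_folds: int = 10,
    seed: int = 0,
    cut_heights: tuple[float, ...] = DEFAULT_CUT_HEIGHTS,
    classifier=None,
) -> RepresentativeSelection:
    """Pick one representative SNP per dendrogram node at a CV-chosen cut.

    Each node's representative is the member SNP with maximum mutual
    information with cluster membership (ties broken by name).  Candidate
    cuts are a fixed grid of redundancy thresholds (merge heights); cuts
    yielding identical partitions are scored once.  Each candidate is scored
    by stratified cross-validated accuracy of the baseline cost-weighted
    classifier (cost ratio 1:1) on its representative columns, and the
    best-scoring cut wins, ties going to the higher cut (fewer
    representatives).
    """
    y = labels.labels_for(genotypes.ids)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("cluster labels have a single class")
    mi = snp_label_mi(genotypes, labels)

    if classifier is None:
        from .prediction import default_classifier

        classifier = default_classifier(cost_ratio=1.0)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X_full = genotypes.frame
    reps_by_cut: dict[float, list[str]] = {}
    for h in sorted(cut_heights):
        groups = dendrogram.cut(h)
        # per node: max MI with the label, ties to the lexicographically first
        reps_by_cut[h] = sorted(
            min(members, key=lambda s: (-mi[s], s)) for members in groups.values()
        )

    accuracy: dict[float, float] = {}
    score_cache: dict[tuple[str, ...], float] = {}
    for h, reps in reps_by_cut.items():
        key = tuple(reps)
        if key not in score_cache:
            X = X_full[reps].to_numpy()
            correct = 0
            for tr, te in skf.split(X, y):
                model = clone(classifier)
                model.fit(X[tr], y[tr])
                correct += int(np.sum(model.predict(X[te]) == y[te]))
            score_cache[key] = correct / len(y)
        accuracy[h] = score_cache[key]
    best = min(accuracy, key=lambda h_: (-accuracy[h_], -h_))
    return RepresentativeSelection(
        representatives=reps_by_cut[best],
        cut_height=best,
        cv_accuracy=accuracy[best],
        mi_with_label=mi,
        accuracy_by_cut=pd.Series(accuracy).sort_index(),
    )
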