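"""Interaction mining and cost-sensitive prediction of cluster membership.

Candidate gene-environment interactions are mined from a pruned
classification tree: every split variable on a root-to-leaf path is a main
effect, and every pair of variables at adjacent depths on a path suggests a
two-factor interaction ("split on A, split on B, split on A" yields the
words A, B, and A x B).  Three- and higher-order interactions are ignored,
self-pairs are excluded, and sub-word closure holds by construction.

Three nested feature sets are evaluated: FS1 = age/BMI terms, FS2 = FS1 plus
representative SNP main effects, FS3 = FS2 plus the mined interaction
products.  Prediction quality is summarized by a stratified k-fold
cross-validation harness over a grid of false-negative : false-positive
misclassification-cost ratios; the default classifier is a cost-weighted
linear margin classifier (any scikit-learn classifier can be plugged in —
the evaluation protocol, not the classifier internals, is the point).  An
added-value permutation test permutes the SNP block across individuals
(recomputing interactions from the permuted SNPs) and compares
cross-validated AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import Assignment, Cohort, GenotypeMatrix
from .errors import (
    ConsistencyError,
    DegenerateLabelsError,
    DomainError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: age/BMI design columns used as base features
BASE_FEATURES: tuple[str, ...] = ("AGE", "BMI", "AGE2", "BMI2", "AGE_BMI")

POSITIVE_CLASS = 1  # the insulin-resistant cluster
NEGATIVE_CLASS = 2


def default_classifier(cost_ratio: float = 1.0):
    """Cost-weighted linear margin classifier in a scaling pipeline.

    Class weights are proportional to the misclassification costs
    (false negative on the insulin-resistant class costs ``cost_ratio``
    times a false positive).
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                LinearSVC(
                    class_weight={POSITIVE_CLASS: cost_ratio, NEGATIVE_CLASS: 1.0},
                ),
            ),
        ]
    )


# -- CART growth and word mining --------------------------------------------


@dataclass
class CARTModel:
    tree: DecisionTreeClassifier
    feature_names: list[str]

    @property
    def depth(self) -> int:
        return int(self.tree.get_depth())


def grow_cart(
    X: pd.DataFrame, labels: np.ndarray, seed: int = 0, n_folds: int = 10
) -> CARTModel:
    """Grow a Gini tree with prior x loss equalized, then cost-complexity prune.

    Equalizing the product of empirical class frequency and loss means class
    weights inversely proportional to class frequency ("balanced").  Pruning
    strength is chosen by internal stratified cross-validation on balanced
    accuracy: candidate strengths are the midpoints of the cost-complexity
    path intervals (plus one past the root, so the trivial tree is always a
    candidate); the tree is kept only if its best candidate beats the root's
    0.5 balanced accuracy by more than three standard errors, otherwise it
    collapses to the root, and among surviving candidates the
    one-standard-error rule picks the strongest pruning.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("need two classes to grow a tree")
    Xa = X.to_numpy()

    def fit(alpha: float) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini",
            class_weight="balanced",
            random_state=seed,
            ccp_alpha=float(alpha),
        )

    path = fit(0.0).cost_complexity_pruning_path(Xa, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    # midpoints avoid the boundary ambiguity at the path's exact alphas
    candidates = sorted(
        {0.0}
        | {(a + b) / 2.0 for a, b in zip(alphas[:-1], alphas[1:])}
        | {float(alphas[-1]) * 1.01 + 1e-12}
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xa, y))
    means, ses = [], []
    for alpha in candidates:
        scores = []
        for tr, te in splits:
            pred = fit(alpha).fit(Xa[tr], y[tr]).predict(Xa[te])
            # balanced accuracy matches the equalized-prior objective
            accs = [np.mean(pred[y[te] == c] == c) for c in classes]
            scores.append(float(np.mean(accs)))
        means.append(float(np.mean(scores)))
        ses.append(float(np.std(scores, ddof=1) / np.sqrt(len(scores))))
    best = int(np.argmax(means))
    if means[best] - 3.0 * ses[best] <= 0.5:
        chosen = candidates[-1]  # no detectable signal: the root
    else:
        threshold = means[best] - ses[best]
        chosen = max(
            (a for a, m in zip(candidates, means) if m >= threshold),
            default=candidates[best],
        )
    final = fit(chosen).fit(Xa, y)
    return CARTModel(tree=final, feature_names=list(X.columns))


@dataclass
class InteractionWordSet:
    """Mined main-effect and two-factor interaction words.

    Sub-word closure invariant: both constituents of every pair are present
    as main effects.
    """

    mains: set[str] = field(default_factory=set)
    pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.pairs:
            if not pair <= self.mains:
                raise ConsistencyError(f"pair {set(pair)} lacks its sub-words")


def extract_words(model: CARTModel) -> InteractionWordSet:
    """Main effects and adjacent-split interaction pairs from tree paths."""
    t = model.tree.tree_
    names = model.feature_names
    mains: set[str] = set()
    pairs: set[frozenset] = set()

    def walk(node: int, path: list[str]) -> None:
        if t.children_left[node] == -1:  # leaf
            mains.update(path)
            for a, b in zip(path, path[1:]):
                if a != b:  # self-pairs are not interactions
                    pairs.add(frozenset((a, b)))
            return
        feat = names[t.feature[node]]
        walk(t.children_left[node], path + [feat])
        walk(t.children_right[node], path + [feat])

    walk(0, [])
    return InteractionWordSet(mains=mains, pairs=pairs)


# -- feature sets ------------------------------------------------------------


@dataclass
class FeatureSet:
    """A named design matrix plus the metadata to rebuild its interactions."""

    name: str
    base: pd.DataFrame  # raw age/BMI term columns
    snps: pd.DataFrame  # raw 0/1/2 SNP columns (possibly empty)
    words: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.base.columns) | set(self.snps.columns)
        for w in self.words:
            unknown = set(w) - known
            if unknown:
                raise ConsistencyError(f"interaction references unknown {unknown}")

    @property
    def feature_names(self) -> list[str]:
        return (
            list(self.base.columns)
            + list(self.snps.columns)
            + ["*".join(sorted(w)) for w in self.words]
        )

    def matrix(self) -> pd.DataFrame:
        """Assembled design: base terms, SNPs, interaction products.

        Interaction products multiply standardized constituents; SNP
        constituents are centered only (their 0/1/2 coding is kept).
        """
        parts = [self.base, self.snps]
        inter = {}
        for w in self.words:
            cols = sorted(w)
            prod = np.ones(len(self.base))
            for c in cols:
                if c in self.base.columns:
                    v = self.base[c].to_numpy()
                    sd = v.std(ddof=0)
                    prod = prod * ((v - v.mean()) / (sd if sd > 0 else 1.0))
                else:
                    v = self.snps[c].to_numpy()
                    prod = prod * (v - v.mean())
            inter["*".join(cols)] = prod
        if inter:
            parts.append(pd.DataFrame(inter, index=self.base.index))
        return pd.concat(parts, axis=1)

    def with_permuted_snps(self, permutation: np.ndarray) -> "FeatureSet":
        """The same features with SNP rows permuted across individuals."""
        snps = pd.DataFrame(
            self.snps.to_numpy()[permutation],
            index=self.snps.index,
            columns=self.snps.columns,
        )
        return FeatureSet(self.name, self.base, snps, list(self.words))


def base_terms(cohort: Cohort, ids: list[str] | None = None) -> pd.DataFrame:
    """AGE, BMI and their quadratic terms for the given ids (default: all)."""
    sub = cohort if ids is None else cohort.subset(ids)
    age, bmi = sub.ages, sub.bmis
    return pd.DataFrame(
        {
            "AGE": age,
            "BMI": bmi,
            "AGE2": age**2,
            "BMI2": bmi**2,
            "AGE_BMI": age * bmi,
        },
        index=pd.Index(sub.ids, name="id"),
    )


def assemble_feature_sets(
    cohort: Cohort,
    representatives: GenotypeMatrix | pd.DataFrame,
    words: InteractionWordSet,
) -> dict[str, FeatureSet]:
    """FS1 (age/BMI), FS2 (+ SNP main effects), FS3 (+ interaction products)."""
    snps = (
        representatives.frame
        if isinstance(representatives, GenotypeMatrix)
        else representatives
    )
    ids = [i for i in cohort.ids if i in set(snps.index)]
    base = base_terms(cohort, ids)
    snps = snps.loc[ids]
    fs1 = FeatureSet("FS1", base, snps.iloc[:, :0])
    fs2 = FeatureSet("FS2", base, snps)
    fs3 = FeatureSet("FS3", base, snps, sorted(words.pairs, key=sorted))
    return {"FS1": fs1, "FS2": fs2, "FS3": fs3}


# -- cost-sensitive cross-validation -----------------------------------------


@dataclass
class CVReport:
    """Held-out performance per cost ratio (summary) and per fold."""

    feature_set: str
    summary: pd.DataFrame  # ratio, sensitivity, specificity, overall, miscost
    folds: pd.DataFrame


def _fold_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == POSITIVE_CLASS) & (y_pred == POSITIVE_CLASS)))
    fn = int(np.sum((y_true == POSITIVE_CLASS) & (y_pred != POSITIVE_CLASS)))
    tn = int(np.sum((y_true != POSITIVE_CLASS) & (y_pred != POSITIVE_CLASS)))
    fp = int(np.sum((y_true != POSITIVE_CLASS) & (y_pred == POSITIVE_CLASS)))
    return tp, fn, tn, fp


def cost_sensitive_cv(
    features: FeatureSet,
    labels: Assignment,
    cost_ratios=(1.8, 1.9, 2.0, 2.1, 2.2, 2.3),
    n_folds: int = 10,
    seed: int = 0,
    classifier_factory=default_classifier,
    builder=None,
) -> CVReport:
    """Stratified k-fold evaluation over a grid of FN:FP cost ratios.

    Misclassification cost is c_FN * FN + c_FP * FP summed over held-out
    folds with (c_FN, c_FP) = (ratio, 1).  When ``builder`` is given it is
    called as ``builder(train_ids, test_ids) -> (X_train, X_test)`` inside
    every fold, so feature selection and interaction mining can be re-run on
    the training fold only (cross-validation of the entire process).
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    ids = list(features.base.index)
    y = labels.labels_for(ids)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels have a single class")
    X = features.matrix().to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DegenerateLabelsError(
                "stratification failed: a fold has a single class"
            )

    rows = []
    for ratio in cost_ratios:
        for fold, (tr, te) in enumerate(splits):
            if builder is not None:
                Xtr, Xte = builder([ids[i] for i in tr], [ids[i] for i in te])
                Xtr, Xte = np.asarray(Xtr), np.asarray(Xte)
            else:
                Xtr, Xte = X[tr], X[te]
            model = classifier_factory(ratio)
            model.fit(Xtr, y[tr])
            pred = model.predict(Xte)
            tp, fn, tn, fp = _fold_counts(y[te], pred)
            rows.append(
                {
                    "ratio": ratio,
                    "fold": fold,
                    "tp": tp,
                    "fn": fn,
                    "tn": tn,
                    "fp": fp,
                }
            )
    folds = pd.DataFrame(rows)
    agg = folds.groupby("ratio")[["tp", "fn", "tn", "fp"]].sum()
    summary = pd.DataFrame(
        {
            "ratio": agg.index,
            "sensitivity": agg.tp / (agg.tp + agg.fn),
            "specificity": agg.tn / (agg.tn + agg.fp),
            "overall": (agg.tp + agg.tn) / agg.sum(axis=1),
            "miscost": agg.index * agg.fn + agg.fp,
        }
    ).reset_index(drop=True)
    return CVReport(feature_set=features.name, summary=summary, folds=folds)


def _cv_auc(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int, classifier_factory
) -> float:
    from sklearn.metrics import roc_auc_score

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        model = classifier_factory(1.0)
        model.fit(X[tr], y[tr])
        scores[te] = model.decision_function(X[te])
    # LinearSVC scores increase toward the class with the larger label;
    # orient toward the positive (insulin-resistant) class
    sign = 1.0 if POSITIVE_CLASS > NEGATIVE_CLASS else -1.0
    return float(roc_auc_score(y == POSITIVE_CLASS, sign * scores))


def permutation_auc_test(
    features_base: FeatureSet,
    features_full: FeatureSet,
    labels: Assignment,
    n_perm: int = 1000,
    seed: int = 0,
    n_folds: int = 10,
    classifier_factory=default_classifier,
) -> tuple[float, float, np.ndarray]:
    """Added value of the SNP block, by permutation of cross-validated AUC.

    The observed statistic is the CV AUC of the full feature set.  Each null
    draw permutes the SNP rows across individuals (base features fixed),
    rebuilds the interaction products from the permuted SNPs, and recomputes
    the AUC.  Returns (p_value, observed AUC, null AUCs) with the add-one
    rule p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if features_full.snps.shape[1] == 0:
        raise ParameterError("full feature set has no SNP block to permute")
    ids = list(features_full.base.index)
    y = labels.labels_for(ids)
    obs = _cv_auc(features_full.matrix().to_numpy(), y, n_folds, seed, classifier_factory)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(ids))
        fs = features_full.with_permuted_snps(perm)
        null[b] = _cv_auc(fs.matrix().to_numpy(), y, n_folds, seed, classifier_factory)
    p = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    return p, obs, null


def classification_chisq(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Pearson chi-square (no continuity correction) of predicted vs actual."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ParameterError("label vectors must have the same length")
    p_levels = np.unique(np.concatenate([predicted, actual]))
    if len(p_levels) != 2:
        raise DomainError("both label vectors must be binary over the same levels")
    table = np.array(
        [
            [
                np.sum((predicted == a) & (actual == b))
                for b in p_levels
            ]
            for a in p_levels
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DomainError("degenerate 2x2 table: a margin is zero")
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat)
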