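"""Gauss-mixture vector quantization with hard-decision Lloyd fitting.

Each cluster i is a weighted Gaussian component (prior p_i, mean m_i,
covariance K_i).  A point x is encoded to the component minimizing the
distortion

    rho_i(x) = -ln p_i + 1/2 (x - m_i)' K_i^{-1} (x - m_i) + 1/2 ln det K_i,

which is exactly a maximum-a-posteriori component choice (the common
(d/2) ln 2pi constant is omitted; it cancels in encoding).  The Lloyd
iteration alternates hard assignment under this rule with per-cluster
updates p_i = n_i/n, m_i = sample mean, K_i = regularized sample covariance
(1-gamma) S_i + gamma (tr S_i / d) I.  The length function l(i) = -log2 p_i
is admissible with equality: sum_i 2^{-l(i)} = sum_i p_i = 1.

Model-order selection follows three routes: the decrement of the
quantization-error curve over sibship-bootstrap replicates, the gap
statistic (uniform reference over the data's principal-axis bounding box),
and the mean silhouette width.  The error curve recorded for K-selection is
the Mahalanobis + half-log-determinant part of the distortion; the -ln p_i
rate term is reported alongside in the full objective but excluded from the
curve because it grows by construction as priors shrink with K, so only the
error part is monotone in K.

Initialization is tree-structured (TSVQ): successively split the component
contributing most distortion along its leading covariance eigenvector and
re-run Lloyd to convergence after each split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DomainError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GaussComponent:
    prior: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        if not 0 < self.prior <= 1:
            raise ParameterError(f"prior must be in (0, 1], got {self.prior}")
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ParameterError("covariance shape does not match mean dimension")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")


class GMVQCodebook:
    """K weighted Gaussian components plus the encoding (distortion) rule."""

    def __init__(self, components: list[GaussComponent], variable_rate: bool = True):
        if not components:
            raise ParameterError("codebook needs at least one component")
        total = sum(c.prior for c in components)
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ParameterError(f"priors must sum to 1, got {total}")
        self.components = components
        self.variable_rate = variable_rate
        self._prepare()

    def _prepare(self) -> None:
        self._chol = []
        self._logdet = np.empty(self.k)
        for i, c in enumerate(self.components):
            try:
                L = np.linalg.cholesky(c.cov)
            except np.linalg.LinAlgError as exc:
                raise DomainError(
                    f"component {i}: singular covariance; increase the "
                    "regularization weight"
                ) from exc
            self._chol.append(L)
            self._logdet[i] = 2.0 * np.sum(np.log(np.diag(L)))
        self._priors = np.array([c.prior for c in self.components])

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def d(self) -> int:
        return self.components[0].mean.size

    def length_function(self, base: float = 2.0) -> np.ndarray:
        """l(i) = -log_base p_i (variable rate) or log_base K (fixed rate)."""
        if self.variable_rate:
            return -np.log(self._priors) / np.log(base)
        return np.full(self.k, np.log(self.k) / np.log(base))

    def distortions(self, X: np.ndarray) -> np.ndarray:
        """n x K matrix of rho_i(x); the rate term per the codebook's mode."""
        return self._error_terms(X) + self._rate_terms()

    def _rate_terms(self) -> np.ndarray:
        if self.variable_rate:
            return -np.log(self._priors)
        return np.full(self.k, np.log(self.k))

    def _error_terms(self, X: np.ndarray) -> np.ndarray:
        """n x K matrix of 1/2 Mahalanobis^2 + 1/2 ln det K_i."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.k))
        for i, c in enumerate(self.components):
            diff = X - c.mean
            w = solve_triangular(self._chol[i], diff.T, lower=True)
            out[:, i] = 0.5 * np.sum(w**2, axis=0) + 0.5 * self._logdet[i]
        return out


def encode(x: np.ndarray, codebook: GMVQCodebook) -> int:
    """Cluster index (1-based) minimizing rho_i(x); ties to the smallest."""
    rho = codebook.distortions(np.atleast_2d(x))
    return int(np.argmin(rho[0])) + 1


def encode_all(X: np.ndarray, codebook: GMVQCodebook) -> np.ndarray:
    """1-based hard assignments for every row of X."""
    return np.argmin(codebook.distortions(X), axis=1) + 1


def average_distortion(X: np.ndarray, codebook: GMVQCodebook) -> float:
    """Sample average of min_i rho_i(x) over the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ParameterError("need at least one sample")
    return float(np.min(codebook.distortions(X), axis=1).mean())


def quantization_error(X: np.ndarray, codebook: GMVQCodebook) -> float:
    """Average (over the encoding) of the Mahalanobis + log-det error part."""
    err = codebook._error_terms(np.atleast_2d(X))
    idx = np.argmin(codebook.distortions(X), axis=1)
    return float(err[np.arange(err.shape[0]), idx].mean())


@dataclass
class FitDiagnostics:
    distortion_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_reseeds: int = 0
    assignment: np.ndarray | None = None  # 1-based labels per row


def _regularize(S: np.ndarray, reg: float, floor: float) -> np.ndarray:
    d = S.shape[0]
    tr = np.trace(S)
    R = (1.0 - reg) * S + reg * (tr / d) * np.eye(d)
    return R + floor * np.eye(d)


def lloyd_fit(
    X: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
    reg: float = 1e-3,
    init: GMVQCodebook | None = None,
    variable_rate: bool = True,
) -> tuple[GMVQCodebook, FitDiagnostics]:
    """Hard-assignment Lloyd iteration from a random or given start.

    Empty clusters are reseeded at the point with the highest current
    distortion (logged and counted).  Apart from reseeding events the
    average distortion is non-increasing across iterations up to O(reg):
    the shrinkage applied to each cluster covariance perturbs the exact
    maximum-likelihood update by a term of that order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of samples n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.cov(X, rowvar=False, ddof=0).reshape(d, d)
    floor = 1e-8 * (np.trace(pooled) / d + 1.0)

    if init is None:
        rows = rng.choice(n, size=k, replace=False)
        comps = [
            GaussComponent(1.0 / k, X[r], _regularize(pooled, reg, floor)) for r in rows
        ]
        codebook = GMVQCodebook(comps, variable_rate=variable_rate)
    else:
        codebook = init

    diag = FitDiagnostics()
    prev = np.inf
    labels = np.ones(n, dtype=int)
    for it in range(max_iter):
        rho = codebook.distortions(X)
        labels = np.argmin(rho, axis=1)
        current = float(rho[np.arange(n), labels].mean())
        diag.distortion_history.append(current)
        diag.n_iter = it + 1
        if np.isfinite(prev) and abs(prev - current) <= tol * max(abs(prev), 1.0):
            diag.converged = True
            break
        prev = current

        # reseed empty clusters at the worst-encoded point
        point_cost = rho[np.arange(n), labels].copy()
        for i in range(codebook.k):
            if not np.any(labels == i):
                j = int(np.argmax(point_cost))
                labels[j] = i
                point_cost[j] = -np.inf
                diag.n_reseeds += 1
                logger.info("lloyd_fit: reseeded empty cluster %d at row %d", i, j)

        comps = []
        for i in range(codebook.k):
            members = X[labels == i]
            p = members.shape[0] / n
            m = members.mean(axis=0)
            S = np.cov(members, rowvar=False, ddof=0).reshape(d, d) if len(members) > 1 else np.zeros((d, d))
            comps.append(GaussComponent(p, m, _regularize(S, reg, floor)))
        codebook = GMVQCodebook(comps, variable_rate=variable_rate)

    diag.assignment = encode_all(X, codebook)
    return codebook, diag


def split_init(
    X: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
    reg: float = 1e-3,
    eps: float = 0.05,
    variable_rate: bool = True,
) -> GMVQCodebook:
    """Tree-structured (greedy splitting) initialization fitted to K components."""
    codebook, _ = tsvq_path(
        X, k, seed=seed, tol=tol, max_iter=max_iter, reg=reg, eps=eps,
        variable_rate=variable_rate,
    )[-1]
    return codebook


def tsvq_path(
    X: np.ndarray,
    k_max: int,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
    reg: float = 1e-3,
    eps: float = 0.05,
    variable_rate: bool = True,
) -> list[tuple[GMVQCodebook, FitDiagnostics]]:
    """Fitted codebooks for K = 1..k_max by successive splitting.

    Starting from the one-component fit, the component with the largest
    contribution to the average distortion is split into two children
    perturbed +/- eps standard deviations along its leading covariance
    eigenvector, then Lloyd runs to convergence; the path of all K fits is
    returned.
    """
    if eps <= 0:
        raise ParameterError("split perturbation eps must be > 0 (degenerate split)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    codebook, diag = lloyd_fit(
        X, 1, rng, tol=tol, max_iter=max_iter, reg=reg, variable_rate=variable_rate
    )
    out.append((codebook, diag))
    for k in range(2, k_max + 1):
        rho = codebook.distortions(X)
        labels = np.argmin(rho, axis=1)
        contrib = np.array(
            [rho[labels == i, i].sum() if np.any(labels == i) else -np.inf
             for i in range(codebook.k)]
        )
        target = int(np.argmax(contrib))
        comps = []
        for i, c in enumerate(codebook.components):
            if i != target:
                comps.append(GaussComponent(c.prior, c.mean, c.cov))
                continue
            vals, vecs = np.linalg.eigh(c.cov)
            direction = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
            for sgn in (+1.0, -1.0):
                comps.append(
                    GaussComponent(c.prior / 2.0, c.mean + sgn * eps * direction, c.cov)
                )
        init = GMVQCodebook(comps, variable_rate=variable_rate)
        codebook, diag = lloyd_fit(
            X, k, rng, tol=tol, max_iter=max_iter, reg=reg, init=init,
            variable_rate=variable_rate,
        )
        out.append((codebook, diag))
    return out


def fit_gmvq(
    X: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    **kw,
) -> tuple[GMVQCodebook, FitDiagnostics]:
    """Default fitting route: TSVQ splitting down to K, Lloyd-polished."""
    return tsvq_path(X, k, seed=seed, **kw)[-1]


def orient_labels(
    labels: np.ndarray, X: np.ndarray, column: int = 6, descending: bool = True
) -> np.ndarray:
    """Relabel clusters so label 1 has the highest mean of ``X[:, column]``.

    Cluster indices from a fit are arbitrary; the pipeline's convention is
    that cluster 1 is the insulin-resistant side, identified by the highest
    mean fasting-insulin residual (column 6 of the residual matrix).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    means = [X[labels == lab, column].mean() for lab in uniq]
    order = np.argsort(means)
    if descending:
        order = order[::-1]
    mapping = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


@dataclass
class KSelectionReport:
    """Evidence for the number of clusters from three criteria."""

    ks: list[int]
    boot_error: np.ndarray  # n_boot x k_max quantization-error curve
    boot_distortion: np.ndarray  # n_boot x k_max full-objective curve
    decrements: np.ndarray  # mean error decrement, length k_max - 1
    gap: np.ndarray  # gap statistic, length k_max
    gap_se: np.ndarray
    silhouette: dict[int, float]
    chosen: dict[str, int]


def _within_sse(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def _family_bootstrap_rows(
    rng: np.random.Generator, families: np.ndarray | None, n: int
) -> np.ndarray:
    """Row indices of one replicate: size-biased sibship draws, or plain iid."""
    if families is None:
        return rng.integers(0, n, size=n)
    fams, inverse = np.unique(families, return_inverse=True)
    members = [np.where(inverse == i)[0] for i in range(len(fams))]
    picks = rng.integers(0, n, size=len(fams))
    return np.concatenate([members[inverse[p]] for p in picks])


def select_k(
    X: np.ndarray,
    k_max: int,
    n_boot: int,
    seed: int,
    families: np.ndarray | None = None,
    gap_b: int = 50,
    tol: float = 1e-8,
    max_iter: int = 100,
    reg: float = 1e-3,
) -> KSelectionReport:
    """Estimate the number of clusters by decrement, gap, and silhouette.

    The error curve is computed on ``n_boot`` sibship-bootstrap replicates
    (plain bootstrap when ``families`` is None); gap and silhouette are
    computed on the original data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k_max < 2:
        raise ParameterError("k_max must be >= 2")
    if k_max > n:
        raise ParameterError("k_max exceeds the number of samples")
    ks = list(range(1, k_max + 1))

    boot_err = np.empty((n_boot, k_max))
    boot_dist = np.empty((n_boot, k_max))
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        rows = _family_bootstrap_rows(rng, families, n)
        Xb = X[rows]
        path = tsvq_path(Xb, k_max, seed=rng, tol=tol, max_iter=max_iter, reg=reg)
        for j, (cb, _) in enumerate(path):
            boot_err[b, j] = quantization_error(Xb, cb)
            boot_dist[b, j] = average_distortion(Xb, cb)
    mean_err = boot_err.mean(axis=0)
    decrements = mean_err[:-1] - mean_err[1:]
    chosen_decrement = int(np.argmax(decrements)) + 2

    # gap statistic on the original data (standard k-means within-cluster
    # dispersion, uniform reference in the PCA-aligned bounding box)
    rng = np.random.default_rng([seed, 10_007])
    path = tsvq_path(X, k_max, seed=rng, tol=tol, max_iter=max_iter, reg=reg)
    labels_by_k = [np.argmin(cb.distortions(X), axis=1) for cb, _ in path]

    def _kmeans_log_w(data: np.ndarray) -> np.ndarray:
        out = np.empty(k_max)
        for j, k in enumerate(ks):
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(2**31)))
            out[j] = np.log(km.fit(data).inertia_)
        return out

    log_w = _kmeans_log_w(X)
    center = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - center, full_matrices=False)
    proj = (X - center) @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    ref_log_w = np.empty((gap_b, k_max))
    for b in range(gap_b):
        ref = rng.uniform(lo, hi, size=proj.shape) @ vt + center
        ref_log_w[b] = _kmeans_log_w(ref)
    gap = ref_log_w.mean(axis=0) - log_w
    gap_se = ref_log_w.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / gap_b)
    chosen_gap = k_max
    for j in range(k_max - 1):
        if gap[j] >= gap[j + 1] - gap_se[j + 1]:
            chosen_gap = ks[j]
            break

    silhouette: dict[int, float] = {}
    for j in range(1, k_max):
        lab = labels_by_k[j]
        if len(np.unique(lab)) < 2:
            silhouette[ks[j]] = float("nan")
        else:
            silhouette[ks[j]] = float(silhouette_score(X, lab))
    chosen_sil = max(silhouette, key=lambda k_: (silhouette[k_], -k_))

    return KSelectionReport(
        ks=ks,
        boot_error=boot_err,
        boot_distortion=boot_dist,
        decrements=decrements,
        gap=gap,
        gap_se=gap_se,
        silhouette=silhouette,
        chosen={
            "decrement": chosen_decrement,
            "gap": chosen_gap,
            "silhouette": chosen_sil,
        },
    )
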