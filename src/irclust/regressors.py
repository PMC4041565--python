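"""Age/BMI regressor choice and residualization of the clinical features.

The candidate basis is 17 simple functions of age and BMI drawn from
Maclaurin and Fourier expansions (powers up to cubic, square roots, logs,
and sines/cosines at two frequencies).  A principal-component analysis of
the basis correlation matrix, bootstrapped over sibships, shows how few
directions carry the variability; the final regression design is fixed to
{1, AGE, BMI, AGE^2, BMI^2, AGE*BMI}, the quadratic terms the first two
components load on plus their first-order parents.  Each clinical feature is
residualized on that design by ordinary least squares, and the residual
matrix is the clustering input.

The trigonometric columns take their argument scaled to a quarter period
over fixed physiological ranges (age 20-90 y, BMI 14-45 kg/m^2), so every
basis column is a smooth monotone transform of age or BMI; with raw-unit
arguments the sines and cosines oscillate through dozens of periods across
the cohort and degenerate into noise columns that carry their own principal
components.  PCA is on the correlation matrix because the raw columns
differ in scale by orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import draw_bootstrap
from .cohort import CLINICAL_FEATURES, Cohort
from .errors import DomainError, ParameterError

logger = logging.getLogger(__name__)

#: The 17 basis columns, in fixed order.
BASIS_COLUMNS: tuple[str, ...] = (
    "AGE",
    "BMI",
    "AGE2",
    "BMI2",
    "AGE_BMI",
    "AGE3",
    "BMI3",
    "SQRT_AGE",
    "SQRT_BMI",
    "LOG_AGE",
    "LOG_BMI",
    "SIN_AGE",
    "SIN_BMI",
    "COS_AGE",
    "COS_BMI",
    "SIN_AGE_2",
    "COS_BMI_2",
)

#: The final regression design (intercept added separately).
DESIGN_COLUMNS: tuple[str, ...] = ("AGE", "BMI", "AGE2", "BMI2", "AGE_BMI")


#: fixed physiological ranges mapped onto a quarter period for the trig columns
TRIG_AGE_RANGE: tuple[float, float] = (20.0, 90.0)
TRIG_BMI_RANGE: tuple[float, float] = (14.0, 45.0)


def _quarter_period(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0) * (np.pi / 2.0)


def build_basis(cohort: Cohort) -> pd.DataFrame:
    """The n x 17 basis matrix, indexed by individual id."""
    age = cohort.ages
    bmi = cohort.bmis
    if np.any(age <= 0) or np.any(bmi <= 0):
        bad = np.asarray(cohort.ids)[(age <= 0) | (bmi <= 0)][0]
        raise DomainError(f"individual {bad}: age and BMI must be > 0 for log/sqrt")
    ta = _quarter_period(age, *TRIG_AGE_RANGE)
    tb = _quarter_period(bmi, *TRIG_BMI_RANGE)
    cols = {
        "AGE": age,
        "BMI": bmi,
        "AGE2": age**2,
        "BMI2": bmi**2,
        "AGE_BMI": age * bmi,
        "AGE3": age**3,
        "BMI3": bmi**3,
        "SQRT_AGE": np.sqrt(age),
        "SQRT_BMI": np.sqrt(bmi),
        "LOG_AGE": np.log(age),
        "LOG_BMI": np.log(bmi),
        "SIN_AGE": np.sin(ta),
        "SIN_BMI": np.sin(tb),
        "COS_AGE": np.cos(ta),
        "COS_BMI": np.cos(tb),
        "SIN_AGE_2": np.sin(ta / 2),
        "COS_BMI_2": np.cos(tb / 2),
    }
    return pd.DataFrame(cols, index=pd.Index(cohort.ids, name="id"))[list(BASIS_COLUMNS)]


@dataclass
class ScreeSummary:
    """Bootstrap distribution of basis-correlation eigenstructure."""

    #: one array of descending eigenvalues per replicate (length may differ
    #: if constant columns were dropped in a replicate)
    eigenvalues: list[np.ndarray]
    #: one array of cumulative variance ratios per replicate
    cumulative_ratios: list[np.ndarray]
    dropped_columns: list[list[str]]

    def median_cumulative_ratio(self, n_components: int) -> float:
        return float(
            np.median([r[min(n_components, len(r)) - 1] for r in self.cumulative_ratios])
        )


def _correlation_eigs(basis: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Eigenvalues/vectors of the basis correlation matrix.

    Constant columns (zero variance) are dropped; their names are returned.
    """
    sd = basis.std(ddof=1)
    dropped = sd.index[sd == 0].tolist()
    kept = basis.loc[:, sd > 0]
    corr = np.corrcoef(kept.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    return np.clip(vals[order], 0, None), vecs[:, order], dropped


def bootstrap_scree(cohort: Cohort, n_boot: int, seed: int) -> ScreeSummary:
    """Eigenvalue spectra of the basis over sibship-bootstrap replicates."""
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    eigs, ratios, dropped_all = [], [], []
    for b in range(n_boot):
        rep = draw_bootstrap(cohort, np.random.default_rng([seed, b]))
        vals, _, dropped = _correlation_eigs(build_basis(rep.cohort))
        if dropped:
            logger.info("scree replicate %d: dropped constant columns %s", b, dropped)
        eigs.append(vals)
        ratios.append(np.cumsum(vals) / vals.sum())
        dropped_all.append(dropped)
    return ScreeSummary(eigs, ratios, dropped_all)


def dominant_loadings(basis: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Basis columns carrying the first two principal components.

    Returns the columns whose absolute loading on either of the first two
    components of the basis correlation matrix is at least ``threshold``
    times that component's maximum absolute loading.  Exactly-tied loadings
    (e.g. duplicated columns) are kept together: the comparison is >=, so
    either both copies pass or neither does.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    vals, vecs, dropped = _correlation_eigs(basis)
    kept = [c for c in basis.columns if c not in dropped]
    selected: list[str] = []
    for comp in range(min(2, vecs.shape[1])):
        load = np.abs(vecs[:, comp])
        cut = threshold * load.max()
        selected.extend(c for c, v in zip(kept, load) if v >= cut)
    return [c for c in basis.columns if c in set(selected)]


@dataclass
class ResidualMatrix:
    """OLS residuals and fitted values of the 9 clinical features."""

    residuals: pd.DataFrame  # n x 9, indexed by id
    fitted: pd.DataFrame  # same shape
    coefficients: pd.DataFrame  # (1 + design terms) x 9

    @property
    def matrix(self) -> np.ndarray:
        return self.residuals.to_numpy()


def fit_residuals(cohort: Cohort) -> ResidualMatrix:
    """Regress each clinical feature on {1, AGE, BMI, AGE^2, BMI^2, AGE*BMI}."""
    basis = build_basis(cohort)
    design = np.column_stack(
        [np.ones(cohort.n)] + [basis[c].to_numpy() for c in DESIGN_COLUMNS]
    )
    names = ("intercept",) + DESIGN_COLUMNS
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the collinear columns via the QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DomainError(f"regression design is rank-deficient; collinear: {bad}")
    y = cohort.clinical_matrix().to_numpy()
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    idx = pd.Index(cohort.ids, name="id")
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=idx, columns=list(CLINICAL_FEATURES)),
        fitted=pd.DataFrame(fitted, index=idx, columns=list(CLINICAL_FEATURES)),
        coefficients=pd.DataFrame(beta, index=list(names), columns=list(CLINICAL_FEATURES)),
    )
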