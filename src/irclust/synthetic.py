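"""Synthetic sibship cohorts and genotype matrices with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a fixed sibship-size composition (106 singletons plus 120/40/15/5/1
families of sizes 2-6, i.e. 287 families and 557 women), age and BMI from
truncated-normal marginals, a latent two-cluster (insulin-resistant vs not)
label with configurable prevalence and within-family correlation, nine
clinical features that are linear in (AGE, BMI, AGE^2, BMI^2, AGE*BMI) plus a
cluster-specific mean shift and Gaussian noise, and SNPs under Hardy-Weinberg
with cluster-dependent allele frequencies for the truly associated ones,
near-duplicate high-LD pairs, and structured missingness.

Default shifts and residual standard deviations are calibrated to the
separation regime of the real cohort's published cluster summaries; the
triglycerides shift follows the value consistent with the published
t-statistic (cluster-1 mean 155.66) rather than the internally inconsistent
printed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CLINICAL_FEATURES, Cohort
from .config import DEFAULT_SEED
from .cohort import GenotypeMatrix
from .errors import ConsistencyError, ParameterError

#: Design terms the clinical features depend on, in fixed order.
DESIGN_TERMS: tuple[str, ...] = ("AGE", "BMI", "AGE2", "BMI2", "AGE_BMI")

# Cluster-2 ("not insulin resistant") feature means and sds, and the
# cluster-1 minus cluster-2 mean shifts, on the original measurement scale.
_CLUSTER2_MEANS = {
    "triglycerides": 92.28,
    "total_cholesterol": 185.33,
    "hdl": 49.81,
    "glucose0": 87.18,
    "glucose60": 157.69,
    "glucose120": 131.59,
    "insulin0": 5.86,
    "insulin60": 53.18,
    "insulin120": 49.30,
}
_RESIDUAL_SDS = {
    "triglycerides": 38.01,
    "total_cholesterol": 36.85,
    "hdl": 12.64,
    "glucose0": 9.38,
    "glucose60": 39.04,
    "glucose120": 32.45,
    "insulin0": 2.93,
    "insulin60": 24.88,
    "insulin120": 30.26,
}
_SHIFTS = {
    "triglycerides": 155.66 - 92.28,  # t-statistic-consistent cluster-1 mean
    "total_cholesterol": 198.82 - 185.33,
    "hdl": 43.47 - 49.81,
    "glucose0": 97.16 - 87.18,
    "glucose60": 204.17 - 157.69,
    "glucose120": 167.02 - 131.59,
    "insulin0": 10.79 - 5.86,
    "insulin60": 121.35 - 53.18,
    "insulin120": 110.54 - 49.30,
}


def _default_coefficients() -> pd.DataFrame:
    """Moderate age/BMI dependence, scaled to each feature's residual sd.

    Coefficients are sized so each design term contributes a fixed fraction
    of the feature's residual sd per marginal sd of the term (age sd 8.5 y,
    BMI sd 3.5 kg/m^2, and the delta-method sds of the quadratic terms).
    HDL falls with adiposity, the rest rise.
    """
    term_sd = {
        "AGE": 8.5,
        "BMI": 3.5,
        "AGE2": 2 * 49.5 * 8.5,
        "BMI2": 2 * 24.7 * 3.5,
        "AGE_BMI": np.hypot(49.5 * 3.5, 24.7 * 8.5),
    }
    weight = {"AGE": 0.25, "BMI": 0.35, "AGE2": 0.10, "BMI2": 0.10, "AGE_BMI": 0.10}
    rows = {}
    for feat in CLINICAL_FEATURES:
        s = _RESIDUAL_SDS[feat]
        sign = -1.0 if feat == "hdl" else 1.0
        rows[feat] = {t: sign * weight[t] * s / term_sd[t] for t in DESIGN_TERMS}
    return pd.DataFrame(rows).T.loc[list(CLINICAL_FEATURES), list(DESIGN_TERMS)]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study's composition."""

    n_families_by_size: dict[int, int] = field(
        default_factory=lambda: {1: 106, 2: 120, 3: 40, 4: 15, 5: 5, 6: 1}
    )
    age_mean: float = 49.5
    age_sd: float = 8.5
    age_bounds: tuple[float, float] = (30.0, 75.0)
    bmi_mean: float = 24.7
    bmi_sd: float = 3.5
    bmi_bounds: tuple[float, float] = (16.0, 40.0)
    prevalence: float = 177 / 557
    family_correlation: float = 0.0
    feature_shifts: dict[str, float] = field(default_factory=lambda: dict(_SHIFTS))
    residual_sds: dict[str, float] = field(default_factory=lambda: dict(_RESIDUAL_SDS))
    coefficients: pd.DataFrame | None = None
    n_snps: int = 100
    n_associated_snps: int = 3
    allele_shift: float = 0.25
    n_duplicate_snp_pairs: int = 3
    flip_prob: float = 0.01
    n_constant_snps: int = 2
    n_undergenotyped_snps: int = 2
    undergenotyped_rate: float = 0.35
    missing_rate: float = 0.02
    elevated_fraction: float = 0.02
    elevated_rate: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ParameterError("prevalence must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if not 0 <= self.family_correlation <= 1:
            raise ParameterError("family_correlation must be in [0, 1]")
        if any(c < 0 for c in self.n_families_by_size.values()):
            raise ParameterError("family counts must be non-negative")
        if sum(self.n_families_by_size.values()) == 0:
            raise ParameterError("configuration generates zero families")
        if any(s <= 0 for s in self.residual_sds.values()):
            raise ParameterError("residual sds must be > 0")
        n_special = (
            self.n_associated_snps
            + self.n_duplicate_snp_pairs
            + self.n_constant_snps
            + self.n_undergenotyped_snps
        )
        if self.n_snps < n_special:
            raise ParameterError(
                f"n_snps={self.n_snps} too small for {n_special} structured SNPs"
            )

    def coefficient_matrix(self) -> pd.DataFrame:
        if self.coefficients is not None:
            return self.coefficients
        return _default_coefficients()


@dataclass
class GroundTruth:
    """What the generator knows: labels, causal SNPs, regression truth."""

    labels: pd.Series  # id -> cluster label in {1, 2}
    associated_snps: list[str]
    duplicate_pairs: list[tuple[str, str]]
    coefficients: pd.DataFrame
    intercepts: pd.Series


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Cohort, GroundTruth]:
    """Draw a complete-case cohort with latent two-cluster structure."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    fam_sizes = [
        size
        for size, count in sorted(config.n_families_by_size.items())
        for _ in range(count)
    ]
    n = sum(fam_sizes)
    family_id = np.repeat([f"F{i + 1:04d}" for i in range(len(fam_sizes))], fam_sizes)
    ids = np.array([f"I{i + 1:04d}" for i in range(n)])

    # Latent cluster labels: exchangeable within family at the configured
    # correlation (family shares a single draw with probability rho).
    labels = np.empty(n, dtype=int)
    pos = 0
    for size in fam_sizes:
        if rng.random() < config.family_correlation:
            lab = 1 if rng.random() < config.prevalence else 2
            labels[pos : pos + size] = lab
        else:
            labels[pos : pos + size] = np.where(
                rng.random(size) < config.prevalence, 1, 2
            )
        pos += size

    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_bounds, n)
    bmi = _truncnorm(rng, config.bmi_mean, config.bmi_sd, *config.bmi_bounds, n)
    design = np.column_stack([age, bmi, age**2, bmi**2, age * bmi])

    coef = config.coefficient_matrix()
    # Intercepts chosen so the cluster-2 feature means land near their
    # configured values at the marginal means of the design terms.
    e_design = np.array(
        [
            config.age_mean,
            config.bmi_mean,
            config.age_mean**2 + config.age_sd**2,
            config.bmi_mean**2 + config.bmi_sd**2,
            config.age_mean * config.bmi_mean,
        ]
    )
    intercepts = pd.Series(
        {
            f: _CLUSTER2_MEANS[f] - float(coef.loc[f].to_numpy() @ e_design)
            for f in CLINICAL_FEATURES
        }
    )

    data = {"id": ids, "family_id": family_id, "age": age, "bmi": bmi}
    is_c1 = labels == 1
    for f in CLINICAL_FEATURES:
        values = (
            intercepts[f]
            + design @ coef.loc[f].to_numpy()
            + config.feature_shifts[f] * is_c1
            + rng.normal(0.0, config.residual_sds[f], n)
        )
        data[f] = np.clip(values, 0.0, None)

    cohort = Cohort(pd.DataFrame(data))
    truth = GroundTruth(
        labels=pd.Series(labels, index=ids),
        associated_snps=[],
        duplicate_pairs=[],
        coefficients=coef,
        intercepts=intercepts,
    )
    return cohort, truth


def generate_genotypes(
    cohort: Cohort,
    truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Draw genotypes with cluster-associated, duplicate, and filtered SNPs.

    Column roles (associated / near-duplicate copy / constant /
    under-genotyped / background) are recorded on ``truth``.  Background and
    associated SNPs follow Hardy-Weinberg at their major-allele frequencies;
    associated SNPs use a lower major-allele frequency in cluster 1.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed + 1)
    ids = cohort.ids
    if set(truth.labels.index) != set(ids):
        raise ConsistencyError("ground truth labels do not match cohort ids")
    n = cohort.n
    is_c1 = (truth.labels.loc[ids] == 1).to_numpy()

    n_assoc = config.n_associated_snps
    n_dup = config.n_duplicate_snp_pairs
    n_const = config.n_constant_snps
    n_under = config.n_undergenotyped_snps
    n_background = config.n_snps - n_assoc - n_dup - n_const - n_under

    columns: list[np.ndarray] = []
    roles: list[str] = []

    for _ in range(n_assoc):
        p2 = rng.uniform(0.75, 0.90)
        p1 = max(p2 - config.allele_shift, 0.05)
        p = np.where(is_c1, p1, p2)
        columns.append(rng.binomial(2, p).astype(float))
        roles.append("associated")
    for _ in range(n_background):
        p = rng.uniform(0.5, 0.95)
        columns.append(rng.binomial(2, p, n).astype(float))
        roles.append("background")
    for _ in range(n_const):
        columns.append(np.full(n, 2.0))
        roles.append("constant")
    for _ in range(n_under):
        p = rng.uniform(0.5, 0.95)
        columns.append(rng.binomial(2, p, n).astype(float))
        roles.append("undergenotyped")

    # Near-duplicate copies: the first copies an associated SNP when one
    # exists (so redundancy removal among causal SNPs is exercised), the
    # rest copy random background SNPs.
    dup_sources: list[int] = []
    background_idx = [i for i, r in enumerate(roles) if r == "background"]
    for j in range(n_dup):
        if j == 0 and n_assoc > 0:
            dup_sources.append(0)
        else:
            dup_sources.append(int(rng.choice(background_idx)))
    for src in dup_sources:
        copy = columns[src].copy()
        flips = rng.random(n) < config.flip_prob
        copy[flips] = rng.integers(0, 3, int(flips.sum())).astype(float)
        columns.append(copy)
        roles.append("duplicate")

    order = rng.permutation(len(columns))
    names = [f"SNP{i + 1:04d}" for i in range(len(columns))]
    mat = np.column_stack([columns[i] for i in order])
    role_by_name = {names[k]: roles[order[k]] for k in range(len(order))}
    pos_by_orig = {int(orig): k for k, orig in enumerate(order)}

    # Missingness: base rate everywhere, a higher rate for under-genotyped
    # SNPs, and an elevated-missingness subset of individuals (so the
    # per-individual filter has something to remove).
    miss = rng.random(mat.shape) < config.missing_rate
    for k in range(len(names)):
        if role_by_name[names[k]] == "undergenotyped":
            miss[:, k] |= rng.random(n) < config.undergenotyped_rate
    elevated = rng.random(n) < config.elevated_fraction
    miss[elevated, :] |= rng.random((int(elevated.sum()), mat.shape[1])) < config.elevated_rate
    mat[miss] = np.nan

    frame = pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=names)
    truth.associated_snps = [
        names[pos_by_orig[i]] for i, r in enumerate(roles) if r == "associated"
    ]
    n_base = n_assoc + n_background + n_const + n_under
    truth.duplicate_pairs = [
        (names[pos_by_orig[src]], names[pos_by_orig[n_base + j]])
        for j, src in enumerate(dup_sources)
    ]
    return GenotypeMatrix(frame)
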