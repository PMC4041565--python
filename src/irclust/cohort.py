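"""Core in-memory containers: cohort, genotype matrix, cluster assignment.

A cohort is one row per individual: an id, a family (sibship) id, age, BMI,
and nine clinical measurements (lipids plus the six OGTT glucose/insulin
values).  Family structure is carried by the ``family_id`` column only —
the analyses use sibship membership, never parental links.  Cohorts are
complete-case by construction: rows with any missing clinical value are
rejected (the I/O layer drops and logs them).

Genotypes are an individuals x SNPs matrix coded as the number of copies of
the major allele, 0/1/2, with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError, ParameterError

#: The nine clinical features, in the fixed column order used everywhere.
CLINICAL_FEATURES: tuple[str, ...] = (
    "triglycerides",
    "total_cholesterol",
    "hdl",
    "glucose0",
    "glucose60",
    "glucose120",
    "insulin0",
    "insulin60",
    "insulin120",
)

#: Mandatory cohort table columns, in order.
COHORT_COLUMNS: tuple[str, ...] = ("id", "family_id", "age", "bmi") + CLINICAL_FEATURES


@dataclass(frozen=True)
class Individual:
    """One study subject with the eleven measurements."""

    id: str
    family_id: str
    age: float
    bmi: float
    clinical: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise DomainError(f"individual {self.id}: age must be > 0, got {self.age}")
        if not self.bmi > 0:
            raise DomainError(f"individual {self.id}: bmi must be > 0, got {self.bmi}")
        if len(self.clinical) != len(CLINICAL_FEATURES):
            raise DomainError(
                f"individual {self.id}: expected {len(CLINICAL_FEATURES)} clinical "
                f"values, got {len(self.clinical)}"
            )
        arr = np.asarray(self.clinical, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DomainError(
                f"individual {self.id}: clinical values must be finite and non-negative"
            )


class Cohort:
    """A validated set of individuals partitioned into families.

    Internally a pandas DataFrame with :data:`COHORT_COLUMNS`; the frame is
    copied on construction and should be treated as immutable.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ConsistencyError(f"cohort frame missing columns: {missing}")
        df = frame.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True).copy()
        df["id"] = df["id"].astype(str)
        df["family_id"] = df["family_id"].astype(str)
        num = df.columns[2:]
        df[num] = df[num].astype(float)
        if len(df) == 0:
            raise DomainError("cohort is empty")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ConsistencyError(f"duplicate individual id: {dup!r}")
        if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
            bad = df.loc[(df["age"] <= 0) | (df["bmi"] <= 0), "id"].iloc[0]
            raise DomainError(f"individual {bad}: age and bmi must be > 0")
        clin = df[list(CLINICAL_FEATURES)].to_numpy()
        if not np.all(np.isfinite(clin)) or np.any(clin < 0):
            raise DomainError("clinical values must be finite and non-negative")
        self._df = df

    # -- basic accessors -------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def ids(self) -> list[str]:
        return self._df["id"].tolist()

    @property
    def family_ids(self) -> np.ndarray:
        """Per-row family id, aligned with the frame order."""
        return self._df["family_id"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self._df["age"].to_numpy()

    @property
    def bmis(self) -> np.ndarray:
        return self._df["bmi"].to_numpy()

    def clinical_matrix(self) -> pd.DataFrame:
        """n x 9 frame of the clinical features, indexed by individual id."""
        m = self._df.set_index("id")[list(CLINICAL_FEATURES)]
        return m

    def families(self) -> dict[str, list[str]]:
        """Mapping family id -> member individual ids."""
        return {
            fam: grp["id"].tolist()
            for fam, grp in self._df.groupby("family_id", sort=False)
        }

    def family_sizes(self) -> dict[str, int]:
        return {fam: len(m) for fam, m in self.families().items()}

    def size_histogram(self) -> dict[int, int]:
        """Mapping sibship size -> number of families of that size."""
        sizes = pd.Series(self.family_sizes())
        return sizes.value_counts().sort_index().to_dict()

    @property
    def n_families(self) -> int:
        return self._df["family_id"].nunique()

    def individuals(self) -> list[Individual]:
        return [
            Individual(
                id=row["id"],
                family_id=row["family_id"],
                age=row["age"],
                bmi=row["bmi"],
                clinical=tuple(row[f] for f in CLINICAL_FEATURES),
            )
            for _, row in self._df.iterrows()
        ]

    def subset(self, ids: Iterable[str]) -> "Cohort":
        ids = list(ids)
        sub = self._df[self._df["id"].isin(set(ids))]
        if len(sub) != len(ids):
            missing = set(ids) - set(sub["id"])
            raise ConsistencyError(f"ids not in cohort: {sorted(missing)[:5]}")
        order = pd.Categorical(sub["id"], categories=ids, ordered=True)
        return Cohort(sub.assign(_o=order).sort_values("_o").drop(columns="_o"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"Cohort(n={self.n}, families={self.n_families})"


class GenotypeMatrix:
    """Individuals x SNPs matrix of major-allele counts with missing values.

    Entries are 0, 1, 2, or NaN.  Row ids are individual ids (a subset of a
    cohort's), columns are SNP names.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.astype(float).copy()
        vals = df.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise DomainError(
                f"genotype entry out of {{0,1,2,NA}} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}: {vals[r, c]!r}"
            )
        if df.index.duplicated().any():
            raise ConsistencyError("duplicate individual ids in genotype matrix")
        if df.columns.duplicated().any():
            raise ConsistencyError("duplicate SNP names in genotype matrix")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self._df = df

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def snps(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def missing_per_snp(self) -> pd.Series:
        return self._df.isna().sum(axis=0)

    def missing_per_individual(self) -> pd.Series:
        return self._df.isna().sum(axis=1)

    def n_genotyped_per_snp(self) -> pd.Series:
        return self._df.notna().sum(axis=0)

    @property
    def n_missing(self) -> int:
        return int(self._df.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"GenotypeMatrix({n} individuals x {m} SNPs, {self.n_missing} missing)"


class Assignment:
    """Mapping individual id -> cluster label in 1..K, every label used."""

    def __init__(self, labels: Mapping[str, int] | pd.Series):
        s = pd.Series(labels).astype(int)
        s.index = s.index.astype(str)
        if len(s) == 0:
            raise ParameterError("assignment is empty")
        used = sorted(s.unique())
        k = used[-1]
        if used != list(range(1, k + 1)):
            raise ParameterError(
                f"cluster labels must be 1..K with every label used, got {used}"
            )
        self._s = s
        self.k = k

    @property
    def series(self) -> pd.Series:
        return self._s

    def labels_for(self, ids: Iterable[str]) -> np.ndarray:
        ids = list(ids)
        missing = set(ids) - set(self._s.index)
        if missing:
            raise ConsistencyError(f"assignment missing ids: {sorted(missing)[:5]}")
        return self._s.loc[ids].to_numpy()

    def cluster_sizes(self) -> dict[int, int]:
        return self._s.value_counts().sort_index().to_dict()

    def __len__(self) -> int:
        return len(self._s)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Assignment):
            return NotImplemented
        return self._s.sort_index().equals(other._s.sort_index())

    def __repr__(self) -> str:
        return f"Assignment(n={len(self)}, k={self.k})"
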