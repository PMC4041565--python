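"""Reading and writing the pipeline's tab-separated interchange files.

All tables are TSV with a header row.  The missing-genotype token is "NA".
Every filtering decision (rows dropped for missing clinical values) emits one
structured log line with in/out counts, mirroring how such exclusions are
reported in cohort studies.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CLINICAL_FEATURES, COHORT_COLUMNS, Assignment, Cohort, GenotypeMatrix
from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort TSV, dropping (and logging) incomplete rows.

    Raises :class:`FormatError` if a mandatory column is absent and
    :class:`ParseError` (with the row number) on a non-numeric cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory column(s) {missing_cols}")
    numeric_cols = list(COHORT_COLUMNS[2:])
    parsed = df.copy()
    for col in numeric_cols:
        raw = df[col].replace("", MISSING_TOKEN)
        vals = pd.to_numeric(raw.where(raw != MISSING_TOKEN), errors="coerce")
        bad = vals.isna() & (raw != MISSING_TOKEN)
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} in "
                f"column {col!r} at line {row}"
            )
        parsed[col] = vals
    complete = parsed[numeric_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "read_cohort: dropped %d of %d rows with missing values (complete-case)",
            n_dropped,
            len(parsed),
        )
    return Cohort(parsed.loc[complete])


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV (first column ``id``, then one column per SNP).

    Entries must be 0, 1, 2, or the missing token; anything else raises
    :class:`ParseError` with its coordinates.  Missingness tallies per SNP
    and per individual are logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'id'")
    df = df.set_index("id")
    out = pd.DataFrame(index=df.index.astype(str), dtype=float)
    for col in df.columns:
        raw = df[col].replace("", MISSING_TOKEN)
        vals = pd.to_numeric(raw.where(raw != MISSING_TOKEN), errors="coerce")
        bad = (vals.isna() & (raw != MISSING_TOKEN)) | (~vals.isin([0, 1, 2]) & vals.notna())
        if bad.any():
            i = bad.idxmax()
            raise ParseError(
                f"{path}: invalid genotype {df.loc[i, col]!r} at (row {i!r}, "
                f"column {col!r}); expected 0/1/2/{MISSING_TOKEN}"
            )
        out[col] = vals.to_numpy()
    gm = GenotypeMatrix(out)
    logger.info(
        "read_genotypes: %d individuals x %d SNPs, %d missing entries "
        "(max per SNP %d, max per individual %d)",
        *gm.shape,
        gm.n_missing,
        int(gm.missing_per_snp().max()) if gm.snps else 0,
        int(gm.missing_per_individual().max()) if gm.ids else 0,
    )
    return gm


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.frame.copy()
    # keep integer formatting for observed calls
    out = df.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_assignment(path: str | Path) -> Assignment:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster": int})
    for col in ("id", "cluster"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return Assignment(pd.Series(df["cluster"].to_numpy(), index=df["id"]))


def write_assignment(assignment: Assignment, path: str | Path) -> None:
    df = assignment.series.rename("cluster").rename_axis("id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a generic id-indexed numeric TSV (residuals, fitted values...)."""
    return pd.read_csv(path, sep="\t", index_col="id")


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.rename_axis("id").to_csv(path, sep="\t")
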