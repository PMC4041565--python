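"""Sibship-structured bootstrap resampling.

A replicate is drawn by sampling M individuals (M = number of families)
uniformly at random with replacement and including each chosen individual's
entire sibship once per draw — equivalently, M sibship draws with probability
proportional to sibship size.  This keeps (i) the number of sibships per
replicate fixed at M, and is the constructive description of the resampling
scheme used throughout the pipeline (scree, cluster-number, and test
procedures).  Repeated families are materialized as distinct copies with
draw-suffixed individual ids so downstream matrix code needs no multiset
awareness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class BootstrapReplicate:
    """One resample: the drawn family ids and the materialized cohort view."""

    family_draws: list[str]
    cohort: Cohort
    #: for each replicate row, the id of the source-cohort row it copies
    source_ids: list[str]


def draw_bootstrap(cohort: Cohort, seed: int | np.random.Generator) -> BootstrapReplicate:
    """Draw one sibship bootstrap replicate (M size-biased family draws)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cohort.frame
    m = cohort.n_families
    picks = rng.integers(0, cohort.n, size=m)
    fam_of_row = df["family_id"].to_numpy()
    drawn_families = [fam_of_row[i] for i in picks]

    groups = {fam: sub for fam, sub in df.groupby("family_id", sort=False)}
    parts = []
    source: list[str] = []
    for draw_idx, fam in enumerate(drawn_families):
        sub = groups[fam].copy()
        source.extend(sub["id"])
        sub["id"] = sub["id"] + f"#b{draw_idx}"
        sub["family_id"] = sub["family_id"] + f"#b{draw_idx}"
        parts.append(sub)
    replicate = Cohort(pd.concat(parts, ignore_index=True))
    return BootstrapReplicate(drawn_families, replicate, source)


def bootstrap_statistic(
    cohort: Cohort,
    statistic: Callable[[Cohort], Sequence[float] | float],
    n_boot: int,
    seed: int,
) -> list[np.ndarray]:
    """Evaluate ``statistic`` on ``n_boot`` replicates.

    Each replicate uses a seed derived from (seed, replicate index), so runs
    are reproducible and independent of evaluation order.  Replicates on
    which the statistic raises are skipped and logged.
    """
    if n_boot < 0:
        raise ParameterError("n_boot must be >= 0")
    out: list[np.ndarray] = []
    n_failed = 0
    for b in range(n_boot):
        rep = draw_bootstrap(cohort, np.random.default_rng([seed, b]))
        try:
            out.append(np.atleast_1d(np.asarray(statistic(rep.cohort), dtype=float)))
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed:
        logger.info("bootstrap_statistic: %d of %d replicates failed", n_failed, n_boot)
    return out
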