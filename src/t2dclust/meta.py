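"""Genetic risk score associations from summary statistics.

A cluster's GRS-trait association is obtained without individual-level data
by combining the member variants' per-allele effects with inverse-variance
weighted (IVW) fixed-effects meta-analysis, optionally with per-variant
multipliers (e.g. cluster weights):

    beta = sum(w_i b_i / se_i^2) / sum(w_i^2 / se_i^2)
    se   = 1 / sqrt(sum(w_i^2 / se_i^2))

With all w_i = 1 this is the textbook fixed-effects estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class MetaResult(NamedTuple):
    beta: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class GrsAssociation:
    """Combined association of one cluster's GRS with one trait or outcome."""

    cluster: str
    trait: str
    beta: float
    se: float
    p: float
    n_variants: int


def ivw_meta(betas: Sequence[float], ses: Sequence[float],
             weights: Sequence[float] | None = None) -> MetaResult:
    """Inverse-variance weighted fixed-effects combination.

    ``weights`` are optional per-variant multipliers (risk-score loadings);
    the default of 1 gives the plain fixed-effects estimator.  The p-value is
    two-sided from the normal z = beta/se.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("empty input")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if (s <= 0).any():
        raise ValueError("all ses must be > 0")
    w = np.ones_like(b) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != b.shape:
        raise ValueError("weights must match betas in length")
    inv_var = 1.0 / (s * s)
    denom = float(np.sum(w * w * inv_var))
    beta = float(np.sum(w * b * inv_var)) / denom
    se = 1.0 / np.sqrt(denom)
    z = beta / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, z=z, p=p)


def grs_trait_assoc(cluster: str, members: Sequence[str],
                    trait_stats: pd.DataFrame, trait: str,
                    weights: pd.Series | None = None) -> GrsAssociation:
    """IVW GRS association of a cluster's member variants with one trait.

    ``trait_stats`` is indexed by variant id with ``beta``/``se`` columns
    already aligned to the risk allele.  Members missing from the table are
    dropped with a warning; supplying ``weights`` (indexed by variant)
    switches to the cluster-weighted estimator.
    """
    present = [v for v in members if v in trait_stats.index]
    missing = sorted(set(members) - set(present))
    if missing:
        logger.warning("%s/%s: dropping %d member variants without stats: %s",
                       cluster, trait, len(missing), ", ".join(missing))
    if not present:
        raise ValueError(f"{cluster}/{trait}: no member variant has aligned stats")
    sub = trait_stats.loc[present]
    w = None if weights is None else weights.loc[present].to_numpy()
    res = ivw_meta(sub["beta"].to_numpy(), sub["se"].to_numpy(), w)
    return GrsAssociation(cluster=cluster, trait=trait, beta=res.beta,
                          se=res.se, p=res.p, n_variants=len(present))


def bonferroni_flag(p: float, n_tests: int) -> bool:
    """Significance at the Bonferroni-corrected level 0.05 / n_tests (strict <)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return p < 0.05 / n_tests


def association_table(assocs: Sequence[GrsAssociation],
                      n_tests: int | None = None) -> pd.DataFrame:
    """Tidy clusters x traits results table with optional Bonferroni flags."""
    df = pd.DataFrame([vars(a) for a in assocs])
    if n_tests is not None:
        df["significant"] = [bonferroni_flag(p, n_tests) for p in df["p"]]
    return df
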