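"""Individual-level cluster risk scores and cohort stratification.

Per individual, a cluster GRS is the sum of risk-allele dosages weighted by
the cluster weights of the cluster's top-weighted variants (weight >=
cutoff).  Individuals at or above the cohort's 90th-percentile GRS for a
cluster are flagged as top-decile for that cluster; an individual flagged in
exactly one cluster is "uniquely assigned" to it.  GRS-trait associations
are tested per cohort with linear or logistic regression adjusting for sex,
age and principal components, then combined across cohorts by IVW
fixed-effects meta-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .meta import MetaResult, ivw_meta

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """Risk-allele dosages and phenotypes/covariates for one cohort."""

    dosages: pd.DataFrame      # individuals x variants, values in [0, 2]
    phenotypes: pd.DataFrame   # individuals x (traits, sex, age, PCs)
    label: str = "cohort"


@dataclass
class GrsProfile:
    """Per-individual cluster GRS, top-decile flags and unique assignment."""

    grs: pd.DataFrame                # individuals x clusters
    deciles: pd.DataFrame            # decile rank 1..10 per cluster
    top_decile: pd.DataFrame         # boolean flags
    unique_top_cluster: pd.Series    # cluster label or None per individual


def individual_grs(dosages: pd.DataFrame, variant_weights: pd.DataFrame,
                   cutoff: float) -> pd.DataFrame:
    """Cluster GRS per individual: sum of dosage * weight over member variants.

    Only variants at or above the cutoff in a cluster contribute to that
    cluster's score.  A member variant missing from the dosage matrix is an
    error (silent dropping would bias scores), as are dosages outside [0, 2].
    """
    arr = dosages.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 2)).any():
        raise ValueError("dosages must lie in [0, 2]")
    out = {}
    for cluster in variant_weights.columns:
        w = variant_weights[cluster]
        members = list(w.index[w >= cutoff])
        missing = [v for v in members if v not in dosages.columns]
        if missing:
            raise KeyError(
                f"{cluster}: member variants missing from dosages: {missing}")
        if members:
            out[cluster] = dosages[members].to_numpy() @ w.loc[members].to_numpy()
        else:
            out[cluster] = np.zeros(len(dosages))
    return pd.DataFrame(out, index=dosages.index)


def top_decile_flags(grs: pd.DataFrame) -> GrsProfile:
    """Flag individuals at or above the cohort's 90th-percentile GRS per cluster.

    The threshold is the ceil(n/10)-th largest score (nearest-rank decile),
    so with distinct values exactly ceil(n/10) individuals are flagged; ties
    at the threshold are all included and the inflation logged.
    """
    n = len(grs)
    if n < 10:
        raise ValueError("need at least 10 individuals for decile flags")
    k = math.ceil(n / 10)
    flags = {}
    deciles = {}
    for cluster in grs.columns:
        values = grs[cluster].to_numpy(dtype=float)
        thresh = np.sort(values)[::-1][k - 1]
        flag = values >= thresh
        if flag.sum() > k:
            logger.warning("%s: ties at the decile boundary inflate the top "
                           "decile from %d to %d individuals",
                           cluster, k, int(flag.sum()))
        flags[cluster] = flag
        # decile rank 1 (lowest) .. 10 (highest), average ranks for ties
        r = stats.rankdata(values, method="average")
        deciles[cluster] = np.ceil(10.0 * r / n).astype(int)
    flags = pd.DataFrame(flags, index=grs.index)
    n_flags = flags.sum(axis=1)
    unique = pd.Series(
        [flags.columns[row.to_numpy()][0] if cnt == 1 else None
         for cnt, (_, row) in zip(n_flags, flags.iterrows())],
        index=grs.index, dtype=object)
    return GrsProfile(grs=grs, deciles=pd.DataFrame(deciles, index=grs.index),
                      top_decile=flags, unique_top_cluster=unique)


def assoc_grs_trait(grs: pd.Series, trait: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    binary: bool | None = None,
                    scale_by_trait_sd: bool = False) -> MetaResult:
    """GRS coefficient from a linear (continuous) or logistic (binary) model.

    Covariates (sex, age, PCs) enter additively; rows with any missing value
    are dropped (complete-case).  ``binary=None`` auto-detects a 0/1 trait.
    With ``scale_by_trait_sd`` the effect (and its SE) is expressed per raw
    trait standard deviation.
    """
    df = pd.DataFrame({"grs": grs, "trait": trait})
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        logger.info("complete-case analysis dropped %d rows", n_before - len(df))
    n_cov = 0 if covariates is None else covariates.shape[1]
    if len(df) < n_cov + 2:
        raise ValueError("too few complete cases for the model")
    y = df["trait"].to_numpy(dtype=float)
    X = sm.add_constant(df.drop(columns="trait"))
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        fit = sm.Logit(y, X).fit(disp=False)
    else:
        fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params["grs"]), float(fit.bse["grs"])
    if scale_by_trait_sd and not binary:
        sd = float(np.std(y, ddof=1))
        if sd == 0:
            raise ValueError("trait has zero variance")
        beta, se = beta / sd, se / sd
    z = beta / se
    return MetaResult(beta=beta, se=se, z=z,
                      p=2.0 * float(stats.norm.sf(abs(z))))


def compare_extremes(trait: pd.Series, groups: pd.Series,
                     test: str = "kruskal") -> tuple[float, float]:
    """Compare a trait across subgroups (unique-top-decile vs others).

    ``test="kruskal"`` runs the Kruskal-Wallis test on continuous traits;
    ``test="chi2"`` a chi-squared contingency test (used for the sex
    proportion).  Returns (statistic, p).
    """
    df = pd.DataFrame({"trait": trait, "group": groups}).dropna()
    samples = [sub["trait"].to_numpy() for _, sub in df.groupby("group")]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least 2 nonempty groups")
    if test == "kruskal":
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:  # all values identical in every group
            return 0.0, 1.0
        return float(stat), float(p)
    if test == "chi2":
        table = pd.crosstab(df["group"], df["trait"])
        res = stats.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def meta_cohorts(betas, ses) -> MetaResult:
    """Combine per-cohort GRS-trait effects by IVW fixed-effects meta-analysis."""
    return ivw_meta(betas, ses)
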