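"""Turn raw cluster weights into cluster memberships.

Two independent procedures select the membership cutoff on variant cluster
weights:

* the **delta rule** - pool all variant weights across clusters, sort them
  in descending order, and call the top 5% of consecutive differences
  "significant"; the weight at the last significant delta marks the start of
  the long tail of uninformative weights and becomes the cutoff;
* the **stepwise rule** - per cluster, meta-analyze the cluster's
  top-weighted trait over its variants, removing variants from lowest to
  highest weight until the meta-analysis p reaches its first local minimum.

Membership is inclusive (weight >= cutoff) and soft: a variant may belong
to several clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta import ivw_meta


@dataclass
class ClusterModel:
    """Cluster weights plus the membership cutoff and the resulting members."""

    variant_weights: pd.DataFrame   # variants x K
    trait_weights: pd.DataFrame     # (2*traits) x K, _pos/_neg row labels
    cutoff: float
    memberships: dict[str, list[str]] = field(default_factory=dict)

    def multi_cluster_variants(self) -> dict[str, list[str]]:
        """Variants that are top-weighted in more than one cluster."""
        counts: dict[str, list[str]] = {}
        for cluster, members in self.memberships.items():
            for v in members:
                counts.setdefault(v, []).append(cluster)
        return {v: cs for v, cs in counts.items() if len(cs) > 1}


def delta_threshold(weights, top_frac: float = 0.05) -> float:
    """Membership cutoff from the sorted-weight delta procedure.

    Weights (pooled over all variants and clusters) are sorted in descending
    order; the consecutive differences are ranked and the top ``top_frac``
    fraction counted as significant.  The returned cutoff is the weight just
    above the last significant delta - the boundary where the long tail of
    uninformative weights begins.
    """
    w = np.sort(np.asarray(weights, dtype=float))[::-1]
    if w.size < 3:
        raise ValueError("need at least 3 weights")
    deltas = w[:-1] - w[1:]
    nonzero = np.flatnonzero(deltas > 0)
    if nonzero.size == 0:
        raise ValueError("all weights are equal; no deltas to rank")
    k = max(1, math.ceil(top_frac * deltas.size))
    # top-k nonzero deltas; ties resolve toward higher weights so duplicate
    # tail weights (zero deltas) can never become significant
    order = nonzero[np.argsort(-deltas[nonzero], kind="stable")]
    significant = order[:k]
    last = int(significant.max())
    return float(w[last])


def stepwise_threshold(cluster_variants: pd.DataFrame) -> list[str]:
    """Variant subset at the first local minimum of the stepwise meta-analysis p.

    ``cluster_variants`` carries columns ``variant_id``, ``weight``,
    ``beta``, ``se`` where beta/se refer to the cluster's top-weighted trait.
    Starting from the full set, the lowest-weighted variant is removed one at
    a time; the sweep stops at the first set whose IVW p is smaller than both
    neighbors' (the ends of the sweep count as p = +inf).  Comparisons use
    |z| (monotone in p) so that extremely small p-values do not underflow.
    """
    required = {"variant_id", "weight", "beta", "se"}
    if not required.issubset(cluster_variants.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if cluster_variants[["beta", "se"]].isna().any().any():
        raise ValueError("missing top-trait stats for some variants")
    df = cluster_variants.sort_values(
        ["weight", "variant_id"], kind="stable").reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no variants supplied")
    # abs z of the IVW meta for each suffix set (drop j lowest-weighted)
    abs_z = [abs(ivw_meta(df["beta"].iloc[j:], df["se"].iloc[j:]).z)
             for j in range(n)]
    for j in range(n):
        left = abs_z[j - 1] if j > 0 else -np.inf
        right = abs_z[j + 1] if j < n - 1 else -np.inf
        if abs_z[j] > left and abs_z[j] > right:
            break
    else:  # exact ties everywhere: fall back to the global minimum p
        j = int(np.argmax(abs_z))
    keep = df["variant_id"].iloc[j:]
    order = {v: i for i, v in enumerate(cluster_variants["variant_id"])}
    return sorted(keep, key=order.get)


def assign_clusters(variant_weights: pd.DataFrame, cutoff: float,
                    trait_weights: pd.DataFrame | None = None) -> ClusterModel:
    """Inclusive membership assignment: variant in cluster iff weight >= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    memberships = {
        str(c): list(variant_weights.index[variant_weights[c] >= cutoff])
        for c in variant_weights.columns}
    if trait_weights is None:
        trait_weights = pd.DataFrame(columns=variant_weights.columns)
    return ClusterModel(variant_weights=variant_weights,
                        trait_weights=trait_weights, cutoff=cutoff,
                        memberships=memberships)


def defining_traits(trait_weights: pd.DataFrame, cluster: str,
                    top_n: int = 5) -> pd.DataFrame:
    """Top-weighted traits of one cluster, with their direction of effect.

    Trait rows are labeled ``<trait>_pos`` / ``<trait>_neg``; the returned
    frame has columns ``trait``, ``direction``, ``weight``, ranked by
    descending weight (ties broken by trait name for stability).
    """
    if cluster not in trait_weights.columns:
        raise KeyError(f"unknown cluster {cluster!r}")
    col = trait_weights[cluster]
    ranked = col.reset_index()
    ranked.columns = ["label", "weight"]
    ranked = ranked.sort_values(["weight", "label"],
                                ascending=[False, True],
                                kind="stable").head(top_n)
    ranked["direction"] = [
        "pos" if lbl.endswith("_pos") else "neg" for lbl in ranked["label"]]
    ranked["trait"] = [lbl[:-4] for lbl in ranked["label"]]
    return ranked[["trait", "direction", "weight"]].reset_index(drop=True)
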