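"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end so every stage is testable
without consortium downloads:

* :func:`gen_summary_stats` - per-trait GWAS summary-statistic tables whose
  z-scores carry a planted sparse nonnegative bilinear structure
  (W_true . H_true with signed trait directions) plus Gaussian z-score noise;
* :func:`gen_cohort` - Hardy-Weinberg dosages and phenotypes with planted
  cluster-GRS effects and covariate structure;
* :func:`gen_annotations` - per-cell-type chromatin-state intervals with
  planted overlap enrichment for chosen (cluster, cell type) pairs.

Every generator is driven by a single seeded generator and returns a
machine-readable truth record; recovery tests read the truth only from it.
Defaults plant defining variant-trait |z| of about 5-15 (the scale of
genome-wide-significant loci) against unit z-score noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortData, individual_grs
from .enrichment import CredibleSet, credible_set
from .matrix import TraitAssociation, VariantManifest, write_manifest


@dataclass
class PlantedModel:
    """Ground truth for the summary-statistic generator."""

    k_true: int
    w_true: pd.DataFrame        # variants x K, sparse nonnegative blocks
    h_true: pd.DataFrame        # K x 2*traits (_pos/_neg columns)
    manifest: list[VariantManifest]
    trait_n: pd.Series          # per-trait GWAS sample size
    noise_sd: float
    seed: int

    @property
    def traits(self) -> list[str]:
        return [c[:-4] for c in self.h_true.columns if c.endswith("_pos")]

    @property
    def memberships(self) -> dict[str, list[str]]:
        return {c: list(self.w_true.index[self.w_true[c] > 0])
                for c in self.w_true.columns}

    def z_signed(self) -> pd.DataFrame:
        """Planted signed z-score matrix (variants x traits, z-score units)."""
        traits = self.traits
        pos = self.h_true[[f"{t}_pos" for t in traits]].to_numpy()
        neg = self.h_true[[f"{t}_neg" for t in traits]].to_numpy()
        z = self.w_true.to_numpy() @ (pos - neg)
        return pd.DataFrame(z, index=self.w_true.index, columns=traits)

    def truth_record(self) -> dict:
        return {
            "seed": self.seed,
            "k_true": self.k_true,
            "noise_sd": self.noise_sd,
            "memberships": self.memberships,
            "trait_n": {t: float(n) for t, n in self.trait_n.items()},
            "w_true": {c: self.w_true[c].to_dict() for c in self.w_true.columns},
            "h_true": {c: self.h_true[c].to_dict() for c in self.h_true.columns},
        }


def make_planted_model(k_true: int = 3,
                       variants_per_cluster: int = 8,
                       traits_per_cluster: int = 4,
                       n_null_traits: int = 0,
                       noise_sd: float = 1.0,
                       signal_range: tuple[float, float] = (5.0, 15.0),
                       weight_range: tuple[float, float] = (0.8, 1.2),
                       n_range: tuple[int, int] = (50_000, 200_000),
                       seed: int = 0) -> PlantedModel:
    """Plant disjoint variant blocks and defining traits for ``k_true`` clusters.

    Each cluster owns ``variants_per_cluster`` variants (weights uniform in
    ``weight_range``) and ``traits_per_cluster`` defining traits, each with a
    random direction and |z| magnitude uniform in ``signal_range``; optional
    null traits carry no signal.  Variants are spread 1 Mb apart with
    unambiguous allele pairs so the manifest passes every upstream filter.
    """
    if k_true < 1 or variants_per_cluster < 3 or traits_per_cluster < 2:
        raise ValueError("each cluster needs >= 3 variants and >= 2 traits")
    rng = np.random.default_rng(seed)
    n_variants = k_true * variants_per_cluster
    n_traits = k_true * traits_per_cluster + n_null_traits

    variant_ids = [f"rs{i + 1:04d}" for i in range(n_variants)]
    traits = [f"trait_{j + 1:02d}" for j in range(n_traits)]
    clusters = [f"cluster_{k + 1}" for k in range(k_true)]

    W = pd.DataFrame(0.0, index=variant_ids, columns=clusters)
    H = pd.DataFrame(0.0, index=clusters,
                     columns=[f"{t}_pos" for t in traits]
                     + [f"{t}_neg" for t in traits])
    for k, cluster in enumerate(clusters):
        vs = variant_ids[k * variants_per_cluster:(k + 1) * variants_per_cluster]
        W.loc[vs, cluster] = rng.uniform(*weight_range, size=len(vs))
        ts = traits[k * traits_per_cluster:(k + 1) * traits_per_cluster]
        for t in ts:
            side = "pos" if rng.random() < 0.5 else "neg"
            H.loc[cluster, f"{t}_{side}"] = rng.uniform(*signal_range)

    manifest = []
    for i, vid in enumerate(variant_ids):
        chrom = str(i % 22 + 1)
        pos = 1_000_000 * (i // 22 + 1) + 10_000 * (i % 22)
        manifest.append(VariantManifest(
            variant_id=vid, chrom=chrom, pos=pos,
            risk_allele="A", other_allele="G",
            locus_label=f"locus_{i + 1}", is_distinct_signal=False))

    trait_n = pd.Series(rng.integers(n_range[0], n_range[1], size=n_traits),
                        index=traits, dtype=float)
    return PlantedModel(k_true=k_true, w_true=W, h_true=H, manifest=manifest,
                        trait_n=trait_n, noise_sd=noise_sd, seed=seed)


def gen_summary_stats(model: PlantedModel,
                      ) -> tuple[dict[str, list[TraitAssociation]], dict]:
    """Per-trait summary-statistic tables realizing the planted z structure.

    Observed z = planted z + Normal(0, noise_sd); betas are z * se with
    se = 1/sqrt(n_t).  About half the rows are emitted in the flipped allele
    orientation (effect allele = non-risk allele, beta negated) to exercise
    risk-allele alignment downstream.  Returns the tables and the truth
    record.
    """
    rng = np.random.default_rng(model.seed)
    z_true = model.z_signed()
    by_id = {m.variant_id: m for m in model.manifest}
    tables: dict[str, list[TraitAssociation]] = {}
    from scipy import stats as _st
    for trait in model.traits:
        n_t = float(model.trait_n[trait])
        se = 1.0 / np.sqrt(n_t)
        z_obs = z_true[trait].to_numpy() + \
            model.noise_sd * rng.standard_normal(len(z_true))
        flip = rng.random(len(z_true)) < 0.5
        rows = []
        for i, vid in enumerate(z_true.index):
            m = by_id[vid]
            beta = float(z_obs[i] * se)
            if flip[i]:
                ea, oa, beta = m.other_allele, m.risk_allele, -beta
            else:
                ea, oa = m.risk_allele, m.other_allele
            rows.append(TraitAssociation(
                variant_id=vid, trait_name=trait, effect_allele=ea,
                other_allele=oa, beta=beta, se=float(se),
                p=float(2.0 * _st.norm.sf(abs(z_obs[i]))), n=n_t))
        tables[trait] = rows
    return tables, model.truth_record()


def write_summary_stats(model: PlantedModel,
                        tables: dict[str, list[TraitAssociation]],
                        truth: dict, out_dir: str | Path) -> None:
    """Write tables in the matrix-builder input format plus truth.json."""
    out = Path(out_dir)
    (out / "gwas").mkdir(parents=True, exist_ok=True)
    write_manifest(model.manifest, out / "manifest.tsv")
    by_id = {m.variant_id: m for m in model.manifest}
    for trait, rows in tables.items():
        pd.DataFrame(
            [(a.variant_id, by_id[a.variant_id].chrom, by_id[a.variant_id].pos,
              a.effect_allele, a.other_allele, a.beta, a.se, a.p, a.n)
             for a in rows],
            columns=["SNP", "CHR", "POS", "EA", "NEA", "BETA", "SE", "P", "N"],
        ).to_csv(out / "gwas" / f"{trait}.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def gen_cohort(variant_weights: pd.DataFrame,
               n_individuals: int,
               trait_effects: dict[str, dict[str, float]] | None = None,
               binary_traits: frozenset[str] = frozenset(),
               allele_freqs: pd.Series | None = None,
               cutoff: float = 0.75,
               noise_sd: float = 1.0,
               label: str = "sim_cohort",
               seed: int = 0) -> tuple[CohortData, dict]:
    """Simulate a T2D cohort with planted cluster-GRS trait effects.

    Dosages are Binomial(2, f) per variant (Hardy-Weinberg); each trait in
    ``trait_effects`` is a linear combination of the cluster GRSs (keys:
    cluster labels) plus sex/age/PC covariate effects and Gaussian noise.
    Traits named in ``binary_traits`` are emitted 0/1 through a logistic
    link.  Returns the cohort and the truth record.
    """
    rng = np.random.default_rng(seed)
    variants = list(variant_weights.index)
    if allele_freqs is None:
        allele_freqs = pd.Series(rng.uniform(0.1, 0.9, size=len(variants)),
                                 index=variants)
    if ((allele_freqs <= 0) | (allele_freqs >= 1)).any():
        raise ValueError("allele frequencies must lie in (0, 1)")
    dosages = pd.DataFrame(
        rng.binomial(2, allele_freqs.to_numpy(),
                     size=(n_individuals, len(variants))).astype(float),
        columns=variants,
        index=[f"id_{i + 1}" for i in range(n_individuals)])
    grs = individual_grs(dosages, variant_weights, cutoff)

    pheno = pd.DataFrame(index=dosages.index)
    pheno["sex"] = rng.integers(0, 2, size=n_individuals).astype(float)
    pheno["age"] = rng.normal(60.0, 10.0, size=n_individuals)
    pheno["PC1"] = rng.standard_normal(n_individuals)
    pheno["PC2"] = rng.standard_normal(n_individuals)
    cov_effects = {"sex": 0.3, "age": 0.01, "PC1": 0.1, "PC2": 0.1}

    trait_effects = trait_effects or {}
    for trait, effects in trait_effects.items():
        lin = np.zeros(n_individuals)
        for cluster, eff in effects.items():
            lin += eff * grs[cluster].to_numpy()
        for cov, eff in cov_effects.items():
            lin += eff * pheno[cov].to_numpy()
        if trait in binary_traits:
            logits = lin - np.mean(lin)     # ~50% prevalence
            prob = 1.0 / (1.0 + np.exp(-logits))
            pheno[trait] = (rng.random(n_individuals) < prob).astype(float)
        else:
            pheno[trait] = lin + noise_sd * rng.standard_normal(n_individuals)

    truth = {"seed": seed, "cutoff": cutoff, "noise_sd": noise_sd,
             "trait_effects": trait_effects,
             "cov_effects": cov_effects,
             "binary_traits": sorted(binary_traits),
             "allele_freqs": {v: float(f) for v, f in allele_freqs.items()}}
    return CohortData(dosages=dosages, phenotypes=pheno, label=label), truth


# ---------------------------------------------------------------------------
# Credible sets and annotations
# ---------------------------------------------------------------------------

def gen_credible_sets(cluster_loci: dict[str, list[str]],
                      variants_per_locus: int = 3,
                      omega: float = 0.04,
                      seed: int = 0) -> dict[str, list[CredibleSet]]:
    """Small synthetic credible sets per locus for the enrichment stage.

    Each locus receives ``variants_per_locus`` members 100 bp apart with
    z-scores uniform in (2, 6) at se = 0.05; posteriors follow from the
    Wakefield ABFs at the given omega.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[CredibleSet]] = {}
    idx = 0
    for cluster, loci in cluster_loci.items():
        sets = []
        for locus in loci:
            chrom = str(idx % 22 + 1)
            base = 1_000_000 * (idx + 1)
            z = rng.uniform(2.0, 6.0, size=variants_per_locus)
            se = 0.05
            df = pd.DataFrame({
                "variant_id": [f"{locus}_v{i + 1}"
                               for i in range(variants_per_locus)],
                "chrom": chrom,
                "pos": [base + 100 * i for i in range(variants_per_locus)],
                "beta": z * se,
                "se": se,
            })
            sets.append(credible_set(locus, df, omega))
            idx += 1
        out[cluster] = sets
    return out


def gen_annotations(clusters: dict[str, list[CredibleSet]],
                    cell_types: list[str],
                    enriched_pairs: set[tuple[str, str]] = frozenset(),
                    overlap_prob_high: float = 0.9,
                    overlap_prob_low: float = 0.1,
                    seed: int = 0) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-cell-type interval annotations with planted overlap enrichment.

    A credible-set variant of a locus in an enriched (cluster, cell type)
    pair is covered by a qualifying enhancer interval with probability
    ``overlap_prob_high``, otherwise ``overlap_prob_low``.  Non-covered
    variants receive a non-qualifying ("Quiescent") interval so files are
    never empty.  Returns BED-like frames (chrom, start, end, state) per
    cell type and the truth record.
    """
    if not (0 <= overlap_prob_low <= 1 and 0 <= overlap_prob_high <= 1):
        raise ValueError("overlap probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    beds: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        rows = []
        for cluster, loci in clusters.items():
            p = (overlap_prob_high if (cluster, ct) in enriched_pairs
                 else overlap_prob_low)
            for cs in loci:
                for chrom, pos in zip(cs.variants["chrom"], cs.variants["pos"]):
                    start = int(pos) - 1           # BED 0-based half-open
                    if rng.random() < p:
                        rows.append((str(chrom), start, start + 10,
                                     "Active Enhancer 1"))
                    else:
                        rows.append((str(chrom), start, start + 10,
                                     "Quiescent"))
        beds[ct] = pd.DataFrame(rows,
                                columns=["chrom", "start", "end", "state"])
    truth = {"seed": seed,
             "enriched_pairs": sorted(map(list, enriched_pairs)),
             "overlap_prob_high": overlap_prob_high,
             "overlap_prob_low": overlap_prob_low}
    return beds, truth


def write_annotations(beds: dict[str, pd.DataFrame],
                      out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ct, bed in beds.items():
        bed.to_csv(out / f"{ct}.bed", sep="\t", index=False, header=False)
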