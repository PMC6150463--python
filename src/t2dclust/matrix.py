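"""Build the variant x trait association matrix from GWAS summary statistics.

Every association is aligned to the T2D risk-increasing allele, standardized
to a z-score (beta / SE), and scaled by the square root of the study's mean
per-SNP sample size so that traits measured in studies of very different
size become comparable.  The signed matrix Z is then split column-wise into
a nonnegative "doubled trait" matrix X (one ``_pos`` and one ``_neg`` column
per trait) that a nonnegative factorization can consume without losing
direction-of-effect information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Strand-ambiguous allele pairs: indistinguishable after strand flip.
AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: Default column mapping for GWAS summary-statistic tables.
GWAS_COLUMNS = {
    "snp": "SNP", "chrom": "CHR", "pos": "POS", "effect_allele": "EA",
    "other_allele": "NEA", "beta": "BETA", "se": "SE", "p": "P", "n": "N",
}

MANIFEST_COLUMNS = ["SNP", "CHR", "POS", "RISK_ALLELE", "OTHER_ALLELE",
                    "LOCUS", "DISTINCT_SIGNAL"]


class AlleleMismatchError(ValueError):
    """Raised when an association's alleles match the manifest in neither orientation."""


class AmbiguousAlleleError(ValueError):
    """Raised when a manifest entry carries a strand-ambiguous allele pair."""


@dataclass(frozen=True)
class VariantManifest:
    """One T2D variant with its risk-increasing allele and locus label."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    risk_allele: str
    other_allele: str
    locus_label: str = ""
    is_distinct_signal: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: risk and other allele identical")

    @property
    def is_ambiguous(self) -> bool:
        return frozenset({self.risk_allele, self.other_allele}) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class TraitAssociation:
    """A single variant-trait association from a GWAS summary-statistic file."""

    variant_id: str
    trait_name: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}/{self.trait_name}: se must be > 0")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}/{self.trait_name}: n must be > 0")


@dataclass
class VariantTraitMatrix:
    """Aligned, scaled z-score matrix (variants x traits) with missingness mask.

    ``values`` holds the scaled z-scores with missing cells zero-filled;
    ``mask`` is True where the cell was actually observed; ``n_bar`` is the
    per-trait mean sample size used for scaling.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    n_bar: pd.Series

    @property
    def variants(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Allele alignment and scaling
# ---------------------------------------------------------------------------

def align_to_risk_allele(assoc: TraitAssociation, entry: VariantManifest) -> float:
    """Return the association beta oriented to the manifest's risk allele.

    The sign convention for the whole analysis is "per copy of the T2D
    risk-increasing allele": if the GWAS reported the effect for the other
    allele the beta is negated.
    """
    if entry.is_ambiguous:
        raise AmbiguousAlleleError(
            f"{entry.variant_id}: ambiguous allele pair "
            f"{{{entry.risk_allele},{entry.other_allele}}}")
    if (assoc.effect_allele == entry.risk_allele
            and assoc.other_allele == entry.other_allele):
        return assoc.beta
    if (assoc.effect_allele == entry.other_allele
            and assoc.other_allele == entry.risk_allele):
        return -assoc.beta
    raise AlleleMismatchError(
        f"{entry.variant_id}: alleles {assoc.effect_allele}/{assoc.other_allele} "
        f"match manifest {entry.risk_allele}/{entry.other_allele} in neither orientation")


def standardize_and_scale(beta: float, se: float, n_bar: float,
                          direction: str = "divide") -> float:
    """z = beta / se, rescaled by sqrt(mean sample size).

    ``direction="divide"`` (default) divides z by sqrt(n_bar), putting traits
    from studies of different sizes on a comparable per-sample scale;
    ``"multiply"`` is exposed for sensitivity analysis.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if n_bar <= 0:
        raise ValueError("n_bar must be > 0")
    z = beta / se
    if direction == "divide":
        return z / math.sqrt(n_bar)
    if direction == "multiply":
        return z * math.sqrt(n_bar)
    raise ValueError(f"unknown scaling direction {direction!r}")


# ---------------------------------------------------------------------------
# Variant and trait filters
# ---------------------------------------------------------------------------

def trait_filter_cutoff(n_variants: int) -> float:
    """|z| cutoff equivalent to a two-sided Bonferroni p of 0.05 / n_variants."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return float(stats.norm.isf(0.05 / n_variants / 2.0))


def filter_traits(z_unscaled: pd.DataFrame, n_variants: int | None = None) -> list[str]:
    """Traits to retain: at least one variant with |z| past the Bonferroni cutoff.

    The filter runs on unscaled z-scores (beta/SE), since the p-value is a
    property of the association itself, not of the sqrt-N rescaling.
    """
    if z_unscaled.size == 0:
        raise ValueError("empty z-score matrix")
    if n_variants is None:
        n_variants = z_unscaled.shape[0]
    cutoff = trait_filter_cutoff(n_variants)
    max_abs = z_unscaled.abs().max(axis=0, skipna=True)
    return [t for t in z_unscaled.columns if max_abs[t] > cutoff]


def select_variants(candidates: Sequence[VariantManifest],
                    reference_p: Mapping[str, float],
                    window_bp: int = 500_000,
                    p_cutoff: float = 0.05) -> list[VariantManifest]:
    """Apply the reference-association and 500 kb proximity filters.

    Candidates must be at least nominally associated with T2D in the
    reference meta-analysis (p < ``p_cutoff``).  Among candidates that do not
    represent distinct signals, only one variant is kept within any
    ``window_bp`` window on the same chromosome - the one with the smaller
    reference p (ties broken by genomic order).  Distinct-signal variants are
    exempt from the proximity rule.
    """
    passing = [m for m in candidates
               if m.variant_id in reference_p
               and reference_p[m.variant_id] < p_cutoff]
    distinct = [m for m in passing if m.is_distinct_signal]
    regular = [m for m in passing if not m.is_distinct_signal]
    # Greedy by ascending reference p; genomic order breaks ties.
    regular.sort(key=lambda m: (reference_p[m.variant_id], m.chrom, m.pos))
    kept: list[VariantManifest] = []
    for m in regular:
        if any(k.chrom == m.chrom and abs(k.pos - m.pos) <= window_bp
               for k in kept):
            continue
        kept.append(m)
    out = kept + distinct
    order = {m.variant_id: i for i, m in enumerate(candidates)}
    out.sort(key=lambda m: order[m.variant_id])
    return out


# ---------------------------------------------------------------------------
# Matrix assembly and the signed split
# ---------------------------------------------------------------------------

def build_matrix(manifest: Sequence[VariantManifest],
                 trait_tables: Mapping[str, Iterable[TraitAssociation]],
                 scale_direction: str = "divide",
                 apply_trait_filter: bool = True) -> VariantTraitMatrix:
    """Assemble the scaled z-score matrix Z from per-trait association tables.

    Per trait: betas are aligned to the risk allele, n_bar is the mean of the
    per-SNP sample sizes over the variants present in that trait's table,
    and z/sqrt(n_bar) fills the column.  Variant-trait cells with no GWAS
    entry are zero-filled (neutral in the nonnegative factorization) and
    recorded in the mask.
    """
    by_id = {m.variant_id: m for m in manifest}
    variant_ids = [m.variant_id for m in manifest]
    z_unscaled = pd.DataFrame(np.nan, index=variant_ids,
                              columns=list(trait_tables))
    n_bar = pd.Series(np.nan, index=list(trait_tables), dtype=float)

    for trait, assocs in trait_tables.items():
        rows = [a for a in assocs if a.variant_id in by_id]
        if not rows:
            continue
        n_bar[trait] = float(np.mean([a.n for a in rows]))
        for a in rows:
            beta = align_to_risk_allele(a, by_id[a.variant_id])
            z_unscaled.loc[a.variant_id, trait] = beta / a.se

    if apply_trait_filter:
        retained = filter_traits(z_unscaled)
        dropped = sorted(set(z_unscaled.columns) - set(retained))
        if dropped:
            logger.info("trait filter removed %d traits: %s",
                        len(dropped), ", ".join(dropped))
        z_unscaled = z_unscaled[retained]
        n_bar = n_bar[retained]

    mask = z_unscaled.notna()
    n_missing = int((~mask).to_numpy().sum())
    if n_missing:
        logger.info("zero-filling %d missing variant-trait cells", n_missing)
    scale = np.sqrt(n_bar.to_numpy())
    if (scale <= 0).any() or np.isnan(scale).any():
        raise ValueError("every retained trait needs a positive mean sample size")
    if scale_direction == "divide":
        values = z_unscaled / scale
    elif scale_direction == "multiply":
        values = z_unscaled * scale
    else:
        raise ValueError(f"unknown scaling direction {scale_direction!r}")
    values = values.fillna(0.0)
    return VariantTraitMatrix(values=values, mask=mask, n_bar=n_bar)


def split_signed(z: pd.DataFrame) -> pd.DataFrame:
    """Split the signed matrix Z into the nonnegative doubled-trait matrix X.

    Each trait column becomes two: ``_pos`` holds positive z-scores, ``_neg``
    holds negated negative z-scores, zeros elsewhere, so that
    ``X[:, pos] - X[:, neg]`` reconstructs Z exactly.
    """
    arr = z.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("Z contains non-finite entries")
    pos = np.where(arr > 0, arr, 0.0)
    neg = np.where(arr < 0, -arr, 0.0)
    cols = [f"{c}_pos" for c in z.columns] + [f"{c}_neg" for c in z.columns]
    return pd.DataFrame(np.hstack([pos, neg]), index=z.index, columns=cols)


def signed_to_z(x: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`split_signed`: pos columns minus neg columns."""
    traits = [c[:-4] for c in x.columns if c.endswith("_pos")]
    pos = x[[f"{t}_pos" for t in traits]].to_numpy()
    neg = x[[f"{t}_neg" for t in traits]].to_numpy()
    return pd.DataFrame(pos - neg, index=x.index, columns=traits)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[VariantManifest]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return [VariantManifest(variant_id=str(r.SNP), chrom=str(r.CHR),
                            pos=int(r.POS), risk_allele=str(r.RISK_ALLELE),
                            other_allele=str(r.OTHER_ALLELE),
                            locus_label=str(r.LOCUS),
                            is_distinct_signal=bool(r.DISTINCT_SIGNAL))
            for r in df.itertuples()]


def write_manifest(manifest: Sequence[VariantManifest], path: str | Path) -> None:
    pd.DataFrame(
        [(m.variant_id, m.chrom, m.pos, m.risk_allele, m.other_allele,
          m.locus_label, int(m.is_distinct_signal)) for m in manifest],
        columns=MANIFEST_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gwas_table(path: str | Path, trait_name: str,
                    column_map: Mapping[str, str] | None = None,
                    ) -> list[TraitAssociation]:
    """Read one trait's tab-delimited summary statistics.

    ``column_map`` overrides the default header names (keys: snp, chrom, pos,
    effect_allele, other_allele, beta, se, p, n).
    """
    cols = dict(GWAS_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t")
    return [TraitAssociation(
        variant_id=str(r[cols["snp"]]), trait_name=trait_name,
        effect_allele=str(r[cols["effect_allele"]]),
        other_allele=str(r[cols["other_allele"]]),
        beta=float(r[cols["beta"]]), se=float(r[cols["se"]]),
        p=float(r[cols["p"]]), n=float(r[cols["n"]]))
        for _, r in df.iterrows()]


def read_gwas_dir(gwas_dir: str | Path,
                  column_map: Mapping[str, str] | None = None,
                  ) -> dict[str, list[TraitAssociation]]:
    """Read every ``<trait>.tsv`` in a directory into association tables."""
    tables = {}
    for path in sorted(Path(gwas_dir).glob("*.tsv")):
        tables[path.stem] = read_gwas_table(path, path.stem, column_map)
    return tables


def write_matrix(vtm: VariantTraitMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vtm.values.to_csv(out / "Z.tsv", sep="\t")
    vtm.mask.astype(int).to_csv(out / "mask.tsv", sep="\t")
    split_signed(vtm.values).to_csv(out / "X.tsv", sep="\t")
    vtm.n_bar.rename("N_BAR").to_csv(out / "n_bar.tsv", sep="\t")
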