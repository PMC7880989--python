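"""Polygenic risk score computation and within-cohort standardization.

The raw score for sample i is sum_j d_ij * beta_j where d_ij counts the
effect allele (the complement 2 - d is used where the effect allele is the
panel's non-counted allele) and beta_j is the published per-allele log
odds ratio. Scores are standardized to mean 0 / unit variance over a
standardization population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PrsWeight:
    """One variant's contribution to a score definition."""

    variant_id: str            # dosage column in the cohort panel
    weight: float              # log OR per effect allele
    counted_allele: str = ""   # allele the dosage column counts, if known
    use_complement: bool = False  # score on 2 - d (effect allele = other allele)
    source_subphenotype: Optional[str] = None
    source_rsid: Optional[str] = None  # catalog lead if matched via proxy

    def __post_init__(self):
        if not np.isfinite(self.weight):
            raise ValueError(f"non-finite weight for {self.variant_id}")


@dataclass(frozen=True)
class PrsDefinition:
    """A cancer site code plus its pruned (variant, weight) list."""

    cancer: str
    weights: tuple[PrsWeight, ...]
    provenance: str = "full"

    def __post_init__(self):
        ids = [w.variant_id for w in self.weights]
        if len(ids) != len(set(ids)):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variants in PRS definition: {dupes}")

    @property
    def variant_ids(self) -> list[str]:
        return [w.variant_id for w in self.weights]

    def with_weights(self, weights: Sequence[PrsWeight], provenance: str) -> "PrsDefinition":
        return PrsDefinition(cancer=self.cancer, weights=tuple(weights), provenance=provenance)


@dataclass
class PrsVector:
    """Raw and standardized scores with the moments used to standardize."""

    raw: pd.Series
    z: pd.Series
    mean: float
    sd: float


def compute_prs(dosages: pd.DataFrame, prs: PrsDefinition) -> pd.Series:
    """Raw weighted allele-dosage sum per sample.

    Missing dosages must already be mean-imputed. Raises KeyError naming
    the first absent variant column.
    """
    missing = [v for v in prs.variant_ids if v not in dosages.columns]
    if missing:
        raise KeyError(f"PRS variant(s) absent from dosage matrix: {missing}")
    score = np.zeros(len(dosages))
    for w in prs.weights:
        d = dosages[w.variant_id].to_numpy(dtype=float)
        if w.use_complement:
            d = 2.0 - d
        score += w.weight * d
    return pd.Series(score, index=dosages.index, name=f"prs_{prs.cancer}")


def standardize_prs(raw: pd.Series, population_mask: Optional[pd.Series] = None) -> PrsVector:
    """Standardize raw scores using moments from the standardization population.

    The population defaults to all samples; sd uses the n-1 denominator.
    Raises ValueError for fewer than two population samples or a constant
    score.
    """
    if population_mask is None:
        pop = raw
    else:
        pop = raw[population_mask.reindex(raw.index, fill_value=False)]
    if len(pop) < 2:
        raise ValueError("standardization population must contain at least 2 samples")
    mu = float(pop.mean())
    sigma = float(pop.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("constant PRS: standard deviation is zero")
    z = (raw - mu) / sigma
    z.name = (raw.name or "prs") + "_z"
    return PrsVector(raw=raw, z=z, mean=mu, sd=sigma)


def definitions_to_frame(defs: Sequence[PrsDefinition]) -> pd.DataFrame:
    rows = []
    for d in defs:
        for w in d.weights:
            rows.append(
                {
                    "cancer": d.cancer,
                    "variant_id": w.variant_id,
                    "counted_allele": w.counted_allele,
                    "weight": w.weight,
                    "use_complement": w.use_complement,
                    "source_subphenotype": w.source_subphenotype or "",
                    "source_rsid": w.source_rsid or "",
                    "provenance": d.provenance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer",
            "variant_id",
            "counted_allele",
            "weight",
            "use_complement",
            "source_subphenotype",
            "source_rsid",
            "provenance",
        ],
    )


def frame_to_definitions(df: pd.DataFrame) -> list[PrsDefinition]:
    defs = []
    for (cancer, provenance), grp in df.groupby(["cancer", "provenance"], sort=False):
        weights = tuple(
            PrsWeight(
                variant_id=str(r.variant_id),
                weight=float(r.weight),
                counted_allele=str(getattr(r, "counted_allele", "") or ""),
                use_complement=bool(getattr(r, "use_complement", False)),
                source_subphenotype=(str(r.source_subphenotype) or None)
                if getattr(r, "source_subphenotype", "") not in ("", None)
                else None,
                source_rsid=(str(r.source_rsid) or None)
                if getattr(r, "source_rsid", "") not in ("", None)
                else None,
            )
            for r in grp.itertuples(index=False)
        )
        defs.append(PrsDefinition(cancer=str(cancer), weights=weights, provenance=str(provenance)))
    return defs
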