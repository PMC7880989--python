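"""Curation of a literature variant-association catalog.

Reduces a raw table of published variant-phenotype associations to at most
one usable association per (variant, phenotype/sub-phenotype, ancestry
group) and applies the eligibility filters used for score construction:
autosomal variants only, predominantly European-ancestry discovery
populations, genome-wide significance, and a reported, sign-determinable
effect estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

AUTOSOMES = {str(c) for c in range(1, 23)}

#: defaults mirroring the published analysis
GW_SIGNIFICANCE = 5e-8
MIN_EUR_FRACTION = 0.70

CATALOG_COLUMNS = [
    "study_id",
    "phenotype",
    "subphenotype",
    "ancestry_label",
    "ancestry_eur_fraction",
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect",
    "effect_type",
    "p_value",
    "imputation_info",
    "phenotype_rank",
]


@dataclass(frozen=True)
class CatalogRecord:
    """One published variant-phenotype association.

    ``effect`` is stored on the log-odds scale regardless of how the source
    reported it; use :func:`parse_effect` when constructing records from an
    odds ratio. ``phenotype_rank`` encodes phenotype breadth (0 = broadest)
    and is consumed by priority pruning.
    """

    study_id: str
    phenotype: str
    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    p_value: float
    ancestry_eur_fraction: float = 1.0
    ancestry_label: str = "EUR"
    other_allele: Optional[str] = None
    effect: Optional[float] = None
    effect_type: str = "beta"
    subphenotype: Optional[str] = None
    imputation_info: Optional[float] = None
    phenotype_rank: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.effect_type not in ("OR", "beta"):
            raise ValueError(f"effect_type must be 'OR' or 'beta', got {self.effect_type!r}")
        if not self.effect_allele:
            raise ValueError("effect_allele must be a non-empty string")

    @property
    def key(self) -> tuple:
        return (self.rsid, self.phenotype, self.subphenotype, self.ancestry_label)

    @property
    def has_effect(self) -> bool:
        return self.effect is not None and math.isfinite(self.effect)

    @property
    def has_effect_allele(self) -> bool:
        return bool(self.effect_allele) and self.effect_allele not in ("?", "NA", "N")


def parse_effect(value: float, effect_type: str) -> float:
    """Convert a reported effect to the log-odds scale used as PRS weight."""
    if effect_type == "OR":
        if value <= 0:
            raise ValueError(f"odds ratio must be positive, got {value}")
        return math.log(value)
    return float(value)


def _dedupe_sort_key(rec: CatalogRecord) -> tuple:
    # usable records (known risk allele + effect) always beat unusable ones;
    # then smallest p, highest imputation info, lexicographic study id
    usable = rec.has_effect and rec.has_effect_allele
    info = rec.imputation_info if rec.imputation_info is not None else -math.inf
    return (not usable, rec.p_value, -info, rec.study_id)


def dedupe_associations(records: Iterable[CatalogRecord]) -> list[CatalogRecord]:
    """Keep one association per (variant, phenotype/sub-phenotype, ancestry).

    Among candidates with a known risk allele and effect estimate, the
    record with the smallest p-value wins; ties break on larger imputation
    info, then lexicographic study id. Groups in which no record is usable
    retain their smallest-p member (it is removed later by the eligibility
    filter, preserving the per-reason exclusion count).
    """
    groups: dict[tuple, list[CatalogRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in groups:
            groups[rec.key] = []
            order.append(rec.key)
        groups[rec.key].append(rec)
    return [min(groups[k], key=_dedupe_sort_key) for k in order]


@dataclass
class Exclusion:
    record: CatalogRecord
    reason: str


@dataclass
class CurationResult:
    kept: list[CatalogRecord]
    excluded: list[Exclusion] = field(default_factory=list)

    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for exc in self.excluded:
            counts[exc.reason] = counts.get(exc.reason, 0) + 1
        return counts


def filter_catalog(
    records: Iterable[CatalogRecord],
    *,
    gw_significance: float = GW_SIGNIFICANCE,
    min_eur_fraction: float = MIN_EUR_FRACTION,
) -> CurationResult:
    """Apply the eligibility filters to deduplicated records.

    Retains autosomal records from >=70% European-ancestry populations at
    genome-wide significance with a reported effect estimate and a
    determinable effect allele. Every exclusion is logged with one reason
    (first failing check, in the order below), so counts conserve.
    """
    kept: list[CatalogRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if str(rec.chrom) not in AUTOSOMES:
            excluded.append(Exclusion(rec, "non-autosomal"))
        elif rec.ancestry_eur_fraction < min_eur_fraction:
            excluded.append(Exclusion(rec, "ancestry<70%EUR"))
        elif rec.p_value > gw_significance:
            excluded.append(Exclusion(rec, "not-genome-wide-significant"))
        elif not rec.has_effect:
            excluded.append(Exclusion(rec, "missing-effect-estimate"))
        elif not rec.has_effect_allele:
            excluded.append(Exclusion(rec, "undeterminable-effect-allele"))
        else:
            kept.append(rec)
    return CurationResult(kept=kept, excluded=excluded)


def curate(records: Iterable[CatalogRecord], **kwargs) -> CurationResult:
    """Deduplicate then filter; the composition used by the pipeline."""
    records = list(records)
    deduped = dedupe_associations(records)
    n_dupes = len(records) - len(deduped)
    result = filter_catalog(deduped, **kwargs)
    result.excluded.extend(
        Exclusion(r, "duplicate-association")
        for r in _duplicate_losers(records, deduped)
    )
    assert len(result.kept) + len(result.excluded) == len(records)
    del n_dupes
    return result


def _duplicate_losers(
    records: list[CatalogRecord], deduped: list[CatalogRecord]
) -> list[CatalogRecord]:
    winners: dict[tuple, CatalogRecord] = {r.key: r for r in deduped}
    losers = []
    for rec in records:
        if winners.get(rec.key) is not rec:
            losers.append(rec)
    return losers


# ---------------------------------------------------------------------------
# TSV i/o


def records_to_frame(records: Iterable[CatalogRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "phenotype": r.phenotype,
                "subphenotype": r.subphenotype if r.subphenotype is not None else "",
                "ancestry_label": r.ancestry_label,
                "ancestry_eur_fraction": r.ancestry_eur_fraction,
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele if r.other_allele is not None else "",
                "effect": r.effect if r.effect is not None else "",
                "effect_type": r.effect_type,
                "p_value": r.p_value,
                "imputation_info": r.imputation_info if r.imputation_info is not None else "",
                "phenotype_rank": r.phenotype_rank,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CatalogRecord]:
    records = []
    for row in df.itertuples(index=False):
        effect = getattr(row, "effect", None)
        effect = None if effect in ("", None) or pd.isna(effect) else float(effect)
        effect_type = getattr(row, "effect_type", "beta")
        if effect is not None and effect_type == "OR":
            effect = parse_effect(effect, "OR")
        other = getattr(row, "other_allele", None)
        other = None if other in ("", None) or pd.isna(other) else str(other)
        sub = getattr(row, "subphenotype", None)
        sub = None if sub in ("", None) or pd.isna(sub) else str(sub)
        info = getattr(row, "imputation_info", None)
        info = None if info in ("", None) or pd.isna(info) else float(info)
        records.append(
            CatalogRecord(
                study_id=str(row.study_id),
                phenotype=str(row.phenotype),
                subphenotype=sub,
                ancestry_label=str(getattr(row, "ancestry_label", "EUR")),
                ancestry_eur_fraction=float(getattr(row, "ancestry_eur_fraction", 1.0)),
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=other,
                effect=effect,
                effect_type=str(effect_type),
                p_value=float(row.p_value),
                imputation_info=info,
                phenotype_rank=int(getattr(row, "phenotype_rank", 0)),
            )
        )
    return records


def read_catalog(path) -> list[CatalogRecord]:
    """Read a catalog TSV; odds ratios are converted to log scale."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return frame_to_records(df)


def write_catalog(records: Iterable[CatalogRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_exclusions(excluded: Iterable[Exclusion], path) -> None:
    rows = [
        {
            "rsid": e.record.rsid,
            "phenotype": e.record.phenotype,
            "subphenotype": e.record.subphenotype or "",
            "ancestry_label": e.record.ancestry_label,
            "study_id": e.record.study_id,
            "reason": e.reason,
        }
        for e in excluded
    ]
    pd.DataFrame(
        rows,
        columns=["rsid", "phenotype", "subphenotype", "ancestry_label", "study_id", "reason"],
    ).to_csv(path, sep="\t", index=False)
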