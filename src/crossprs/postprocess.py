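"""Region enrichment of pleiotropic variants and sensitivity filters.

Enrichment compares, per genomic region, the proportion of pleiotropic
associations falling in the region against the proportion of all score
variants there, with an optional size normalization (proportion per Mb).
Sensitivity filters produce reduced score definitions (LD-overlap removal,
explicit exclusion lists, discovery-subphenotype restriction) that rerun
through scoring, association, and meta-analysis unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .prs import PrsDefinition, PrsWeight

OTHER_LABEL = "other"


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    label: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"region {self.label}: end must exceed start")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """pos is 1-based; the interval is 0-based half-open."""
        return str(chrom) == self.chrom and self.start <= pos - 1 < self.end


class RegionMap:
    """Ordered list of labeled intervals; a position maps to <= 1 label."""

    def __init__(self, regions: Sequence[Region]):
        self.regions = list(regions)

    def locate(self, chrom: str, pos: int) -> str:
        for region in self.regions:
            if region.contains(chrom, pos):
                return region.label
        return OTHER_LABEL

    @classmethod
    def from_bed(cls, path) -> "RegionMap":
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom = fields[0].removeprefix("chr")
                regions.append(
                    Region(chrom=chrom, start=int(fields[1]), end=int(fields[2]), label=fields[3])
                )
        return cls(regions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


@dataclass
class EnrichmentRow:
    label: str
    pleiotropic_count: int
    pleiotropic_proportion: float
    background_count: int
    background_proportion: float
    size_bp: Optional[int]
    pleiotropic_per_mb: Optional[float]
    background_per_mb: Optional[float]
    enrichment_ratio: Optional[float]  # None when the background proportion is 0


def region_enrichment(
    pleiotropic: pd.DataFrame,
    background: pd.DataFrame,
    regions: RegionMap,
) -> list[EnrichmentRow]:
    """Per-region pleiotropic vs background proportions.

    Both inputs need ``chrom`` and ``pos`` (1-based) columns; pleiotropic
    rows are associations and may repeat a variant. Positions outside all
    regions pool under "other". The size-normalized columns divide each
    proportion by the region length in Mb ("other" has no defined size).
    """
    def _counts(df: pd.DataFrame) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in df.itertuples(index=False):
            label = regions.locate(str(row.chrom), int(row.pos))
            counts[label] = counts.get(label, 0) + 1
        return counts

    pleio_counts = _counts(pleiotropic)
    bg_counts = _counts(background)
    n_pleio = max(len(pleiotropic), 1) if len(pleiotropic) else 0
    n_bg = max(len(background), 1) if len(background) else 0
    sizes = {r.label: r.size_bp for r in regions.regions}

    rows = []
    labels = [r.label for r in regions.regions] + [OTHER_LABEL]
    for label in labels:
        pc = pleio_counts.get(label, 0)
        bc = bg_counts.get(label, 0)
        pp = pc / n_pleio if n_pleio else 0.0
        bp = bc / n_bg if n_bg else 0.0
        size = sizes.get(label)
        mb = size / 1e6 if size else None
        rows.append(
            EnrichmentRow(
                label=label,
                pleiotropic_count=pc,
                pleiotropic_proportion=pp,
                background_count=bc,
                background_proportion=bp,
                size_bp=size,
                pleiotropic_per_mb=pp / mb if mb else None,
                background_per_mb=bp / mb if mb else None,
                enrichment_ratio=(pp / bp) if bp > 0 else None,
            )
        )
    return rows


def enrichment_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "pleiotropic_count": r.pleiotropic_count,
                "pleiotropic_proportion": r.pleiotropic_proportion,
                "background_count": r.background_count,
                "background_proportion": r.background_proportion,
                "size_bp": r.size_bp if r.size_bp is not None else "",
                "pleiotropic_per_mb": r.pleiotropic_per_mb if r.pleiotropic_per_mb is not None else "",
                "background_per_mb": r.background_per_mb if r.background_per_mb is not None else "",
                "enrichment_ratio": r.enrichment_ratio if r.enrichment_ratio is not None else "",
            }
            for r in rows
        ]
    )


def filter_prs(
    prs: PrsDefinition,
    mode: str,
    *,
    outcome_variants: Optional[Sequence[str]] = None,
    ld=None,
    r2_min: float = 0.3,
    exclude: Optional[Sequence[str]] = None,
    subphenotype: Optional[str] = None,
) -> PrsDefinition:
    """Return a reduced score definition for a sensitivity rerun.

    Modes: ``ld_overlap`` removes exposure variants in LD (r2 >= r2_min)
    with any listed outcome risk variant; ``exclude_set`` removes an
    explicit variant list; ``restrict_discovery`` keeps variants whose
    discovery sub-phenotype matches. Raises if the filter empties the
    score.
    """
    if mode == "ld_overlap":
        if outcome_variants is None or ld is None:
            raise ValueError("ld_overlap mode needs outcome_variants and an LD source")
        kept: list[PrsWeight] = []
        for w in prs.weights:
            in_ld = False
            for ov in outcome_variants:
                r2 = ld.get(w.variant_id, ov)
                if r2 is not None and r2 >= r2_min:
                    in_ld = True
                    break
            if not in_ld:
                kept.append(w)
        provenance = f"ld_overlap_removed(r2>={r2_min})"
    elif mode == "exclude_set":
        excl = set(exclude or [])
        kept = [w for w in prs.weights if w.variant_id not in excl]
        provenance = f"excluded_{len(set(prs.variant_ids) & excl)}_variants"
    elif mode == "restrict_discovery":
        if subphenotype is None:
            raise ValueError("restrict_discovery mode needs a subphenotype label")
        kept = [w for w in prs.weights if w.source_subphenotype == subphenotype]
        provenance = f"restricted_to_{subphenotype}"
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if not kept:
        raise ValueError(f"empty PRS after filtering {prs.cancer} with mode {mode!r}")
    if len(kept) == len(prs.weights):
        return prs
    return prs.with_weights(kept, provenance)
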