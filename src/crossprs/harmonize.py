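"""Matching catalog variants to a cohort genotype panel.

Three stages, each of which either advances a record or drops it with a
reason: (1) match by id, then position, then best proxy at r2 >= 0.8;
(2) reconcile the published effect allele with the panel's counted allele,
handling strand complements and excluding strand-ambiguous (A/T, C/G)
variants near MAF 0.5; (3) frequency filters — biallelic, MAF >= 0.01,
cohort-vs-reference MAF concordance within 0.10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import CatalogRecord
from .prs import PrsWeight

logger = logging.getLogger(__name__)

PROXY_R2_MIN = 0.8
PROXY_WINDOW_BP = 500_000
AMBIGUOUS_MAF = 0.45
MAF_MIN = 0.01
MAF_DIFF_MAX = 0.10

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        raise ValueError(f"cannot complement allele {allele!r}") from None


def is_ambiguous_pair(a1: str, a2: Optional[str]) -> bool:
    """True for A/T and C/G pairs, whose strand is unresolvable."""
    if a2 is None:
        return False
    return {a1.upper(), a2.upper()} in _AMBIGUOUS_PAIRS


class Panel:
    """Cohort variant panel: manifest plus dosage-derived allele frequencies.

    The counted allele of a dosage column is the manifest's alt allele.
    MAF is min(f, 1-f) of mean dosage / 2, computed on the supplied
    (QC-passed) samples.
    """

    def __init__(
        self,
        manifest: pd.DataFrame,
        dosages: pd.DataFrame,
        sample_ids: Optional[Sequence[str]] = None,
    ):
        self.manifest = manifest.set_index(manifest["variant_id"].astype(str), drop=False)
        self.dosages = dosages if sample_ids is None else dosages.loc[list(sample_ids)]
        self._by_pos = {
            (str(r.chrom), int(r.pos)): str(r.variant_id)
            for r in manifest.itertuples(index=False)
        }
        means = self.dosages.mean(axis=0)
        self._alt_freq = {v: float(means[v]) / 2.0 for v in self.dosages.columns}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.manifest.index

    def by_position(self, chrom: str, pos: int) -> Optional[str]:
        return self._by_pos.get((str(chrom), int(pos)))

    def alleles(self, variant_id: str) -> tuple[str, str]:
        row = self.manifest.loc[variant_id]
        return str(row["ref"]), str(row["alt"])

    def alt_freq(self, variant_id: str) -> float:
        return self._alt_freq[variant_id]

    def maf(self, variant_id: str) -> float:
        f = self.alt_freq(variant_id)
        return min(f, 1.0 - f)

    def is_biallelic(self, variant_id: str) -> bool:
        ref, alt = self.alleles(variant_id)
        return "," not in alt and "," not in ref

    def position(self, variant_id: str) -> tuple[str, int]:
        row = self.manifest.loc[variant_id]
        return str(row["chrom"]), int(row["pos"])

    def imputation_info(self, variant_id: str) -> float:
        if "imputation_info" in self.manifest.columns:
            return float(self.manifest.loc[variant_id, "imputation_info"])
        return 1.0

    def mean_imputed_dosages(self) -> pd.DataFrame:
        """Dosages with missing values replaced by 2 x allele frequency."""
        d = self.dosages.copy()
        for v in d.columns:
            if d[v].isna().any():
                d[v] = d[v].fillna(2.0 * self._alt_freq[v])
        return d


@dataclass(frozen=True)
class HarmonizedVariant:
    """A catalog association aligned to one cohort dosage column."""

    record: CatalogRecord
    panel_id: str
    matched_via: str                       # direct | position | proxy
    effect_allele_is_counted: bool
    strand_flipped: bool
    use_complement: bool                   # score on 2 - d
    cohort_maf: float
    weight: float                          # log OR aligned to the scored dosage
    proxy_r2: Optional[float] = None
    reference_maf: Optional[float] = None
    imputation_info: Optional[float] = None

    def __post_init__(self):
        if self.matched_via == "proxy" and self.proxy_r2 is None:
            raise ValueError("proxy match requires an r2")
        if not np.isfinite(self.weight):
            raise ValueError("weight must be finite")

    def to_prs_weight(self) -> PrsWeight:
        return PrsWeight(
            variant_id=self.panel_id,
            weight=self.weight,
            counted_allele="",
            use_complement=self.use_complement,
            source_subphenotype=self.record.subphenotype,
            source_rsid=self.record.rsid if self.matched_via == "proxy" else None,
        )


@dataclass(frozen=True)
class Dropped:
    record: CatalogRecord
    reason: str
    stage: str


Outcome = Union[HarmonizedVariant, Dropped]


def match_or_proxy(
    record: CatalogRecord,
    panel: Panel,
    ld_source=None,
    r2_min: float = PROXY_R2_MIN,
    window_bp: int = PROXY_WINDOW_BP,
) -> Outcome:
    """Resolve a catalog record to a panel variant, directly or via proxy.

    Order: exact id match, then (chrom, pos) match, then the best available
    proxy with r2 >= r2_min within the search window (ties broken by
    nearest position, then lexicographic id).
    """
    if record.rsid in panel:
        return _initial(record, panel, record.rsid, "direct")
    pos_hit = panel.by_position(record.chrom, record.pos)
    if pos_hit is not None:
        return _initial(record, panel, pos_hit, "position")
    if ld_source is None:
        return Dropped(record, "no LD information", "match")
    candidates = []
    for pid, r2 in ld_source.neighbors(record.rsid).items():
        if pid not in panel or r2 < r2_min:
            continue
        chrom, pos = panel.position(pid)
        if str(chrom) != str(record.chrom):
            continue
        dist = abs(pos - record.pos)
        if dist > window_bp:
            continue
        candidates.append((-r2, dist, pid, r2))
    if not candidates:
        return Dropped(record, f"no proxy with r2>={r2_min}", "match")
    candidates.sort()
    _, _, proxy_id, r2 = candidates[0]
    hv = _initial(record, panel, proxy_id, "proxy")
    return replace(hv, proxy_r2=float(r2))


def _initial(record: CatalogRecord, panel: Panel, panel_id: str, via: str) -> HarmonizedVariant:
    return HarmonizedVariant(
        record=record,
        panel_id=panel_id,
        matched_via=via,
        effect_allele_is_counted=True,
        strand_flipped=False,
        use_complement=False,
        cohort_maf=panel.maf(panel_id),
        weight=float(record.effect),
        proxy_r2=1.0 if via == "proxy" else None,
        imputation_info=panel.imputation_info(panel_id),
    )


def harmonize_alleles(
    hv: HarmonizedVariant,
    panel: Panel,
    ambiguous_maf: float = AMBIGUOUS_MAF,
) -> Outcome:
    """Reconcile the published effect allele with the panel coding.

    Strand-ambiguous (A/T, C/G) variants with cohort MAF >= the threshold
    are dropped; otherwise the effect allele is aligned to the counted
    (alt) allele directly, by counting the complement dosage 2 - d, or
    after base-wise strand complementation.
    """
    record = hv.record
    ref, alt = panel.alleles(hv.panel_id)
    if is_ambiguous_pair(ref, alt) and hv.cohort_maf >= ambiguous_maf:
        return Dropped(record, f"ambiguous-alleles MAF>={ambiguous_maf}", "alleles")
    if hv.matched_via == "proxy":
        # the published alleles describe the lead, not the proxy: count the
        # proxy's alt allele and keep the published weight (positive-LD
        # convention, r2 carries no sign)
        return replace(hv, effect_allele_is_counted=True)
    ea = record.effect_allele.upper()
    oa = record.other_allele.upper() if record.other_allele else None
    if ea == alt and (oa is None or oa == ref):
        return hv
    if ea == ref and (oa is None or oa == alt):
        return replace(hv, effect_allele_is_counted=False, use_complement=True)
    try:
        cea = complement(ea)
        coa = complement(oa) if oa else None
    except ValueError:
        return Dropped(record, "allele mismatch", "alleles")
    if cea == alt and (coa is None or coa == ref):
        return replace(hv, strand_flipped=True)
    if cea == ref and (coa is None or coa == alt):
        return replace(hv, strand_flipped=True, effect_allele_is_counted=False, use_complement=True)
    return Dropped(record, "allele mismatch", "alleles")


def apply_frequency_filters(
    hv: HarmonizedVariant,
    panel: Panel,
    reference_freqs: Optional[Mapping[str, float]] = None,
    maf_min: float = MAF_MIN,
    maf_diff_max: float = MAF_DIFF_MAX,
) -> Outcome:
    """Biallelic, MAF >= 0.01, and reference-MAF concordance filters.

    ``reference_freqs`` maps panel variant id -> reference alt-allele
    frequency. When no reference table is supplied at all, the concordance
    filter is downgraded to a warning; when one is supplied, variants
    absent from it are dropped.
    """
    record = hv.record
    if not panel.is_biallelic(hv.panel_id):
        return Dropped(record, "not biallelic", "frequency")
    if hv.cohort_maf < maf_min:
        return Dropped(record, f"MAF<{maf_min}", "frequency")
    if reference_freqs is None:
        logger.warning(
            "no reference frequencies: skipping MAF-concordance filter for %s", hv.panel_id
        )
        return hv
    if hv.panel_id not in reference_freqs or pd.isna(reference_freqs[hv.panel_id]):
        return Dropped(record, "absent from reference panel", "frequency")
    ref_alt = float(reference_freqs[hv.panel_id])
    ref_maf = min(ref_alt, 1.0 - ref_alt)
    if abs(hv.cohort_maf - ref_maf) > maf_diff_max:
        return Dropped(record, f"MAF differs from reference by >{maf_diff_max}", "frequency")
    return replace(hv, reference_maf=ref_maf)


def harmonize_catalog(
    records: Sequence[CatalogRecord],
    panel: Panel,
    ld_source=None,
    reference_freqs: Optional[Mapping[str, float]] = None,
    r2_min: float = PROXY_R2_MIN,
    window_bp: int = PROXY_WINDOW_BP,
    ambiguous_maf: float = AMBIGUOUS_MAF,
    maf_min: float = MAF_MIN,
    maf_diff_max: float = MAF_DIFF_MAX,
) -> tuple[list[HarmonizedVariant], list[Dropped]]:
    """Run the full harmonization chain; every record maps to one outcome."""
    harmonized: list[HarmonizedVariant] = []
    dropped: list[Dropped] = []
    for record in records:
        out = match_or_proxy(record, panel, ld_source, r2_min=r2_min, window_bp=window_bp)
        if isinstance(out, HarmonizedVariant):
            out = harmonize_alleles(out, panel, ambiguous_maf=ambiguous_maf)
        if isinstance(out, HarmonizedVariant):
            out = apply_frequency_filters(
                out, panel, reference_freqs, maf_min=maf_min, maf_diff_max=maf_diff_max
            )
        if isinstance(out, HarmonizedVariant):
            harmonized.append(out)
        else:
            dropped.append(out)
    assert len(harmonized) + len(dropped) == len(records)
    return harmonized, dropped


def harmonization_report(
    harmonized: Sequence[HarmonizedVariant], dropped: Sequence[Dropped]
) -> pd.DataFrame:
    rows = []
    for hv in harmonized:
        rows.append(
            {
                "rsid": hv.record.rsid,
                "phenotype": hv.record.phenotype,
                "outcome": "harmonized",
                "reason": "",
                "panel_id": hv.panel_id,
                "matched_via": hv.matched_via,
                "proxy_r2": hv.proxy_r2 if hv.proxy_r2 is not None else "",
                "strand_flipped": hv.strand_flipped,
                "use_complement": hv.use_complement,
                "cohort_maf": hv.cohort_maf,
            }
        )
    for d in dropped:
        rows.append(
            {
                "rsid": d.record.rsid,
                "phenotype": d.record.phenotype,
                "outcome": "dropped",
                "reason": d.reason,
                "panel_id": "",
                "matched_via": "",
                "proxy_r2": "",
                "strand_flipped": "",
                "use_complement": "",
                "cohort_maf": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "phenotype", "outcome", "reason", "panel_id", "matched_via",
            "proxy_r2", "strand_flipped", "use_complement", "cohort_maf",
        ],
    )
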