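"""Pairwise linkage disequilibrium and priority pruning.

LD here is the squared Pearson correlation of allele dosages. Sources are
either an explicit (variant_i, variant_j) -> r2 table or in-cohort dosages
with on-demand computation; both expose ``get`` and ``neighbors``.
Priority pruning greedily selects a mutually independent variant set in a
preference order: broadest phenotype first, then smallest p-value, then
highest imputation score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_R2 = 0.3


def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> Optional[float]:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples where both values are non-missing. Returns None
    (missing LD) when fewer than two shared samples remain or either vector
    is constant.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    mask = ~(np.isnan(d1) | np.isnan(d2))
    x, y = d1[mask], d2[mask]
    if x.size < 2:
        return None
    vx = x - x.mean()
    vy = y - y.mean()
    ssx = float(vx @ vx)
    ssy = float(vy @ vy)
    if ssx == 0.0 or ssy == 0.0:
        return None
    r = float(vx @ vy) / math.sqrt(ssx * ssy)
    return r * r


class LdTable:
    """Symmetric sparse r2 lookup backed by an explicit pair table."""

    def __init__(self, pairs: Optional[Mapping[tuple, float]] = None, source: str = "external table"):
        self.source = source
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (i, j), v in pairs.items():
                self.set(i, j, v)

    def set(self, i: str, j: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        if i == j:
            return
        self._r2[frozenset((i, j))] = float(r2)

    def get(self, i: str, j: str) -> Optional[float]:
        if i == j:
            return 1.0
        return self._r2.get(frozenset((i, j)))

    def neighbors(self, i: str) -> dict[str, float]:
        out = {}
        for pair, v in self._r2.items():
            if i in pair:
                (other,) = pair - {i}
                out[other] = v
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "external table") -> "LdTable":
        table = cls(source=source)
        for row in df.itertuples(index=False):
            table.set(str(row.var1), str(row.var2), float(row.r2))
        return table

    @classmethod
    def read_tsv(cls, path) -> "LdTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"), source=str(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"var1": a, "var2": b, "r2": v}
            for pair, v in self._r2.items()
            for a, b in [sorted(pair)]
        ]
        return pd.DataFrame(rows, columns=["var1", "var2", "r2"]).sort_values(
            ["var1", "var2"], ignore_index=True
        )


class CohortLd:
    """LD source computing r2 from in-cohort dosages on demand.

    Cross-chromosome pairs are assumed independent (r2 = 0) without lookup
    when a manifest with chromosome assignments is supplied. An optional
    overlay table takes precedence (used for planted lead-proxy pairs whose
    lead is absent from the panel).
    """

    def __init__(
        self,
        dosages: pd.DataFrame,
        manifest: Optional[pd.DataFrame] = None,
        overlay: Optional[LdTable] = None,
    ):
        self.source = "in-cohort"
        self._dosages = dosages
        self._chrom: dict[str, str] = {}
        if manifest is not None:
            self._chrom = dict(
                zip(manifest["variant_id"].astype(str), manifest["chrom"].astype(str))
            )
        self._overlay = overlay
        self._cache: dict[frozenset, Optional[float]] = {}

    def get(self, i: str, j: str) -> Optional[float]:
        if i == j:
            return 1.0
        if self._overlay is not None:
            v = self._overlay.get(i, j)
            if v is not None:
                return v
        ci, cj = self._chrom.get(i), self._chrom.get(j)
        if ci is not None and cj is not None and ci != cj:
            return 0.0
        if i not in self._dosages.columns or j not in self._dosages.columns:
            return None
        key = frozenset((i, j))
        if key not in self._cache:
            self._cache[key] = pairwise_r2(
                self._dosages[i].to_numpy(), self._dosages[j].to_numpy()
            )
        return self._cache[key]

    def neighbors(self, i: str) -> dict[str, float]:
        return self._overlay.neighbors(i) if self._overlay is not None else {}


@dataclass(frozen=True)
class PruneCandidate:
    """A variant competing for inclusion in one phenotype's pruned set."""

    variant_id: str
    p_value: float
    imputation_info: float = 1.0
    phenotype_rank: int = 0  # 0 = broadest phenotype


def _priority_key(c: PruneCandidate) -> tuple:
    return (c.phenotype_rank, c.p_value, -c.imputation_info, c.variant_id)


@dataclass
class PruneResult:
    kept: list[PruneCandidate]
    removed: list[tuple[PruneCandidate, str]]  # (candidate, removed-by variant id)
    missing_ld_pairs: list[tuple[str, str]]

    @property
    def kept_ids(self) -> list[str]:
        return [c.variant_id for c in self.kept]

    def report(self) -> pd.DataFrame:
        rows = [
            {"variant_id": c.variant_id, "kept": True, "removed_by": ""} for c in self.kept
        ] + [
            {"variant_id": c.variant_id, "kept": False, "removed_by": by}
            for c, by in self.removed
        ]
        return pd.DataFrame(rows, columns=["variant_id", "kept", "removed_by"])


def priority_prune(
    candidates: Sequence[PruneCandidate],
    ld,
    r2_max: float = DEFAULT_PRUNE_R2,
) -> PruneResult:
    """Greedy priority pruning of one phenotype's candidate variants.

    Candidates are visited in priority order (broadest phenotype, ascending
    p, descending imputation info, lexicographic id); a candidate is kept
    iff its r2 against every already-kept variant is below ``r2_max``.
    Pairs with no LD information are treated as independent and logged.
    """
    if not candidates:
        logger.warning("priority_prune called with an empty candidate list")
        return PruneResult(kept=[], removed=[], missing_ld_pairs=[])
    kept: list[PruneCandidate] = []
    removed: list[tuple[PruneCandidate, str]] = []
    missing: list[tuple[str, str]] = []
    for cand in sorted(candidates, key=_priority_key):
        blocker = None
        for acc in kept:
            r2 = ld.get(cand.variant_id, acc.variant_id)
            if r2 is None:
                missing.append((cand.variant_id, acc.variant_id))
                continue
            if r2 >= r2_max:
                blocker = acc.variant_id
                break
        if blocker is None:
            kept.append(cand)
        else:
            removed.append((cand, blocker))
    if missing:
        logger.info("priority_prune: %d pairs had no LD information", len(missing))
    return PruneResult(kept=kept, removed=removed, missing_ld_pairs=missing)
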