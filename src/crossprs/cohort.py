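"""Sample-level quality control and phenotype derivation.

QC removes samples with low genotyping call rate or outlying
heterozygosity / leading principal components (z-scores computed within
the cohort on the QC-input samples). Case/control assignment evaluates
only the first primary cancer per individual, with same-date ties making
the sample a case for each tied site; controls have no registry record,
no self-reported history, and no cancer cause of death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_RATE_MIN = 0.97
OUTLIER_SD = 5.0

#: biomarkers natural-log transformed toward normality
LOG_TRANSFORM_TRAITS = ("crp", "hba1c", "igf1")


@dataclass
class QcResult:
    kept: pd.DataFrame
    removed: pd.DataFrame  # columns: sample_id, reasons

    def removal_report(self) -> pd.DataFrame:
        return self.removed


def _zscores(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(np.zeros(len(x)), index=x.index)
    return (x - x.mean()) / sd


def sample_qc(
    samples: pd.DataFrame,
    call_rate_min: float = CALL_RATE_MIN,
    outlier_sd: float = OUTLIER_SD,
    drop_missing_metrics: bool = False,
) -> QcResult:
    """Filter samples on call rate and heterozygosity / PC1-2 outliers.

    Expects columns ``call_rate``, ``heterozygosity``, ``pc1``, ``pc2``.
    Z-scores are computed within-cohort on the QC-input samples. Samples
    with missing metrics are flagged and kept unless
    ``drop_missing_metrics`` is set.
    """
    df = samples.copy()
    reasons = pd.Series([[] for _ in range(len(df))], index=df.index, dtype=object)

    metric_missing = pd.Series(False, index=df.index)
    for col in ("call_rate", "heterozygosity", "pc1", "pc2"):
        if col in df.columns:
            metric_missing |= df[col].isna()
        else:
            metric_missing |= True

    if "call_rate" in df.columns:
        bad = df["call_rate"] < call_rate_min
        for i in df.index[bad.fillna(False)]:
            reasons[i].append(f"call_rate<{call_rate_min}")
    if "heterozygosity" in df.columns:
        hz = _zscores(df["heterozygosity"])
        bad = hz.abs() > outlier_sd
        for i in df.index[bad.fillna(False)]:
            reasons[i].append(f"heterozygosity>{outlier_sd}SD")
    for pc in ("pc1", "pc2"):
        if pc in df.columns:
            z = _zscores(df[pc])
            bad = z.abs() > outlier_sd
            for i in df.index[bad.fillna(False)]:
                reasons[i].append(f"{pc}>{outlier_sd}SD")

    flagged_missing = df.index[metric_missing]
    if len(flagged_missing):
        logger.warning("%d samples have missing QC metrics (%s)",
                       len(flagged_missing), "dropped" if drop_missing_metrics else "kept")
        if drop_missing_metrics:
            for i in flagged_missing:
                if not reasons[i]:
                    reasons[i].append("missing-qc-metric")

    drop_mask = reasons.map(bool)
    removed = pd.DataFrame(
        {
            "sample_id": df.loc[drop_mask, "sample_id"]
            if "sample_id" in df.columns
            else df.index[drop_mask],
            "reasons": [";".join(r) for r in reasons[drop_mask]],
        }
    ).reset_index(drop=True)
    return QcResult(kept=df.loc[~drop_mask].copy(), removed=removed)


@dataclass
class CaseControlAssignment:
    cancer: str
    subset: str  # all | incident | prevalent
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self):
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"samples assigned as both case and control: {sorted(overlap)[:5]}")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


def first_primary_sites(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Per sample, the site codes diagnosed on the earliest date.

    Same-date ties keep every tied site: such samples are cases for each
    tied outcome. Returns rows (sample_id, site_code, date).
    """
    if diagnoses.empty:
        return diagnoses.copy()
    d = diagnoses.copy()
    d["date"] = pd.to_datetime(d["date"])
    first = d.groupby("sample_id")["date"].transform("min")
    return d[d["date"] == first].copy()


def assign_case_control(
    samples: pd.DataFrame,
    diagnoses: pd.DataFrame,
    cancer: str,
    subset: str = "all",
    sex: Optional[str] = None,
    specimen_date=None,
    valid_sites: Optional[Sequence[str]] = None,
) -> CaseControlAssignment:
    """Assign cases and controls for one cancer site code.

    Cases carry the site among their first primary diagnoses; ``subset``
    restricts to incident (diagnosed strictly after specimen collection)
    or prevalent (on or before — a diagnosis on the collection date counts
    as prevalent) cases. Controls have no diagnosis of any cancer, no
    self-reported history, and no cancer cause of death; for sex-specific
    cancers both cases and controls are restricted to ``sex``.
    """
    if valid_sites is not None and cancer not in valid_sites:
        raise ValueError(
            f"unknown site code {cancer!r}; valid codes: {sorted(valid_sites)}"
        )
    if subset not in ("all", "incident", "prevalent"):
        raise ValueError(f"subset must be all|incident|prevalent, got {subset!r}")

    firsts = first_primary_sites(diagnoses)
    mine = firsts[firsts["site_code"] == cancer] if not firsts.empty else firsts
    case_dates = dict(zip(mine["sample_id"], mine["date"])) if not mine.empty else {}

    df = samples.set_index("sample_id", drop=False)
    case_ids = [s for s in df.index if s in case_dates]
    if sex is not None:
        case_ids = [s for s in case_ids if df.loc[s, "sex"] == sex]

    if subset != "all":
        if specimen_date is None:
            if "specimen_date" not in df.columns:
                raise ValueError("incident/prevalent split requires a specimen date")
            spec = pd.to_datetime(df["specimen_date"])
        else:
            spec = pd.Series(pd.to_datetime(specimen_date), index=df.index)
        if subset == "incident":
            case_ids = [s for s in case_ids if case_dates[s] > spec[s]]
        else:
            case_ids = [s for s in case_ids if case_dates[s] <= spec[s]]

    any_dx = set(diagnoses["sample_id"]) if not diagnoses.empty else set()
    control_mask = ~df["sample_id"].isin(any_dx)
    if "self_report_cancer" in df.columns:
        control_mask &= ~df["self_report_cancer"].fillna(False).astype(bool)
    if "death_cause_cancer" in df.columns:
        control_mask &= ~df["death_cause_cancer"].fillna(False).astype(bool)
    if sex is not None:
        control_mask &= df["sex"] == sex
    control_ids = list(df.index[control_mask])

    return CaseControlAssignment(
        cancer=cancer, subset=subset, case_ids=case_ids, control_ids=control_ids
    )


def prepare_secondary_phenotypes(
    samples: pd.DataFrame,
    log_traits: Sequence[str] = LOG_TRANSFORM_TRAITS,
    reportable_ranges: Optional[dict] = None,
) -> pd.DataFrame:
    """Derive analysis-ready secondary phenotype columns.

    Natural-log transforms the skewed biomarkers (non-positive values set
    missing and logged), builds waist-to-hip ratio, and masks values
    outside supplied reportable ranges. Smoking-derived variables pass
    through unchanged.
    """
    df = samples.copy()
    if reportable_ranges:
        for col, (lo, hi) in reportable_ranges.items():
            if col in df.columns:
                out_of_range = (df[col] < lo) | (df[col] > hi)
                n = int(out_of_range.fillna(False).sum())
                if n:
                    logger.info("%s: %d values outside reportable range set missing", col, n)
                df.loc[out_of_range.fillna(False), col] = np.nan
    for col in log_traits:
        if col in df.columns:
            nonpos = df[col] <= 0
            n = int(nonpos.fillna(False).sum())
            if n:
                logger.warning("%s: %d non-positive values set missing before log", col, n)
            df.loc[nonpos.fillna(False), col] = np.nan
            df[f"log_{col}"] = np.log(df[col])
    if "waist" in df.columns and "hip" in df.columns:
        df["waist_hip_ratio"] = df["waist"] / df["hip"]
    return df
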