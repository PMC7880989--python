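"""Synthetic two-cohort fixtures: LD-block genotypes, phenotypes, traits,
and a literature catalog with planted harmonization traps.

Genotypes come from a Gaussian latent copula: within a block, each
haplotype's latent vector has compound-symmetric correlation rho and an
allele is present when the latent value falls below the allele-frequency
quantile; a dosage is the sum of two independent haplotypes. Case status
follows a logistic model logit = alpha + theta * z + gamma'C with z the
standardized true score, so every planted effect is recoverable by the
downstream pipeline. The catalog generator plants known traps (duplicate
records, strand flips, ambiguous alleles, proxy-only and proxyless leads,
frequency failures) and records them in a trap manifest for exact
assertions.

One global seed drives everything; each stage draws from its own
substream so stages stay reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.stats import norm

from .catalog import CatalogRecord
from .harmonize import complement
from .ld import pairwise_r2
from .prs import PrsDefinition, PrsWeight, compute_prs, standardize_prs

# rng substream tags
_STAGE_GENOTYPES = 0
_STAGE_PRS = 1
_STAGE_PHENOTYPES = 2
_STAGE_TRAITS = 3
_STAGE_CATALOG = 4

_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


class BlockSpec(BaseModel):
    n_variants: int = Field(ge=1)
    allele_freqs: Union[float, list[float]]
    rho: float = Field(ge=0.0, le=1.0)

    @field_validator("allele_freqs")
    @classmethod
    def _freqs_nondegenerate(cls, v):
        freqs = [v] if isinstance(v, float) else v
        for f in freqs:
            if not (0.0 < f < 1.0):
                raise ValueError(f"degenerate allele frequency {f}: must be in (0, 1)")
        return v

    @model_validator(mode="after")
    def _freqs_match(self):
        if isinstance(self.allele_freqs, list) and len(self.allele_freqs) != self.n_variants:
            raise ValueError("allele_freqs length must equal n_variants")
        return self

    @property
    def freqs(self) -> np.ndarray:
        if isinstance(self.allele_freqs, float):
            return np.full(self.n_variants, self.allele_freqs)
        return np.asarray(self.allele_freqs, dtype=float)


class CancerSpec(BaseModel):
    site_code: str
    theta: float          # per-SD log odds ratio of the true score
    alpha: float          # baseline log odds
    sex: Optional[str] = None  # restrict cases to one sex (e.g. "F")
    n_prs_variants: int = Field(default=6, ge=1)


class TraitSpec(BaseModel):
    name: str
    slope: float          # per-SD effect of the driver score
    noise_sd: float = Field(ge=0.0)
    driver: Optional[str] = None  # site code; defaults to the first cancer


class TrapConfig(BaseModel):
    duplicates: int = Field(default=0, ge=0)
    missing_effect: int = Field(default=0, ge=0)
    strand_flipped: int = Field(default=0, ge=0)
    ambiguous: int = Field(default=0, ge=0)
    proxy_only: int = Field(default=0, ge=0)
    proxyless: int = Field(default=0, ge=0)
    low_maf: int = Field(default=0, ge=0)
    maf_discordant: int = Field(default=0, ge=0)
    qc_failures: int = Field(default=0, ge=0)

    ambiguous_maf: float = 0.47
    low_maf_freq: float = 0.005
    discordant_cohort_freq: float = 0.30
    discordant_reference_freq: float = 0.45
    proxy_allele_corr: float = 0.95  # per-haplotype allele correlation lead~proxy


class SimulationConfig(BaseModel):
    model_config = {"extra": "forbid"}

    n_samples: int = Field(ge=2)
    blocks: list[BlockSpec]
    cancers: list[CancerSpec] = []
    covariate_effects: dict[str, float] = {}
    secondary_traits: list[TraitSpec] = []
    traps: TrapConfig = TrapConfig()
    seed: int = 0
    cohort_label: str = "cohortA"
    specimen_date: str = "2010-01-01"
    study_window: tuple[str, str] = ("2000-01-01", "2016-06-30")
    confound_pcs: bool = False


@dataclass
class SyntheticCohort:
    """One cohort's genotypes, manifest, phenotypes, and diagnoses."""

    label: str
    dosages: pd.DataFrame       # samples x variants, index = sample_id
    manifest: pd.DataFrame      # variant_id, chrom, pos, ref, alt, freq, ref_freq, ...
    phenotypes: pd.DataFrame
    diagnoses: pd.DataFrame     # sample_id, site_code, date
    extra_ld: pd.DataFrame      # var1, var2, r2 (planted lead-proxy pairs)
    lead_registry: pd.DataFrame # lead_rsid, chrom, pos, proxy_id, r2
    specimen_date: str

    def __post_init__(self):
        assert len(self.manifest) == self.dosages.shape[1], "manifest/dosage mismatch"
        d = self.dosages.to_numpy()
        assert np.nanmin(d) >= 0.0 and np.nanmax(d) <= 2.0, "dosages outside [0, 2]"
        if not self.diagnoses.empty:
            missing = set(self.diagnoses["sample_id"]) - set(self.phenotypes["sample_id"])
            assert not missing, f"diagnosed samples absent from phenotypes: {missing}"


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _block_dosages(rng: np.random.Generator, n: int, freqs: np.ndarray, rho: float) -> np.ndarray:
    m = len(freqs)
    thresholds = norm.ppf(freqs)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, m))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        dosage += (latent < thresholds).astype(np.int8)
    return dosage


def simulate_genotypes(config: SimulationConfig) -> SyntheticCohort:
    """Draw block-LD genotypes, trap variants, and the phenotype scaffold."""
    rng = _rng(config.seed, _STAGE_GENOTYPES)
    n = config.n_samples
    columns: list[np.ndarray] = []
    manifest_rows: list[dict] = []

    for b_idx, block in enumerate(config.blocks):
        chrom = str((b_idx % 22) + 1)
        pos0 = 1_000_000 + (b_idx // 22) * 20_000_000
        dosage = _block_dosages(rng, n, block.freqs, block.rho)
        for j in range(block.n_variants):
            ref, alt = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
            vid = f"rs{b_idx + 1:03d}{j + 1:03d}"
            manifest_rows.append(
                {
                    "variant_id": vid,
                    "chrom": chrom,
                    "pos": pos0 + j * 5_000,
                    "ref": ref,
                    "alt": alt,
                    "freq": float(block.freqs[j]),
                    "ref_freq": float(block.freqs[j]),
                    "imputation_info": round(float(rng.uniform(0.7, 1.0)), 3),
                    "block": b_idx,
                    "trap": "",
                }
            )
            columns.append(dosage[:, j])

    extra_ld_rows: list[dict] = []
    lead_rows: list[dict] = []
    tr = config.traps

    def _add_trap(vid, chrom, pos, ref, alt, freq, ref_freq, trap, dosage_vec):
        manifest_rows.append(
            {
                "variant_id": vid,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "freq": freq,
                "ref_freq": ref_freq,
                "imputation_info": round(float(rng.uniform(0.7, 1.0)), 3),
                "block": -1,
                "trap": trap,
            }
        )
        columns.append(dosage_vec)

    for i in range(tr.ambiguous):
        ref, alt = ("A", "T") if i % 2 == 0 else ("C", "G")
        f = tr.ambiguous_maf
        _add_trap(
            f"rsAMB{i + 1:02d}", "20", 50_000_000 + i * 10_000, ref, alt, f, f,
            "ambiguous", rng.binomial(2, f, n).astype(np.int8),
        )
    for i in range(tr.low_maf):
        f = tr.low_maf_freq
        _add_trap(
            f"rsLOW{i + 1:02d}", "21", 10_000_000 + i * 10_000, "A", "G", f, f,
            "low_maf", rng.binomial(2, f, n).astype(np.int8),
        )
    for i in range(tr.maf_discordant):
        f = tr.discordant_cohort_freq
        _add_trap(
            f"rsDIS{i + 1:02d}", "21", 30_000_000 + i * 10_000, "A", "G", f,
            tr.discordant_reference_freq, "maf_discordant",
            rng.binomial(2, f, n).astype(np.int8),
        )
    for i in range(tr.strand_flipped):
        f = 0.30
        _add_trap(
            f"rsFLP{i + 1:02d}", "22", 10_000_000 + i * 10_000, "A", "G", f, f,
            "strand_flipped", rng.binomial(2, f, n).astype(np.int8),
        )
    for i in range(tr.proxy_only):
        f = 0.40
        eps = 1.0 - tr.proxy_allele_corr  # resampling prob; allele corr = 1 - eps
        lead = np.zeros(n, dtype=np.int8)
        proxy = np.zeros(n, dtype=np.int8)
        for _hap in range(2):
            a_lead = rng.binomial(1, f, n).astype(np.int8)
            resample = rng.random(n) < eps
            a_prox = np.where(resample, rng.binomial(1, f, n), a_lead).astype(np.int8)
            lead += a_lead
            proxy += a_prox
        proxy_id = f"rsPRX{i + 1:02d}"
        lead_id = f"rsLEAD{i + 1:02d}"
        pos = 40_000_000 + i * 100_000
        _add_trap(proxy_id, "22", pos, "A", "G", f, f, "proxy_partner", proxy)
        r2 = pairwise_r2(lead, proxy)
        extra_ld_rows.append({"var1": lead_id, "var2": proxy_id, "r2": r2})
        lead_rows.append(
            {"lead_rsid": lead_id, "chrom": "22", "pos": pos + 500,
             "proxy_id": proxy_id, "r2": r2}
        )

    manifest = pd.DataFrame(manifest_rows)
    sample_ids = [f"{config.cohort_label}_{i:06d}" for i in range(n)]
    dosages = pd.DataFrame(
        np.column_stack(columns).astype(np.int8),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=manifest["variant_id"].tolist(),
    )

    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "age": np.round(rng.uniform(40, 75, n), 1),
            "batch": np.where(rng.random(n) < 0.5, "v1", "v2"),
            "call_rate": np.round(rng.uniform(0.975, 0.999, n), 4),
            "heterozygosity": rng.standard_normal(n),
            "self_report_cancer": False,
            "death_cause_cancer": False,
            "specimen_date": config.specimen_date,
        }
    )
    for k in range(1, 11):
        phenotypes[f"pc{k}"] = rng.standard_normal(n)
    if config.confound_pcs:
        burden = dosages.mean(axis=1).to_numpy(dtype=float)
        burden = (burden - burden.mean()) / burden.std(ddof=1)
        phenotypes["pc1"] = 0.7 * phenotypes["pc1"].to_numpy() + 0.7 * burden
    if tr.qc_failures:
        phenotypes.loc[: tr.qc_failures - 1, "call_rate"] = 0.95

    return SyntheticCohort(
        label=config.cohort_label,
        dosages=dosages,
        manifest=manifest,
        phenotypes=phenotypes,
        diagnoses=pd.DataFrame(columns=["sample_id", "site_code", "date"]),
        extra_ld=pd.DataFrame(extra_ld_rows, columns=["var1", "var2", "r2"]),
        lead_registry=pd.DataFrame(
            lead_rows, columns=["lead_rsid", "chrom", "pos", "proxy_id", "r2"]
        ),
        specimen_date=config.specimen_date,
    )


def make_prs_definitions(config: SimulationConfig, manifest: pd.DataFrame) -> list[PrsDefinition]:
    """Assign each cancer a disjoint set of non-trap variants with drawn weights."""
    rng = _rng(config.seed, _STAGE_PRS)
    eligible = manifest.loc[manifest["trap"] == "", "variant_id"].tolist()
    order = list(rng.permutation(len(eligible)))
    needed = sum(c.n_prs_variants for c in config.cancers)
    if needed > len(eligible):
        raise ValueError(
            f"need {needed} PRS variants but only {len(eligible)} non-trap variants simulated"
        )
    alleles = dict(zip(manifest["variant_id"], manifest["alt"]))
    defs = []
    cursor = 0
    for spec in config.cancers:
        take = [eligible[order[cursor + i]] for i in range(spec.n_prs_variants)]
        cursor += spec.n_prs_variants
        weights = tuple(
            PrsWeight(
                variant_id=v,
                weight=float(rng.uniform(0.05, 0.30)),
                counted_allele=alleles[v],
            )
            for v in sorted(take)
        )
        defs.append(PrsDefinition(cancer=spec.site_code, weights=weights))
    return defs


def _true_scores(cohort: SyntheticCohort, prs_defs: Sequence[PrsDefinition]) -> dict[str, pd.Series]:
    scores = {}
    for prs in prs_defs:
        raw = compute_prs(cohort.dosages, prs)
        scores[prs.cancer] = standardize_prs(raw).z
    return scores


def _covariate_matrix(phenotypes: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    n = len(phenotypes)
    total = np.zeros(n)
    for name, gamma in effects.items():
        if name == "age":
            x = phenotypes["age"].to_numpy(dtype=float)
            x = (x - x.mean()) / x.std(ddof=1)
        elif name == "sex":
            x = (phenotypes["sex"] == "F").to_numpy(dtype=float)
        elif name in phenotypes.columns:
            x = phenotypes[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown covariate {name!r} in covariate_effects")
        total += gamma * x
    return total


def simulate_phenotypes(
    cohort: SyntheticCohort,
    prs_defs: Sequence[PrsDefinition],
    config: SimulationConfig,
) -> SyntheticCohort:
    """Draw case status per cancer from the planted logistic model."""
    rng = _rng(config.seed, _STAGE_PHENOTYPES)
    scores = _true_scores(cohort, prs_defs)
    cov_term = _covariate_matrix(cohort.phenotypes, config.covariate_effects)
    start, end = (pd.Timestamp(d) for d in config.study_window)
    span_days = (end - start).days

    dx_rows = []
    sample_ids = cohort.phenotypes["sample_id"].to_numpy()
    sexes = cohort.phenotypes["sex"].to_numpy()
    for spec in config.cancers:
        if spec.site_code not in scores:
            raise KeyError(f"no PRS definition for cancer {spec.site_code!r}")
        z = scores[spec.site_code].to_numpy()
        logit = spec.alpha + spec.theta * z + cov_term
        prob = 1.0 / (1.0 + np.exp(-logit))
        if spec.sex is not None:
            prob = np.where(sexes == spec.sex, prob, 0.0)
        is_case = rng.random(len(prob)) < prob
        offsets = rng.integers(0, span_days + 1, size=int(is_case.sum()))
        for sid, off in zip(sample_ids[is_case], offsets):
            dx_rows.append(
                {
                    "sample_id": sid,
                    "site_code": spec.site_code,
                    "date": (start + pd.Timedelta(days=int(off))).date().isoformat(),
                }
            )
    diagnoses = pd.DataFrame(dx_rows, columns=["sample_id", "site_code", "date"])
    return dc_replace(cohort, diagnoses=diagnoses)


def simulate_secondary_traits(
    cohort: SyntheticCohort,
    prs_defs: Sequence[PrsDefinition],
    config: SimulationConfig,
) -> SyntheticCohort:
    """Quantitative traits linear in the driver score: slope*z + noise."""
    if not config.secondary_traits:
        return cohort
    rng = _rng(config.seed, _STAGE_TRAITS)
    scores = _true_scores(cohort, prs_defs)
    phenos = cohort.phenotypes.copy()
    default_driver = config.cancers[0].site_code if config.cancers else None
    for trait in config.secondary_traits:
        driver = trait.driver or default_driver
        if driver is None or driver not in scores:
            raise KeyError(f"trait {trait.name!r}: no driver PRS {driver!r}")
        z = scores[driver].to_numpy()
        noise = rng.standard_normal(len(z)) * trait.noise_sd if trait.noise_sd > 0 else 0.0
        phenos[trait.name] = trait.slope * z + noise
    return dc_replace(cohort, phenotypes=phenos)


def simulate_catalog(
    cohort: SyntheticCohort,
    prs_defs: Sequence[PrsDefinition],
    config: SimulationConfig,
) -> tuple[list[CatalogRecord], pd.DataFrame]:
    """Emit catalog records for true PRS variants plus planted traps.

    Returns the records and a trap manifest (rsid, phenotype, trap_type,
    expected_stage, expected_reason, expected_panel_id) for exact test
    assertions.
    """
    rng = _rng(config.seed, _STAGE_CATALOG)
    manifest = cohort.manifest.set_index("variant_id", drop=False)
    records: list[CatalogRecord] = []
    trap_rows: list[dict] = []
    first_cancer = config.cancers[0].site_code if config.cancers else "siteA"

    def _p() -> float:
        return float(10.0 ** rng.uniform(-12, -8.35))

    true_records: list[CatalogRecord] = []
    for prs in prs_defs:
        for w in prs.weights:
            row = manifest.loc[w.variant_id]
            rec = CatalogRecord(
                study_id=f"study_{prs.cancer}",
                phenotype=prs.cancer,
                rsid=w.variant_id,
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["alt"]),
                other_allele=str(row["ref"]),
                effect=w.weight,
                effect_type="beta",
                p_value=_p(),
                ancestry_eur_fraction=1.0,
                imputation_info=float(row["imputation_info"]),
            )
            true_records.append(rec)
    records.extend(true_records)

    tr = config.traps
    for i in range(min(tr.duplicates, len(true_records))):
        base = true_records[i]
        dup = CatalogRecord(
            study_id=f"study_dup{i + 1}",
            phenotype=base.phenotype,
            rsid=base.rsid,
            chrom=base.chrom,
            pos=base.pos,
            effect_allele=base.effect_allele,
            other_allele=base.other_allele,
            effect=base.effect,
            effect_type="beta",
            p_value=min(1.0, base.p_value * 1e3),
            ancestry_eur_fraction=1.0,
        )
        records.append(dup)
        trap_rows.append(
            {
                "rsid": dup.rsid, "phenotype": dup.phenotype, "trap_type": "duplicate",
                "expected_stage": "curation", "expected_reason": "duplicate-association",
                "expected_panel_id": "",
            }
        )
    for i in range(min(tr.missing_effect, len(true_records))):
        base = true_records[-(i + 1)]
        rec = CatalogRecord(
            study_id=f"study_noeff{i + 1}",
            phenotype=base.phenotype,
            rsid=base.rsid,
            chrom=base.chrom,
            pos=base.pos,
            effect_allele=base.effect_allele,
            other_allele=base.other_allele,
            effect=None,
            p_value=base.p_value / 10.0,
            ancestry_eur_fraction=1.0,
        )
        records.append(rec)
        trap_rows.append(
            {
                "rsid": rec.rsid, "phenotype": rec.phenotype, "trap_type": "missing_effect",
                "expected_stage": "curation", "expected_reason": "duplicate-association",
                "expected_panel_id": "",
            }
        )

    def _trap_record(row, phenotype, flip_strand=False):
        ea, oa = str(row["alt"]), str(row["ref"])
        if flip_strand:
            ea, oa = complement(ea), complement(oa)
        return CatalogRecord(
            study_id=f"study_trap_{row['variant_id']}",
            phenotype=phenotype,
            rsid=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=ea,
            other_allele=oa,
            effect=float(rng.uniform(0.05, 0.2)),
            p_value=_p(),
            ancestry_eur_fraction=1.0,
        )

    trap_kinds = [
        ("ambiguous", "harmonization", "ambiguous-alleles", False),
        ("low_maf", "harmonization", "MAF<", False),
        ("maf_discordant", "harmonization", "MAF differs from reference", False),
        ("strand_flipped", "harmonized", "", True),
    ]
    for trap_label, stage, reason, flip in trap_kinds:
        sub = cohort.manifest[cohort.manifest["trap"] == trap_label]
        for _, row in sub.iterrows():
            rec = _trap_record(row, first_cancer, flip_strand=flip)
            records.append(rec)
            trap_rows.append(
                {
                    "rsid": rec.rsid, "phenotype": first_cancer, "trap_type": trap_label,
                    "expected_stage": stage, "expected_reason": reason,
                    "expected_panel_id": str(row["variant_id"]) if stage == "harmonized" else "",
                }
            )

    for _, row in cohort.lead_registry.iterrows():
        rec = CatalogRecord(
            study_id=f"study_trap_{row['lead_rsid']}",
            phenotype=first_cancer,
            rsid=str(row["lead_rsid"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele="A",
            other_allele="G",
            effect=float(rng.uniform(0.05, 0.2)),
            p_value=_p(),
            ancestry_eur_fraction=1.0,
        )
        records.append(rec)
        trap_rows.append(
            {
                "rsid": rec.rsid, "phenotype": first_cancer, "trap_type": "proxy_only",
                "expected_stage": "harmonized", "expected_reason": "",
                "expected_panel_id": str(row["proxy_id"]),
            }
        )
    for i in range(tr.proxyless):
        rec = CatalogRecord(
            study_id=f"study_trap_proxyless{i + 1}",
            phenotype=first_cancer,
            rsid=f"rsNOPRX{i + 1:02d}",
            chrom="3",
            pos=190_000_000 + i * 10_000,
            effect_allele="A",
            other_allele="G",
            effect=float(rng.uniform(0.05, 0.2)),
            p_value=_p(),
            ancestry_eur_fraction=1.0,
        )
        records.append(rec)
        trap_rows.append(
            {
                "rsid": rec.rsid, "phenotype": first_cancer, "trap_type": "proxyless",
                "expected_stage": "harmonization", "expected_reason": "no proxy",
                "expected_panel_id": "",
            }
        )

    trap_manifest = pd.DataFrame(
        trap_rows,
        columns=[
            "rsid", "phenotype", "trap_type", "expected_stage",
            "expected_reason", "expected_panel_id",
        ],
    )
    return records, trap_manifest


def simulate_cohort(
    config: SimulationConfig,
    prs_defs: Optional[Sequence[PrsDefinition]] = None,
) -> tuple[SyntheticCohort, list[PrsDefinition]]:
    """Full generative chain for one cohort under one seed."""
    cohort = simulate_genotypes(config)
    if prs_defs is None:
        prs_defs = make_prs_definitions(config, cohort.manifest)
    cohort = simulate_phenotypes(cohort, prs_defs, config)
    cohort = simulate_secondary_traits(cohort, prs_defs, config)
    return cohort, list(prs_defs)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dosages = cohort.dosages.reset_index()
    dosages.to_csv(out / "dosages.tsv", sep="\t", index=False)
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False, float_format="%.10g")
    cohort.diagnoses.to_csv(out / "diagnoses.tsv", sep="\t", index=False)
    cohort.extra_ld.to_csv(out / "ld_extra.tsv", sep="\t", index=False, float_format="%.10g")


def read_cohort(indir, label: str, specimen_date: str = "2010-01-01") -> SyntheticCohort:
    from pathlib import Path

    ind = Path(indir)
    dosages = pd.read_csv(ind / "dosages.tsv", sep="\t").set_index("sample_id")
    manifest = pd.read_csv(ind / "manifest.tsv", sep="\t", dtype={"chrom": str})
    phenotypes = pd.read_csv(ind / "phenotypes.tsv", sep="\t")
    diagnoses = pd.read_csv(ind / "diagnoses.tsv", sep="\t")
    ld_path = ind / "ld_extra.tsv"
    extra_ld = (
        pd.read_csv(ld_path, sep="\t")
        if ld_path.exists()
        else pd.DataFrame(columns=["var1", "var2", "r2"])
    )
    return SyntheticCohort(
        label=label,
        dosages=dosages,
        manifest=manifest,
        phenotypes=phenotypes,
        diagnoses=diagnoses,
        extra_ld=extra_ld,
        lead_registry=pd.DataFrame(columns=["lead_rsid", "chrom", "pos", "proxy_id", "r2"]),
        specimen_date=specimen_date,
    )
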