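"""End-to-end orchestration: curate -> QC -> harmonize -> prune -> score ->
associate -> meta -> enrich -> sensitivity.

Every stage is a pure function of (inputs, config, seed); each output TSV
carries a header block with the config hash and seed so reruns are
byte-comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import catalog as catalog_mod
from .assoc import AssocEstimate, ModelSpec, estimates_to_frame, fit_linear, fit_logistic, variant_scan
from .cohort import CaseControlAssignment, assign_case_control, sample_qc
from .config import PipelineConfig
from .harmonize import HarmonizedVariant, Panel, harmonization_report, harmonize_catalog
from .ld import CohortLd, LdTable, PruneCandidate, priority_prune
from .meta import MetaEstimate, bh_fdr, bonferroni_threshold, fixed_effects_meta
from .postprocess import RegionMap, enrichment_frame, filter_prs, region_enrichment
from .prs import PrsDefinition, compute_prs, definitions_to_frame, standardize_prs
from .simulate import SyntheticCohort, read_cohort

logger = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n# seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


@dataclass
class CohortState:
    """Per-cohort working state threaded through the stages."""

    cohort: SyntheticCohort
    qc_samples: pd.DataFrame = None
    panel: Panel = None
    ld: CohortLd = None
    harmonized: list[HarmonizedVariant] = field(default_factory=list)
    dosages_imputed: pd.DataFrame = None
    prs_z: dict = field(default_factory=dict)        # cancer -> standardized Series
    assignments: dict = field(default_factory=dict)  # cancer -> CaseControlAssignment


@dataclass
class PipelineResult:
    out_dir: Path
    prs_defs: list[PrsDefinition]
    prs_meta: list[MetaEstimate]
    scan_meta: list[MetaEstimate]
    excluded_cancers: dict
    states: dict


def _covariates_for(outcome_sex: Optional[str], covariates: Sequence[str]) -> tuple[str, ...]:
    # sex drops out of sex-specific models (it is constant there)
    if outcome_sex is not None:
        return tuple(c for c in covariates if c != "sex")
    return tuple(covariates)


def _covariate_frame(samples: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    df = samples.set_index("sample_id", drop=False)
    cols = [c for c in covariates if c in df.columns]
    return df[["sample_id", "sex", *[c for c in cols if c not in ("sample_id", "sex")]]]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    site_codes = [c.site_code for c in config.cancers]
    sex_by_site = {c.site_code: c.sex for c in config.cancers}

    # ---- stage: curate ---------------------------------------------------
    records = catalog_mod.read_catalog(config.catalog)
    curated = catalog_mod.curate(
        records,
        gw_significance=thresholds.gw_significance,
        min_eur_fraction=thresholds.min_eur_fraction,
    )
    logger.info("curate: kept %d / %d records", len(curated.kept), len(records))
    _write_tsv(catalog_mod.records_to_frame(curated.kept), out / "catalog_curated.tsv", config)
    catalog_mod.write_exclusions(curated.excluded, out / "catalog_exclusions.tsv")

    external_ld = LdTable.read_tsv(config.ld_table) if config.ld_table else None

    # ---- per-cohort: load, QC, harmonize ---------------------------------
    states: dict[str, CohortState] = {}
    for cin in config.cohorts:
        cohort = read_cohort(cin.dir, cin.label, specimen_date=cin.specimen_date)
        state = CohortState(cohort=cohort)
        qc = sample_qc(cohort.phenotypes)
        logger.info("qc[%s]: removed %d samples", cin.label, len(qc.removed))
        _write_tsv(qc.removed, out / f"qc_removed_{cin.label}.tsv", config)
        state.qc_samples = qc.kept

        kept_ids = list(qc.kept["sample_id"])
        state.panel = Panel(cohort.manifest, cohort.dosages, sample_ids=kept_ids)
        overlay = LdTable.from_frame(cohort.extra_ld) if len(cohort.extra_ld) else None
        if external_ld is not None:
            overlay = _merge_overlays(overlay, external_ld)
        state.ld = CohortLd(state.panel.dosages, cohort.manifest, overlay=overlay)

        ref_freqs = dict(zip(cohort.manifest["variant_id"], cohort.manifest["ref_freq"])) \
            if "ref_freq" in cohort.manifest.columns else None
        harmonized, dropped = harmonize_catalog(
            curated.kept,
            state.panel,
            ld_source=state.ld,
            reference_freqs=ref_freqs,
            r2_min=thresholds.proxy_r2,
            window_bp=thresholds.proxy_window_bp,
            ambiguous_maf=thresholds.ambiguous_maf,
            maf_min=thresholds.maf_min,
            maf_diff_max=thresholds.maf_diff_max,
        )
        state.harmonized = harmonized
        _write_tsv(harmonization_report(harmonized, dropped),
                   out / f"harmonization_{cin.label}.tsv", config)
        state.dosages_imputed = state.panel.mean_imputed_dosages()
        states[cin.label] = state

    if not states:
        raise ValueError("no cohorts configured")
    ref_label = config.cohorts[0].label
    ref_state = states[ref_label]

    # ---- stage: prune + score definitions --------------------------------
    prs_defs = build_prs_definitions(
        ref_state.harmonized, ref_state.ld, site_codes, thresholds.prune_r2,
        out=out, config=config,
    )
    _write_tsv(definitions_to_frame(prs_defs), out / "prs_definitions.tsv", config)

    # ---- stage: case/control + minimum-case rule -------------------------
    excluded_cancers: dict[str, str] = {}
    for label, state in states.items():
        for site in site_codes:
            state.assignments[site] = assign_case_control(
                state.qc_samples, state.cohort.diagnoses, site,
                sex=sex_by_site.get(site), valid_sites=site_codes,
            )
    for site in site_codes:
        total_cases = sum(states[l].assignments[site].n_cases for l in states)
        if total_cases < thresholds.min_cases:
            excluded_cancers[site] = (
                f"{total_cases} cases across cohorts < min_cases={thresholds.min_cases}"
            )
            logger.warning("excluding %s: %s", site, excluded_cancers[site])
    analyzed_sites = [s for s in site_codes if s not in excluded_cancers]
    prs_defs = [d for d in prs_defs if d.cancer in analyzed_sites]
    _write_tsv(
        pd.DataFrame(
            [{"site_code": k, "reason": v} for k, v in excluded_cancers.items()],
            columns=["site_code", "reason"],
        ),
        out / "excluded_cancers.tsv", config,
    )

    # ---- stage: scoring --------------------------------------------------
    for label, state in states.items():
        score_cohort(state, prs_defs, sex_by_site)
        score_rows = []
        for prs in prs_defs:
            z = state.prs_z[prs.cancer]
            raw = state.prs_raw[prs.cancer]
            for sid in z.index:
                score_rows.append(
                    {"sample_id": sid, "cancer": prs.cancer,
                     "raw": raw[sid], "z": z[sid]}
                )
        _write_tsv(pd.DataFrame(score_rows, columns=["sample_id", "cancer", "raw", "z"]),
                   out / f"prs_scores_{label}.tsv", config)

    # ---- stage: PRS x cancer associations + meta -------------------------
    per_cohort, prs_meta = prs_association_scan(states, prs_defs, analyzed_sites,
                                                sex_by_site, config.covariates)
    _write_tsv(estimates_to_frame(per_cohort), out / "assoc_prs_by_cohort.tsv", config)
    n_outcome_tests = len(analyzed_sites)
    prs_threshold = bonferroni_threshold(thresholds.alpha, max(n_outcome_tests, 1))
    _write_tsv(meta_frame(prs_meta, prs_threshold, thresholds.alpha),
               out / "meta_prs.tsv", config)

    # ---- stage: per-variant scan + meta ----------------------------------
    scan_meta: list[MetaEstimate] = []
    if config.variant_scan and prs_defs:
        scan_estimates: list[AssocEstimate] = []
        for label, state in states.items():
            cov_data = _covariate_frame(state.qc_samples, config.covariates)
            scan_assign = {s: state.assignments[s] for s in analyzed_sites}
            scan_estimates.extend(
                variant_scan(prs_defs, state.dosages_imputed, scan_assign,
                             cov_data, [c for c in config.covariates], cohort=label)
            )
        _write_tsv(estimates_to_frame(scan_estimates), out / "assoc_variants_by_cohort.tsv", config)
        scan_meta = meta_by_key(scan_estimates)
        n_unique = len({v for d in prs_defs for v in d.variant_ids})
        scan_threshold = bonferroni_threshold(thresholds.alpha, max(n_unique, 1))
        _write_tsv(meta_frame(scan_meta, scan_threshold, thresholds.alpha),
                   out / "meta_variants.tsv", config)

        # ---- stage: region enrichment ------------------------------------
        if config.regions_bed:
            regions = RegionMap.from_bed(config.regions_bed)
            pos_of = {
                str(r.variant_id): (str(r.chrom), int(r.pos))
                for r in ref_state.cohort.manifest.itertuples(index=False)
            }
            pleio_rows = [
                {"variant_id": m.exposure, "chrom": pos_of[m.exposure][0],
                 "pos": pos_of[m.exposure][1]}
                for m in scan_meta
                if m.p_value < scan_threshold and m.origin != m.outcome
                and m.exposure in pos_of
            ]
            bg_rows = [
                {"variant_id": v, "chrom": pos_of[v][0], "pos": pos_of[v][1]}
                for v in sorted({v for d in prs_defs for v in d.variant_ids})
                if v in pos_of
            ]
            rows = region_enrichment(
                pd.DataFrame(pleio_rows, columns=["variant_id", "chrom", "pos"]),
                pd.DataFrame(bg_rows, columns=["variant_id", "chrom", "pos"]),
                regions,
            )
            _write_tsv(enrichment_frame(rows), out / "region_enrichment.tsv", config)

    # ---- stage: secondary phenotypes -------------------------------------
    if config.secondary_traits:
        sec_label = config.secondary_cohort or config.cohorts[-1].label
        sec_estimates = secondary_trait_scan(states[sec_label], prs_defs,
                                             config.secondary_traits, config.covariates)
        sec_threshold = bonferroni_threshold(thresholds.alpha, len(config.secondary_traits))
        df = estimates_to_frame(sec_estimates)
        df["significant_bonferroni"] = df["p"].astype(float) < sec_threshold
        _write_tsv(df, out / "assoc_secondary.tsv", config)

    # ---- stage: sensitivity reruns ---------------------------------------
    run_sensitivity(config, states, prs_defs, analyzed_sites, sex_by_site, out)

    return PipelineResult(
        out_dir=out,
        prs_defs=prs_defs,
        prs_meta=prs_meta,
        scan_meta=scan_meta,
        excluded_cancers=excluded_cancers,
        states=states,
    )


def _merge_overlays(a: Optional[LdTable], b: Optional[LdTable]) -> Optional[LdTable]:
    if a is None:
        return b
    if b is None:
        return a
    merged = LdTable(source="merged")
    for table in (a, b):
        for pair, v in table._r2.items():
            i, j = sorted(pair)
            merged.set(i, j, v)
    return merged


def build_prs_definitions(
    harmonized: Sequence[HarmonizedVariant],
    ld,
    site_codes: Sequence[str],
    prune_r2: float,
    out: Optional[Path] = None,
    config: Optional[PipelineConfig] = None,
) -> list[PrsDefinition]:
    """Priority-prune each cancer's harmonized candidates into a definition."""
    defs = []
    prune_reports = []
    for site in site_codes:
        mine = [hv for hv in harmonized if hv.record.phenotype == site]
        # one candidate per panel variant: keep the smallest-p record
        best: dict[str, HarmonizedVariant] = {}
        for hv in mine:
            cur = best.get(hv.panel_id)
            if cur is None or hv.record.p_value < cur.record.p_value:
                best[hv.panel_id] = hv
        candidates = [
            PruneCandidate(
                variant_id=hv.panel_id,
                p_value=hv.record.p_value,
                imputation_info=hv.imputation_info if hv.imputation_info is not None else 1.0,
                phenotype_rank=hv.record.phenotype_rank,
            )
            for hv in best.values()
        ]
        result = priority_prune(candidates, ld, r2_max=prune_r2)
        report = result.report()
        report.insert(0, "cancer", site)
        prune_reports.append(report)
        weights = tuple(best[v].to_prs_weight() for v in sorted(result.kept_ids))
        if weights:
            defs.append(PrsDefinition(cancer=site, weights=weights))
        else:
            logger.warning("no variants survived pruning for %s; skipping its PRS", site)
    if out is not None and config is not None and prune_reports:
        _write_tsv(pd.concat(prune_reports, ignore_index=True), out / "prune_report.tsv", config)
    return defs


def score_cohort(state: CohortState, prs_defs: Sequence[PrsDefinition],
                 sex_by_site: dict) -> None:
    """Compute and standardize every score over the cohort's eligible samples."""
    samples = state.qc_samples.set_index("sample_id", drop=False)
    state.prs_raw = {}
    for prs in prs_defs:
        raw = compute_prs(state.dosages_imputed, prs)
        raw = raw.loc[samples.index]
        sex = sex_by_site.get(prs.cancer)
        mask = pd.Series(True, index=raw.index) if sex is None else (samples["sex"] == sex)
        vec = standardize_prs(raw, population_mask=mask)
        state.prs_raw[prs.cancer] = vec.raw
        state.prs_z[prs.cancer] = vec.z


def prs_association_scan(
    states: dict,
    prs_defs: Sequence[PrsDefinition],
    sites: Sequence[str],
    sex_by_site: dict,
    covariates: Sequence[str],
) -> tuple[list[AssocEstimate], list[MetaEstimate]]:
    """All (PRS, cancer outcome) logistic fits per cohort, then pooled."""
    estimates: list[AssocEstimate] = []
    for label, state in states.items():
        cov_data = _covariate_frame(state.qc_samples, covariates)
        for prs in prs_defs:
            exposure = f"prs_{prs.cancer}_z"
            for site in sites:
                assign = state.assignments[site]
                if assign.n_cases == 0 or assign.n_controls == 0:
                    logger.warning("no cases or controls for %s in %s; skipped", site, label)
                    continue
                ids = assign.case_ids + assign.control_ids
                data = cov_data.loc[ids].copy()
                data[exposure] = state.prs_z[prs.cancer].loc[ids]
                data[site] = [1.0] * assign.n_cases + [0.0] * assign.n_controls
                spec = ModelSpec(
                    outcome=site,
                    exposure=exposure,
                    covariates=_covariates_for(sex_by_site.get(site), covariates),
                    family="logistic",
                )
                est = fit_logistic(spec, data, cohort=label)
                est.origin = prs.cancer
                estimates.append(est)
    return estimates, meta_by_key(estimates)


def secondary_trait_scan(
    state: CohortState,
    prs_defs: Sequence[PrsDefinition],
    traits,
    covariates: Sequence[str],
) -> list[AssocEstimate]:
    """PRS vs secondary-phenotype models restricted to cancer-free controls."""
    estimates: list[AssocEstimate] = []
    control_ids = None
    for assign in state.assignments.values():
        ids = set(assign.control_ids)
        control_ids = ids if control_ids is None else (control_ids & ids)
    control_ids = sorted(control_ids or [])
    cov_data = _covariate_frame(state.qc_samples, covariates)
    samples = state.qc_samples.set_index("sample_id", drop=False)
    for prs in prs_defs:
        exposure = f"prs_{prs.cancer}_z"
        for trait in traits:
            if trait.name not in samples.columns:
                logger.warning("secondary trait %s absent; skipped", trait.name)
                continue
            data = cov_data.loc[control_ids].copy()
            data[exposure] = state.prs_z[prs.cancer].loc[control_ids]
            data[trait.name] = samples.loc[control_ids, trait.name]
            extra = tuple(c for c in trait.extra_covariates if c in data.columns)
            spec = ModelSpec(
                outcome=trait.name,
                exposure=exposure,
                covariates=tuple(covariates) + extra,
                family=trait.family,
            )
            fit = fit_logistic if trait.family == "logistic" else fit_linear
            try:
                est = fit(spec, data, cohort=state.cohort.label)
            except ValueError as exc:
                logger.warning("secondary fit skipped (%s, %s): %s", prs.cancer, trait.name, exc)
                continue
            est.origin = prs.cancer
            estimates.append(est)
    return estimates


def meta_by_key(estimates: Sequence[AssocEstimate]) -> list[MetaEstimate]:
    """Pool estimates sharing (outcome, exposure, origin) across cohorts."""
    groups: dict[tuple, list[AssocEstimate]] = {}
    order = []
    for e in estimates:
        key = (e.outcome, e.exposure, e.origin)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(e)
    out = []
    for key in order:
        members = [e for e in groups[key] if e.converged]
        if not members:
            logger.warning("meta skipped for %s: no converged estimates", key)
            continue
        out.append(fixed_effects_meta(members))
    return out


def meta_frame(metas: Sequence[MetaEstimate], bonf_threshold: float, alpha: float) -> pd.DataFrame:
    rows = []
    for m in metas:
        rows.append(
            {
                "outcome": m.outcome,
                "exposure": m.exposure,
                "origin": m.origin or "",
                "k": m.k,
                "beta": m.beta,
                "se": m.se,
                "p": m.p_value,
                "or": float(np.exp(m.beta)),
                "cochran_q": m.cochran_q,
                "p_q": m.p_q if m.p_q is not None else "",
                "i2": m.i2 if m.i2 is not None else "",
                "heterogeneous": (m.p_q < alpha) if m.p_q is not None else "",
                "duplicate": m.duplicate,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["outcome", "exposure", "origin", "k", "beta", "se", "p", "or",
                 "cochran_q", "p_q", "i2", "heterogeneous", "duplicate"],
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant_bonferroni"] = df["p"] < bonf_threshold
        df["significant_fdr"] = df["q"] < alpha
    else:
        df["q"] = []
        df["significant_bonferroni"] = []
        df["significant_fdr"] = []
    return df


def run_sensitivity(
    config: PipelineConfig,
    states: dict,
    prs_defs: Sequence[PrsDefinition],
    sites: Sequence[str],
    sex_by_site: dict,
    out: Path,
) -> None:
    sens = config.sensitivity
    reruns: list[tuple[str, PrsDefinition]] = []
    by_cancer = {d.cancer: d for d in prs_defs}

    for cancer, variants in sens.exclude.items():
        if cancer in by_cancer:
            reruns.append(
                ("exclude_set", filter_prs(by_cancer[cancer], "exclude_set", exclude=variants))
            )
    for cancer, sub in sens.restrict_discovery.items():
        if cancer in by_cancer:
            reruns.append(
                ("restrict_discovery",
                 filter_prs(by_cancer[cancer], "restrict_discovery", subphenotype=sub))
            )
    if sens.ld_overlap:
        ref_state = states[config.cohorts[0].label]
        for exposure_cancer, d in by_cancer.items():
            for outcome_cancer, od in by_cancer.items():
                if outcome_cancer == exposure_cancer:
                    continue
                try:
                    filtered = filter_prs(
                        d, "ld_overlap",
                        outcome_variants=od.variant_ids,
                        ld=ref_state.ld,
                        r2_min=config.thresholds.prune_r2,
                    )
                except ValueError:
                    continue
                if filtered is not d:
                    reruns.append((f"ld_overlap_vs_{outcome_cancer}", filtered))

    if not reruns:
        return
    all_estimates: list[AssocEstimate] = []
    all_meta_frames = []
    for tag, filtered in reruns:
        for label, state in states.items():
            score_cohort(state, [filtered], sex_by_site)
        ests, metas = prs_association_scan(states, [filtered], sites, sex_by_site,
                                           config.covariates)
        mf = meta_frame(metas, bonferroni_threshold(config.thresholds.alpha,
                                                    max(len(sites), 1)),
                        config.thresholds.alpha)
        mf.insert(0, "sensitivity", tag)
        mf.insert(1, "provenance", filtered.provenance)
        all_meta_frames.append(mf)
        all_estimates.extend(ests)
    # restore full-definition scores
    for label, state in states.items():
        score_cohort(state, prs_defs, sex_by_site)
    _write_tsv(pd.concat(all_meta_frames, ignore_index=True),
               out / "meta_sensitivity.tsv", config)
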