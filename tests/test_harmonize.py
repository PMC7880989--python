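import numpy as np
import pandas as pd
import pytest

from crossprs.catalog import CatalogRecord
from crossprs.harmonize import (
    Dropped,
    HarmonizedVariant,
    Panel,
    apply_frequency_filters,
    complement,
    harmonize_alleles,
    harmonize_catalog,
    harmonization_report,
    is_ambiguous_pair,
    match_or_proxy,
)
from crossprs.ld import LdTable


def make_panel(maf=0.3, ref="A", alt="G", vid="v1", n=1000, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    manifest_rows = [{"variant_id": vid, "chrom": "1", "pos": 1000, "ref": ref, "alt": alt,
                      "imputation_info": 0.95}]
    cols = {vid: rng.binomial(2, maf, n)}
    for row in extra or []:
        manifest_rows.append(row["manifest"])
        cols[row["manifest"]["variant_id"]] = row["dosages"]
    manifest = pd.DataFrame(manifest_rows)
    dosages = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return Panel(manifest, dosages)


def rec(**kwargs):
    defaults = dict(
        study_id="s1", phenotype="lung", rsid="v1", chrom="1", pos=1000,
        effect_allele="G", other_allele="A", effect=0.2, p_value=1e-9,
    )
    defaults.update(kwargs)
    return CatalogRecord(**defaults)


class TestMatchOrProxy:
    def test_direct_match_by_id(self):
        out = match_or_proxy(rec(), make_panel())
        assert isinstance(out, HarmonizedVariant)
        assert out.matched_via == "direct"

    def test_position_match(self):
        out = match_or_proxy(rec(rsid="rs_other_name"), make_panel())
        assert isinstance(out, HarmonizedVariant)
        assert out.matched_via == "position"
        assert out.panel_id == "v1"

    def test_proxy_above_threshold(self):
        ld = LdTable({("lead", "v1"): 0.85})
        out = match_or_proxy(rec(rsid="lead", pos=2000), make_panel(), ld)
        assert isinstance(out, HarmonizedVariant)
        assert out.matched_via == "proxy"
        assert out.proxy_r2 == 0.85

    def test_proxy_below_threshold_dropped(self):
        ld = LdTable({("lead", "v1"): 0.75})
        out = match_or_proxy(rec(rsid="lead", pos=2000), make_panel(), ld)
        assert isinstance(out, Dropped)
        assert "r2" in out.reason

    def test_no_ld_source_dropped(self):
        out = match_or_proxy(rec(rsid="lead", pos=2000), make_panel(), None)
        assert isinstance(out, Dropped)
        assert out.reason == "no LD information"

    def test_proxy_outside_window_dropped(self):
        ld = LdTable({("lead", "v1"): 0.95})
        out = match_or_proxy(rec(rsid="lead", pos=10_000_000), make_panel(), ld)
        assert isinstance(out, Dropped)

    def test_best_proxy_selected(self):
        extra = [{"manifest": {"variant_id": "v2", "chrom": "1", "pos": 3000,
                               "ref": "C", "alt": "T", "imputation_info": 0.9},
                  "dosages": np.random.default_rng(1).binomial(2, 0.4, 1000)}]
        panel = make_panel(extra=extra)
        ld = LdTable({("lead", "v1"): 0.85, ("lead", "v2"): 0.95})
        out = match_or_proxy(rec(rsid="lead", pos=2000), panel, ld)
        assert out.panel_id == "v2"


class TestHarmonizeAlleles:
    def _hv(self, panel, record):
        out = match_or_proxy(record, panel)
        assert isinstance(out, HarmonizedVariant)
        return out

    def test_effect_allele_is_counted(self):
        panel = make_panel()
        out = harmonize_alleles(self._hv(panel, rec()), panel)
        assert out.use_complement is False and out.strand_flipped is False

    def test_effect_allele_is_other(self):
        panel = make_panel()
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="A", other_allele="G")), panel)
        assert out.use_complement is True

    def test_strand_complement_resolved(self):
        # panel A/G, catalog reports T/C (opposite strand): effect C == comp G
        panel = make_panel()
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="C", other_allele="T")), panel)
        assert out.strand_flipped is True and out.use_complement is False

    def test_strand_complement_other_allele(self):
        panel = make_panel()
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="T", other_allele="C")), panel)
        assert out.strand_flipped is True and out.use_complement is True

    def test_ambiguous_high_maf_dropped(self):
        panel = make_panel(ref="A", alt="T", maf=0.48)
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="T", other_allele="A")), panel)
        assert isinstance(out, Dropped)
        assert "ambiguous" in out.reason

    def test_ambiguous_low_maf_kept(self):
        panel = make_panel(ref="C", alt="G", maf=0.10)
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="G", other_allele="C")), panel)
        assert isinstance(out, HarmonizedVariant)

    def test_irreconcilable_dropped(self):
        panel = make_panel()
        out = harmonize_alleles(self._hv(panel, rec(effect_allele="C", other_allele="A")), panel)
        assert isinstance(out, Dropped)
        assert out.reason == "allele mismatch"


class TestFrequencyFilters:
    def _hv(self, panel):
        return match_or_proxy(rec(), panel)

    def test_low_maf_dropped(self):
        panel = make_panel(maf=0.004)
        out = apply_frequency_filters(self._hv(panel), panel, {"v1": 0.004})
        assert isinstance(out, Dropped)
        assert "MAF<" in out.reason

    def test_discordant_maf_dropped(self):
        panel = make_panel(maf=0.30)
        out = apply_frequency_filters(self._hv(panel), panel, {"v1": 0.45})
        assert isinstance(out, Dropped)
        assert "differs" in out.reason

    def test_concordant_kept(self):
        panel = make_panel(maf=0.25)
        out = apply_frequency_filters(self._hv(panel), panel, {"v1": 0.25})
        assert isinstance(out, HarmonizedVariant)
        assert out.reference_maf == pytest.approx(0.25)

    def test_absent_from_reference_dropped(self):
        panel = make_panel()
        out = apply_frequency_filters(self._hv(panel), panel, {"other": 0.3})
        assert isinstance(out, Dropped)
        assert "reference" in out.reason

    def test_no_reference_table_downgrades_to_warning(self):
        panel = make_panel(maf=0.3)
        out = apply_frequency_filters(self._hv(panel), panel, None)
        assert isinstance(out, HarmonizedVariant)


def test_complement_helper():
    assert complement("A") == "T"
    assert complement("CG") == "GC"
    with pytest.raises(ValueError):
        complement("N")
    assert is_ambiguous_pair("A", "T") and is_ambiguous_pair("g", "c")
    assert not is_ambiguous_pair("A", "G")


@pytest.fixture(scope="module")
def harmonized(trap_sim):
    from crossprs.catalog import curate
    from crossprs.ld import CohortLd

    cohort = trap_sim["cohort"]
    curated = curate(trap_sim["records"])
    panel = Panel(cohort.manifest, cohort.dosages)
    ld = CohortLd(cohort.dosages, cohort.manifest,
                  overlay=LdTable.from_frame(cohort.extra_ld))
    ref = dict(zip(cohort.manifest["variant_id"], cohort.manifest["ref_freq"]))
    harm, dropped = harmonize_catalog(curated.kept, panel, ld, ref)
    return curated, harm, dropped


class TestTrapFixture:
    """Planted-trap exactness: dropped set == planted set, counts conserve."""

    def test_dropped_equals_planted_exactly(self, trap_sim, harmonized):
        _, _, dropped = harmonized
        traps = trap_sim["traps"]
        expected = set(traps.loc[traps["expected_stage"] == "harmonization", "rsid"])
        assert {d.record.rsid for d in dropped} == expected

    def test_curation_traps_removed_at_curation(self, trap_sim, harmonized):
        curated, _, _ = harmonized
        traps = trap_sim["traps"]
        curation_traps = traps.loc[traps["expected_stage"] == "curation"]
        kept_study_ids = {r.study_id for r in curated.kept}
        assert not any(s.startswith(("study_dup", "study_noeff")) for s in kept_study_ids)
        assert len(curation_traps) == len(curated.excluded)

    def test_proxy_trap_resolves_to_planted_proxy(self, trap_sim, harmonized):
        _, harm, _ = harmonized
        traps = trap_sim["traps"]
        proxies = traps.loc[traps["trap_type"] == "proxy_only"]
        by_rsid = {h.record.rsid: h for h in harm}
        for _, row in proxies.iterrows():
            hv = by_rsid[row["rsid"]]
            assert hv.matched_via == "proxy"
            assert hv.panel_id == row["expected_panel_id"]
            assert hv.proxy_r2 >= 0.8

    def test_strand_traps_flagged_not_dropped(self, trap_sim, harmonized):
        _, harm, _ = harmonized
        traps = trap_sim["traps"]
        flips = set(traps.loc[traps["trap_type"] == "strand_flipped", "rsid"])
        flagged = {h.record.rsid for h in harm if h.strand_flipped}
        assert flips == flagged

    def test_report_counts_conserve(self, trap_sim, harmonized):
        curated, harm, dropped = harmonized
        report = harmonization_report(harm, dropped)
        assert len(report) == len(curated.kept)
        assert (report["outcome"] == "harmonized").sum() == len(harm)
        assert (report["outcome"] == "dropped").sum() == len(dropped)
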