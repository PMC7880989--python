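import itertools

import numpy as np
import pandas as pd
import pytest

from crossprs.assoc import ModelSpec, fit_linear, fit_logistic
from crossprs.ld import pairwise_r2
from crossprs.prs import compute_prs, standardize_prs
from crossprs.simulate import (
    BlockSpec,
    CancerSpec,
    SimulationConfig,
    TraitSpec,
    make_prs_definitions,
    simulate_catalog,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_secondary_traits,
    write_cohort,
    read_cohort,
)


def base_config(**overrides):
    defaults = dict(
        n_samples=1000,
        blocks=[BlockSpec(n_variants=3, allele_freqs=0.3, rho=0.3)],
        cancers=[],
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BlockSpec(n_variants=1, allele_freqs=0.0, rho=0.5)
        with pytest.raises(ValueError, match="degenerate"):
            BlockSpec(n_variants=2, allele_freqs=[0.3, 1.0], rho=0.5)

    def test_rho_range(self):
        with pytest.raises(ValueError):
            BlockSpec(n_variants=1, allele_freqs=0.3, rho=1.5)

    def test_min_samples(self):
        with pytest.raises(ValueError):
            base_config(n_samples=1)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, blocks=[], typo_field=1)


class TestGenotypes:
    def test_rho_one_equal_freq_gives_r2_one(self):
        cfg = base_config(blocks=[BlockSpec(n_variants=2, allele_freqs=0.4, rho=1.0)])
        cohort = simulate_genotypes(cfg)
        v1, v2 = cohort.dosages.columns[:2]
        assert pairwise_r2(cohort.dosages[v1].to_numpy(),
                           cohort.dosages[v2].to_numpy()) == pytest.approx(1.0)

    def test_cross_block_r2_near_zero(self):
        # E[r2] ~ 1/n under independence
        cfg = base_config(
            n_samples=10_000,
            blocks=[BlockSpec(n_variants=3, allele_freqs=0.3, rho=0.8),
                    BlockSpec(n_variants=3, allele_freqs=0.4, rho=0.8)],
        )
        cohort = simulate_genotypes(cfg)
        block_a = cohort.dosages.columns[:3]
        block_b = cohort.dosages.columns[3:6]
        r2s = [
            pairwise_r2(cohort.dosages[a].to_numpy(), cohort.dosages[b].to_numpy())
            for a in block_a for b in block_b
        ]
        assert np.mean(r2s) < 0.01

    def test_mean_dosage_matches_binomial_oracle(self):
        # dosage ~ Binomial(2, f): mean 2f, var 2f(1-f)
        f, n = 0.3, 10_000
        cfg = base_config(n_samples=n, blocks=[BlockSpec(n_variants=1, allele_freqs=f, rho=0.0)])
        cohort = simulate_genotypes(cfg)
        d = cohort.dosages.iloc[:, 0].to_numpy()
        se = np.sqrt(2 * f * (1 - f) / n)
        assert abs(d.mean() - 2 * f) < 3 * se

    def test_ld_fidelity_monotone_in_rho(self):
        realized = []
        for rho in (0.0, 0.3, 0.6, 0.9, 1.0):
            cfg = base_config(
                n_samples=4000,
                blocks=[BlockSpec(n_variants=2, allele_freqs=0.3, rho=rho)],
                seed=123,
            )
            cohort = simulate_genotypes(cfg)
            v1, v2 = cohort.dosages.columns[:2]
            realized.append(
                pairwise_r2(cohort.dosages[v1].to_numpy(), cohort.dosages[v2].to_numpy())
            )
        assert all(b > a - 0.02 for a, b in zip(realized, realized[1:]))
        assert realized[-1] == pytest.approx(1.0)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = base_config(
            cancers=[CancerSpec(site_code="ca", theta=0.3, alpha=-2.0, n_prs_variants=2)],
            secondary_traits=[TraitSpec(name="t1", slope=0.1, noise_sd=0.5)],
        )
        for d in ("a", "b"):
            cohort, _ = simulate_cohort(cfg)
            write_cohort(cohort, tmp_path / d)
        for fname in ("dosages.tsv", "manifest.tsv", "phenotypes.tsv", "diagnoses.tsv"):
            assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_genotypes(base_config(seed=1)).dosages
        b = simulate_genotypes(base_config(seed=2)).dosages
        assert not a.equals(b)

    def test_manifest_matches_dosage_columns(self):
        cohort = simulate_genotypes(base_config())
        assert list(cohort.dosages.columns) == list(cohort.manifest["variant_id"])

    def test_dosages_in_range(self):
        cohort = simulate_genotypes(base_config())
        assert cohort.dosages.to_numpy().min() >= 0
        assert cohort.dosages.to_numpy().max() <= 2


class TestPhenotypes:
    def _fit_theta(self, cohort, prs_defs, site):
        from crossprs.cohort import assign_case_control

        z = standardize_prs(compute_prs(cohort.dosages, prs_defs[0])).z
        assign = assign_case_control(cohort.phenotypes, cohort.diagnoses, site)
        ids = assign.case_ids + assign.control_ids
        data = cohort.phenotypes.set_index("sample_id", drop=False).loc[ids].copy()
        data["z"] = z.loc[ids]
        data[site] = [1.0] * assign.n_cases + [0.0] * assign.n_controls
        return fit_logistic(ModelSpec(site, "z"), data)

    def test_null_theta_rejection_rate_nominal(self):
        # 500 replicate fits under theta = 0; rejection at alpha=0.05 should
        # stay within Monte-Carlo error of 0.05
        rejections = 0
        reps = 500
        for i in range(reps):
            cfg = base_config(
                n_samples=400,
                blocks=[BlockSpec(n_variants=2, allele_freqs=0.3, rho=0.2)],
                cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=-1.0, n_prs_variants=2)],
                seed=50_000 + i,
            )
            cohort, prs_defs = simulate_cohort(cfg)
            est = self._fit_theta(cohort, prs_defs, "ca")
            if est.converged and est.p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * mc_se

    def test_theta_recovery_large_n(self):
        theta = float(np.log(1.3))
        cfg = base_config(
            n_samples=20_000,
            blocks=[BlockSpec(n_variants=3, allele_freqs=0.3, rho=0.2) for _ in range(2)],
            cancers=[CancerSpec(site_code="ca", theta=theta, alpha=-1.8, n_prs_variants=4)],
            seed=77,
        )
        cohort, prs_defs = simulate_cohort(cfg)
        est = self._fit_theta(cohort, prs_defs, "ca")
        assert abs(est.beta - theta) < 1.96 * est.se

    def test_prevalence_matches_alpha(self):
        p0 = 0.10
        alpha = float(np.log(p0 / (1 - p0)))
        cfg = base_config(
            n_samples=20_000,
            cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=alpha, n_prs_variants=2)],
            seed=9,
        )
        cohort, _ = simulate_cohort(cfg)
        prevalence = cohort.diagnoses["sample_id"].nunique() / cfg.n_samples
        assert prevalence == pytest.approx(p0, abs=3 * np.sqrt(p0 * (1 - p0) / cfg.n_samples))

    def test_sex_specific_cases_single_sex(self):
        cfg = base_config(
            cancers=[CancerSpec(site_code="prost", theta=0.2, alpha=-1.0, sex="M",
                                n_prs_variants=2)],
            seed=3,
        )
        cohort, _ = simulate_cohort(cfg)
        sexes = cohort.phenotypes.set_index("sample_id").loc[
            cohort.diagnoses["sample_id"], "sex"
        ]
        assert set(sexes) <= {"M"}

    def test_diagnosis_dates_within_window(self):
        cfg = base_config(
            cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=-1.0, n_prs_variants=2)]
        )
        cohort, _ = simulate_cohort(cfg)
        dates = pd.to_datetime(cohort.diagnoses["date"])
        lo, hi = (pd.Timestamp(d) for d in cfg.study_window)
        assert dates.between(lo, hi).all()


class TestSecondaryTraits:
    def _trait_slope(self, cfg, trait_name):
        cohort, prs_defs = simulate_cohort(cfg)
        z = standardize_prs(compute_prs(cohort.dosages, prs_defs[0])).z
        data = cohort.phenotypes.copy()
        data["z"] = z.to_numpy()
        return fit_linear(ModelSpec(trait_name, "z", family="linear"), data)

    def test_zero_noise_exact_slope(self):
        cfg = base_config(
            n_samples=500,
            cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=-2.0, n_prs_variants=2)],
            secondary_traits=[TraitSpec(name="t1", slope=0.37, noise_sd=0.0)],
        )
        est = self._trait_slope(cfg, "t1")
        assert est.beta == pytest.approx(0.37, abs=1e-10)

    def test_slope_recovery(self):
        cfg = base_config(
            n_samples=20_000,
            cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=-2.0, n_prs_variants=2)],
            secondary_traits=[TraitSpec(name="t1", slope=0.2, noise_sd=1.0)],
            seed=15,
        )
        est = self._trait_slope(cfg, "t1")
        assert abs(est.beta - 0.2) < 1.96 * est.se

    def test_null_slope_t_test_nominal(self):
        rejections = 0
        reps = 200
        for i in range(reps):
            cfg = base_config(
                n_samples=300,
                cancers=[CancerSpec(site_code="ca", theta=0.0, alpha=-2.0, n_prs_variants=2)],
                secondary_traits=[TraitSpec(name="t1", slope=0.0, noise_sd=1.0)],
                seed=80_000 + i,
            )
            est = self._trait_slope(cfg, "t1")
            if est.p_value < 0.05:
                rejections += 1
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 4 * mc_se


class TestCatalogTraps:
    def test_duplicate_pair_curation_keeps_smaller_p(self, trap_sim):
        from crossprs.catalog import curate

        records = trap_sim["records"]
        traps = trap_sim["traps"]
        dup_rsids = traps.loc[traps["trap_type"] == "duplicate", "rsid"]
        curated = curate(records)
        for rsid in dup_rsids:
            kept = [r for r in curated.kept if r.rsid == rsid]
            group = [r for r in records if r.rsid == rsid and r.has_effect]
            assert len(kept) == 1
            assert kept[0].p_value == min(r.p_value for r in group)

    def test_trap_membership_recorded(self, trap_sim):
        traps = trap_sim["traps"]
        expected_types = {
            "duplicate", "missing_effect", "strand_flipped", "ambiguous",
            "proxy_only", "proxyless", "low_maf", "maf_discordant",
        }
        assert set(traps["trap_type"]) == expected_types

    def test_catalog_covers_all_prs_variants(self, trap_sim):
        rsids = {r.rsid for r in trap_sim["records"]}
        for prs in trap_sim["prs_defs"]:
            assert set(prs.variant_ids) <= rsids


def test_cohort_roundtrip(tmp_path):
    cfg = base_config(
        cancers=[CancerSpec(site_code="ca", theta=0.2, alpha=-1.5, n_prs_variants=2)]
    )
    cohort, _ = simulate_cohort(cfg)
    write_cohort(cohort, tmp_path)
    back = read_cohort(tmp_path, cohort.label)
    pd.testing.assert_frame_equal(
        back.dosages.astype(float), cohort.dosages.astype(float), check_dtype=False
    )
    assert len(back.diagnoses) == len(cohort.diagnoses)


def test_prs_definitions_deterministic_and_disjoint():
    cfg = base_config(
        blocks=[BlockSpec(n_variants=4, allele_freqs=0.3, rho=0.2) for _ in range(3)],
        cancers=[
            CancerSpec(site_code="a", theta=0.1, alpha=-2.0, n_prs_variants=4),
            CancerSpec(site_code="b", theta=0.1, alpha=-2.0, n_prs_variants=4),
        ],
    )
    cohort = simulate_genotypes(cfg)
    d1 = make_prs_definitions(cfg, cohort.manifest)
    d2 = make_prs_definitions(cfg, cohort.manifest)
    assert d1 == d2
    assert not set(d1[0].variant_ids) & set(d1[1].variant_ids)
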