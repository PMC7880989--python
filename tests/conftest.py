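import numpy as np
import pytest

from crossprs.simulate import (
    BlockSpec,
    CancerSpec,
    SimulationConfig,
    TraitSpec,
    TrapConfig,
    make_prs_definitions,
    simulate_catalog,
    simulate_cohort,
)


def trap_config(seed=7, n_samples=2000):
    return SimulationConfig(
        n_samples=n_samples,
        blocks=[BlockSpec(n_variants=4, allele_freqs=0.3, rho=0.2) for _ in range(6)],
        cancers=[
            CancerSpec(site_code="siteA", theta=float(np.log(1.5)), alpha=-1.8, n_prs_variants=6),
            CancerSpec(site_code="siteB", theta=0.0, alpha=-2.0, n_prs_variants=6),
        ],
        covariate_effects={"age": 0.1, "sex": -0.2},
        secondary_traits=[TraitSpec(name="traitX", slope=0.2, noise_sd=1.0)],
        traps=TrapConfig(
            duplicates=2,
            missing_effect=1,
            strand_flipped=2,
            ambiguous=2,
            proxy_only=2,
            proxyless=1,
            low_maf=1,
            maf_discordant=1,
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def trap_sim():
    """Cohort + catalog with every planted harmonization trap."""
    config = trap_config()
    cohort, prs_defs = simulate_cohort(config)
    records, trap_manifest = simulate_catalog(cohort, prs_defs, config)
    return {
        "config": config,
        "cohort": cohort,
        "prs_defs": prs_defs,
        "records": records,
        "traps": trap_manifest,
    }


@pytest.fixture(scope="session")
def plain_cohort():
    """A small trap-free cohort for scoring/association tests."""
    config = SimulationConfig(
        n_samples=1500,
        blocks=[BlockSpec(n_variants=3, allele_freqs=0.3, rho=0.3) for _ in range(4)],
        cancers=[CancerSpec(site_code="siteA", theta=0.4, alpha=-1.8, n_prs_variants=4)],
        covariate_effects={"age": 0.1},
        seed=42,
    )
    cohort, prs_defs = simulate_cohort(config)
    return {"config": config, "cohort": cohort, "prs_defs": prs_defs}


@pytest.fixture(scope="session")
def pipeline_fixture_dir(tmp_path_factory):
    """On-disk two-cohort fixture as the CLI would write it."""
    from crossprs import catalog as catalog_mod
    from crossprs.simulate import write_cohort

    root = tmp_path_factory.mktemp("fixture")
    base = SimulationConfig(
        n_samples=1500,
        blocks=[BlockSpec(n_variants=4, allele_freqs=f, rho=0.2)
                for f in (0.3, 0.4, 0.25, 0.35, 0.3)],
        cancers=[
            CancerSpec(site_code="siteA", theta=0.4, alpha=-1.8, n_prs_variants=5),
            CancerSpec(site_code="siteB", theta=0.0, alpha=-2.0, n_prs_variants=5),
        ],
        covariate_effects={"age": 0.1, "sex": -0.2},
        secondary_traits=[TraitSpec(name="traitX", slope=0.2, noise_sd=1.0)],
        traps=TrapConfig(duplicates=1, ambiguous=1, proxy_only=1, proxyless=1,
                         low_maf=1, maf_discordant=1, strand_flipped=1),
        seed=11,
        cohort_label="cohA",
    )
    cfg_b = base.model_copy(update={"cohort_label": "cohB", "seed": base.seed + 1})
    cohort_a, prs_defs = simulate_cohort(base)
    cohort_b, _ = simulate_cohort(cfg_b, prs_defs=prs_defs)
    write_cohort(cohort_a, root / "cohA")
    write_cohort(cohort_b, root / "cohB")
    records, traps = simulate_catalog(cohort_a, prs_defs, base)
    catalog_mod.write_catalog(records, root / "catalog.tsv")
    traps.to_csv(root / "trap_manifest.tsv", sep="\t", index=False)
    return {"root": root, "config": base, "prs_defs": prs_defs}
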