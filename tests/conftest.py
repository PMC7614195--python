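import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scoremr.cohort import simulate_cohort
from scoremr.derive import (
    ClumpParams,
    LDReference,
    greedy_clump,
    identify_cis,
    run_exposure_gwas,
    select_candidates,
)
from scoremr.fixtures import (
    FGF23_CHROM,
    FGF23_TSS,
    calibrated_config,
    discovery_config,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=list(HealthCheck)
)
settings.load_profile("suite")


def variants_meta(config) -> pd.DataFrame:
    v = config.variants
    return pd.DataFrame(
        {
            "chromosome": [x.chrom for x in v],
            "base_pair_location": [x.pos for x in v],
            "rsid": [x.rsid for x in v],
            "effect_allele": [x.effect_allele for x in v],
            "other_allele": [x.other_allele for x in v],
        }
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One derivation-size cohort calibrated to 6.3%/0.4% variance explained."""
    return simulate_cohort(calibrated_config(seed=11, n=19_195))


@pytest.fixture(scope="session")
def derivation_run():
    """Full derivation on the packaged discovery fixture: GWAS -> selection ->
    clumping -> cis flags.  Shared across tests (read-only)."""
    config = discovery_config()
    cohort = simulate_cohort(config)
    gwas = run_exposure_gwas(
        cohort.dosages, cohort.exposure_true, cohort.covariates[["age", "sex"]], variants_meta(config)
    )
    candidates = select_candidates(gwas, 5e-6)
    ld = LDReference.from_dosages(cohort.dosages, cohort.rsids)
    leads = greedy_clump(candidates, ld, ClumpParams())
    leads = identify_cis(leads, FGF23_CHROM, FGF23_TSS)
    return {
        "config": config,
        "cohort": cohort,
        "gwas": gwas,
        "candidates": candidates,
        "ld": ld,
        "leads": leads,
    }
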