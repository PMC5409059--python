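import numpy as np
import pytest

from gwaskit import simcohort as sc


@pytest.fixture(scope="session")
def independent_panel():
    """200 haplotypes x 100 independent variants (no LD)."""
    return sc.simulate_panel(
        n_haplotypes=200, n_variants=100, maf_range=(0.1, 0.5),
        block_size=10, within_block_correlation=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def ld_panel():
    """400 haplotypes x 100 variants with strong within-block LD."""
    return sc.simulate_panel(
        n_haplotypes=400, n_variants=100, maf_range=(0.1, 0.5),
        block_size=10, within_block_correlation=0.9, seed=2,
    )


@pytest.fixture(scope="session")
def null_cohort(independent_panel):
    """Case-control cohort with no genetic effect and no strata."""
    model = sc.RiskModel.null(prevalence=0.05)
    return sc.simulate_case_control(
        independent_panel, model, n_cases=400, n_controls=400, seed=11,
    )


@pytest.fixture(scope="session")
def causal_cohort(independent_panel):
    """One causal variant (index 5) with RR 2 at moderate prevalence."""
    model = sc.RiskModel(np.array([5]), np.array([np.log(2.0)]), prevalence=0.05)
    return sc.simulate_case_control(
        independent_panel, model, n_cases=2000, n_controls=2000, seed=12,
    )
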