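import numpy as np
import pytest

import imnlr


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort, small enough for unit tests."""
    return imnlr.generate_cohort(n_samples=120, seed=11)


@pytest.fixture(scope="session")
def small_library(small_cohort):
    return imnlr.select_reference_library(
        small_cohort.purified.beta, small_cohort.purified.cell_labels, n_per_type=50
    )


@pytest.fixture(scope="session")
def titration_cohort():
    """Validation cohort whose true NLR spans [0.5, 12] on a log grid."""
    truth = imnlr.generate_reference_profiles(
        1000, n_ldmr_per_type=50, n_surrogates=5, seed=101
    )
    comp = imnlr.composition_from_nlr(np.geomspace(0.5, 12.0, 50))
    beta, _ = imnlr.synthesize_betas(truth, comp, noise_sd=0.02, seed=102)
    purified = imnlr.simulate_purified_reference(truth, noise_sd=0.02, seed=103)
    return truth, comp, beta, purified


@pytest.fixture(scope="session")
def survival_records(small_cohort):
    rec = small_cohort.records.copy()
    rec["male"] = (rec["sex"] == "M").astype(int)
    rec["gbm"] = (rec["grade"] == "GBM").astype(int)
    rec["tert_only"] = (rec["mutation"] == "TERT-only").astype(int)
    rec["mdnlr_high"] = (small_cohort.composition.true_nlr >= 4.0).astype(int)
    return rec
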