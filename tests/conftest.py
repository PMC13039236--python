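import numpy as np
import pytest

import smokegxe as sg


@pytest.fixture(scope="session")
def ea_warmth_block():
    """Published European-American maternal-warmth interaction block."""
    return sg.PUBLISHED["EA"]["maternal_warmth"]


@pytest.fixture(scope="session")
def exact_cohort(ea_warmth_block):
    """Exact-count cohort reproducing the published EA warmth cells."""
    return sg.cohort_from_cell_counts(ea_warmth_block.cells, seed=7)


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized simulated cohort with clear main and interaction effects."""
    params = sg.SimulationParams(
        n_participants=5000,
        seed=11,
        beta0=-0.5,
        beta_G=0.5,
        beta_E=0.7,
        beta_GxE=0.4,
        beta_age=0.0,
        beta_gender=0.0,
        missing_rates={},
    )
    return sg.simulate_cohort(params)


@pytest.fixture(scope="session")
def sim_complete(sim_cohort):
    h = sg.harmonize_cohort(sim_cohort)
    return sg.complete_cases(h, ["Y", "G", "E_maternal_warmth"])


def truth_frame(cohort, epf="maternal_warmth"):
    """Analysis frame built from a simulated cohort's generating truth."""
    df = cohort.truth.rename(columns={"ever_smoked": "Y"})
    return df[["Y", "G", sg.exposure_column(epf)]]
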