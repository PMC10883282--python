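import numpy as np
import pandas as pd
import pytest

from proteoscreen import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.PanelConfig:
    """Scaled-down panel used by module tests: fast, same structure."""
    return sd.PanelConfig(
        n_cell_lines=10,
        n_proteins=300,
        n_psites=600,
        n_kinases=12,
        n_drugs=8,
        n_kinase_inhibitors=6,
        n_periodic_proteins=50,
        n_marker_links=2,
        n_timecourse_features=200,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return sd.generate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    """One full-size panel at the study's default conditions."""
    return sd.generate_panel(sd.PanelConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    """Hand-checkable 3x3 log10 matrix with one missing cell."""
    from proteoscreen.preprocessing import LOG10, AbundanceMatrix

    values = pd.DataFrame(
        [[2.0, 3.0, 4.0], [3.0, 4.0, 5.0], [np.nan, 5.0, 6.0]],
        index=["F1", "F2", "F3"],
        columns=["S1", "S2", "S3"],
    )
    return AbundanceMatrix(values, LOG10)
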