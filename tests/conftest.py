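import pytest

from mbseq import (
    SimulationConfig,
    build_default_panel,
    make_sample_profile,
)


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def small_panel(panel):
    """Two-amplicon subpanel used by the fast simulation tests."""
    return panel.subset(["EGFR_ex20", "EGFR_ex21"])


@pytest.fixture()
def small_config():
    return SimulationConfig(
        molecules_per_amplicon=200,
        reads_per_molecule=(3.0, 0.0),
        seed=11,
    )


@pytest.fixture()
def clean_config():
    """Error-free simulation with constant family size."""
    return SimulationConfig(
        molecules_per_amplicon=100,
        reads_per_molecule=(3.0, 0.0),
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        seed=5,
    )


@pytest.fixture()
def l858r_profile(small_panel):
    return make_sample_profile("s1", [("L858R", 0.11)], small_panel)
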