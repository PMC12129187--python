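import pytest

from alscore import BiomarkerPanel, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return BiomarkerPanel.default()


@pytest.fixture(scope="session")
def cohort63():
    """Default 63-participant synthetic cohort (8 strata, 11 censored
    epinephrine values, BP observed for 34)."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture()
def cohort_csv(tmp_path, cohort63):
    path = tmp_path / "cohort.csv"
    cohort63.data.to_csv(path, index=False)
    return path
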