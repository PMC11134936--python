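import pytest

from nestniche import AmpliconSimConfig, IsotopeSimConfig, gen_amplicon_panel, gen_isotope_panel


@pytest.fixture(scope="session")
def amplicon_panel():
    """Default synthetic amplicon panel (counts, taxonomy, meta)."""
    return gen_amplicon_panel(AmpliconSimConfig(seed=42))


@pytest.fixture(scope="session")
def isotope_panel():
    """Default convergent synthetic isotope panel."""
    return gen_isotope_panel(IsotopeSimConfig(seed=42))
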