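import pytest

from ampmeth.panel import AmpliconDef, CpGSite, PanelConfig
from ampmeth.simulate import synthetic_panel


@pytest.fixture(scope="session")
def tiny_amplicon() -> AmpliconDef:
    """Six-base primerless amplicon with two CpG sites (positions 1 and 4)."""
    return AmpliconDef(
        name="mini",
        reference="ACGTCG",
        cpg_sites=(CpGSite("1", 1), CpGSite("2", 4)),
    )


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    """Synthetic two-amplicon panel: TSDR-like (10 sites, sA excluded) + 7-site."""
    return synthetic_panel()


@pytest.fixture(scope="session")
def foxp3(panel) -> AmpliconDef:
    return panel["FOXP3_TSDR"]


@pytest.fixture(scope="session")
def ctla4(panel) -> AmpliconDef:
    return panel["CTLA4_ex2"]
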