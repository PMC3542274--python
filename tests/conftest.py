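import numpy as np
import pytest

from rhpanel.genotype import GenotypeMatrix
from rhpanel.markers import MarkerDef, MarkerMap
from rhpanel.simulate import PanelScenario, simulate_panel


@pytest.fixture(scope="session")
def chrom2d_map() -> MarkerMap:
    """25 evenly spaced markers on chromosome 2D."""
    length = 655_000_000
    markers = [
        MarkerDef(
            f"m{i + 1:02d}", "2D", pos_bp=int((i + 0.5) * length / 25),
            system="SSR",
        )
        for i in range(25)
    ]
    return MarkerMap(markers, {"2D": length}, {"2D": length // 2})


@pytest.fixture(scope="session")
def mapping_scenario() -> PanelScenario:
    """Breakage-rich single-homolog lines for ordering studies: about five
    breaks per transmitted chromosome, half of acentric fragments lost."""
    return PanelScenario(
        dose_Gy=450.0,
        n_families=460,
        siblings_per_family=1,
        G=1,
        break_rate_per_Gb_per_Gy=0.018,
        fragment_loss_prob=0.5,
        missing_rate=0.01,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_panel():
    """A small dose-driven panel with truth record (40 families x 4)."""
    scenario = PanelScenario(
        n_families=40, siblings_per_family=4, seed=42
    )
    return simulate_panel(scenario)


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    return GenotypeMatrix.from_calls(
        {
            "L1": ["lost", "retained", "retained"],
            "L2": ["retained", "retained", "missing"],
            "L3": ["retained", "lost", "lost"],
            "L4": ["retained", "retained", "retained"],
        },
        ["mA", "mB", "mC"],
        family_of={"L1": "F1", "L2": "F1", "L3": "F2", "L4": "F2"},
    )
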