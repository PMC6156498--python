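import numpy as np
import pytest

from mitodel.capture import CaptureDesign
from mitodel.panel import PanelConfig, Primer, build_panel
from mitodel.synth import canonical_panel


@pytest.fixture(scope="session")
def panel236():
    """The canonical 12F/36R, 236-pair panel."""
    return canonical_panel()


@pytest.fixture(scope="session")
def small_world():
    """A compact capture world (20 pairs, small stocks) for fast exact-chain
    simulations: 5 forward / 6 reverse primers over the scanned window."""
    primers = [
        Primer(f"F{i}", "F", s, s + 19) for i, s in enumerate(range(2000, 8001, 1500))
    ] + [
        Primer(f"R{j}", "R", e - 19, e) for j, e in enumerate(range(4000, 10501, 1300))
    ]
    panel = build_panel(primers, PanelConfig(L_max=1000))
    design = CaptureDesign(
        n_wells=len(panel),
        molecules_per_well=200,
        working_stock_copies=len(panel) * 200,
        n_worms=2,
        copies_per_worm=100_000,
    )
    return panel, design


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
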