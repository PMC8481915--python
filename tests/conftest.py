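import numpy as np
import pytest

from grscreen import synthetic_data as sd


@pytest.fixture(scope="session")
def noise_free_screen():
    """16-drug, two-population screen with exact expected counts."""
    drugs = sd.make_recovery_panel(16, rng=np.random.default_rng(1))
    cfg = sd.SimConfig(noise="none", seed=1)
    return sd.simulate_screen(drugs=drugs, cfg=cfg, include_cells=False)


@pytest.fixture(scope="session")
def noisy_cell_screen():
    """Small Poisson screen with per-cell marker intensities, for gating."""
    drugs = sd.make_drug_panel(8, n_selective=2, rng=np.random.default_rng(2))
    cfg = sd.SimConfig(seed=2)
    return sd.simulate_screen(drugs=drugs, cfg=cfg, include_cells=True)


def stain_control_cells(screen):
    keys = {
        (pm.plate_id, w.well)
        for pm in screen.plate_maps
        for w in pm.wells_by_role("stain_control")
    }
    cells = screen.cells
    mask = [
        (p, w) in keys for p, w in zip(cells["plate_id"], cells["well"])
    ]
    return cells[mask]
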