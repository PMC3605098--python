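import numpy as np
import pandas as pd
import pytest

from sunpanel.panel_io import GeneticMap, GenotypeMatrix, PanelMetadata
from sunpanel.synthetic import SimulationConfig, SweepConfig, simulate_panel


def make_matrix(dosage, positions=None, lgs=None, accession_prefix="a"):
    """Build a GenotypeMatrix (+map when positions given) from a 2-D array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    acc = [f"{accession_prefix}{i + 1}" for i in range(n)]
    markers = [f"m{i + 1:03d}" for i in range(m)]
    gmap = None
    if positions is not None:
        lgs = lgs if lgs is not None else [1] * m
        gmap = GeneticMap(pd.DataFrame(
            {"linkage_group": lgs, "position_cM": positions},
            index=pd.Index(markers, name="marker_id"),
        ))
    return GenotypeMatrix(acc, markers, dosage, gmap)


@pytest.fixture(scope="session")
def sweep_panel():
    """Small two-pool panel with the default sweep, shared across tests."""
    cfg = SimulationConfig(
        seed=101, markers_per_group=40, n_linkage_groups=17,
        n_per_pool={"HA": 40, "RHA": 50, "other": 15},
    )
    g, gmap, meta, truth = simulate_panel(cfg, return_truth=True)
    return cfg, g, gmap, meta, truth


@pytest.fixture(scope="session")
def null_panel():
    """Two pools drawn identically: no divergence, no sweep."""
    cfg = SimulationConfig(
        seed=202, markers_per_group=40, n_linkage_groups=10,
        n_per_pool={"HA": 50, "RHA": 50, "other": 10},
        pool_divergence=0.0, sweep=None,
    )
    g, gmap, meta = simulate_panel(cfg)
    return cfg, g, gmap, meta
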