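import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from perturbmap.barcodes import triplet_design
from perturbmap.config import SimulationConfig
from perturbmap.data import CountMatrix, SpotTable
from perturbmap.simulate import simulate_tissue


def make_spots(n, platform="manual", sample_id="s1", side=None, spacing=100.0,
               total_umi=None):
    """Grid spot table helper for constructed fixtures."""
    side = side or int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), side)
    return SpotTable(pd.DataFrame({
        "spot_id": [f"{sample_id}_s{i}" for i in range(n)],
        "x": cols * spacing,
        "y": rows * spacing,
        "sample_id": sample_id,
        "platform": platform,
        "row": rows,
        "col": cols,
        "total_umi": np.full(n, 6000) if total_umi is None else np.asarray(total_umi),
    }))


def make_counts(matrix, feature_kind="gene", spot_ids=None, prefix="f"):
    matrix = np.asarray(matrix)
    features = pd.DataFrame({
        "feature_id": [f"{prefix}{j}" for j in range(matrix.shape[1])],
        "feature_kind": feature_kind,
    })
    return CountMatrix(sp.csr_matrix(matrix), features, spot_ids)


@pytest.fixture(scope="session")
def design8():
    return triplet_design(8)


@pytest.fixture(scope="session")
def small_tissue(design8):
    """Strong-signal synthetic tissue shared across tests (read-only)."""
    cfg = SimulationConfig(n_spots=400, n_nodules=12, n_filler_genes=0)
    return simulate_tissue(design=design8, config=cfg, seed=1)
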