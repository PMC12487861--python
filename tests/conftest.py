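import numpy as np
import pandas as pd
import pytest

from spatialniche.io_cosmx import SpatialDataset


def make_dataset(cells, counts=None, gene_names=None, fov_offsets=None):
    """Hand-built SpatialDataset from (cell_id, fov, x, y, label) tuples."""
    frame = pd.DataFrame(cells, columns=["cell_id", "fov", "x", "y", "label"])
    frame["label"] = frame["label"].astype("object")
    if gene_names is None:
        gene_names = ["G1"]
    if counts is None:
        counts = np.zeros((len(gene_names), len(frame)), dtype=np.int64)
    else:
        counts = np.asarray(counts, dtype=np.int64)
    if fov_offsets is None:
        fovs = sorted(set(frame["fov"]))
        fov_offsets = pd.DataFrame(
            {"x": [0.0] * len(fovs), "y": [0.0] * len(fovs)},
            index=pd.Index(fovs, name="fov"),
        )
    ds = SpatialDataset(frame, counts, list(gene_names), fov_offsets)
    ds.validate()
    return ds


@pytest.fixture
def planted_dataset():
    """Default-condition synthetic run (regTh17 attracted to IL-36G+ KC)."""
    from spatialniche.simulate import SimConfig, generate_spatial

    dataset, truth, membership = generate_spatial(SimConfig(seed=11))
    return dataset, truth, membership
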