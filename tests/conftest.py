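import numpy as np
import pandas as pd
import pytest

from cytobn.discretize import BinEdges, DiscretizedMatrix
from cytobn.io import CellMatrix


def ann_frame(n, response=None, patient="p1", day=1, tsize=0.0):
    """Minimal per-cell annotation frame for fixtures."""
    if response is None:
        response = [False] * n
    return pd.DataFrame({
        "patient_id": [patient] * n,
        "day": [day] * n,
        "response": list(response),
        "tsize": [tsize] * n,
    })


def labels_matrix(columns: dict, response=None) -> DiscretizedMatrix:
    """DiscretizedMatrix from raw integer label columns (for BN tests)."""
    lab = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in columns.items()})
    edge_map = {c: BinEdges(c, tuple(float(b) for b in range(1, int(lab[c].max()) + 1)),
                            int(lab[c].max()) + 1)
                for c in lab.columns}
    return DiscretizedMatrix(lab, edge_map, ann_frame(len(lab), response=response))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cells(rng):
    """200-cell, 4-marker cohort with 2 responder patients out of 5."""
    n_per, markers = 40, ["M1", "M2", "M3", "M4"]
    frames, anns = [], []
    for p in range(5):
        resp = p < 2
        vals = pd.DataFrame(
            np.exp(rng.normal(5 + 0.3 * resp, 0.5, size=(n_per, len(markers)))),
            columns=markers)
        frames.append(vals)
        anns.append(ann_frame(n_per, response=[resp] * n_per,
                              patient=f"P{p}", tsize=-40.0 if resp else 5.0))
    return CellMatrix(pd.concat(frames, ignore_index=True),
                      pd.concat(anns, ignore_index=True))
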