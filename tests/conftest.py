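import numpy as np
import pandas as pd
import pytest

from dwmerge.refl_io import DatasetGraph, GraphEdge, ReflectionTable


@pytest.fixture
def toy_table() -> ReflectionTable:
    """Two tiny datasets sharing three reflections, Friedel pairs present."""
    rows = []
    rng = np.random.default_rng(11)
    for ds in ("apo", "holo"):
        for i, hkl in enumerate([(1, 2, 3), (2, 0, 1), (3, 1, 1)]):
            for sign in ("+", "-"):
                for img in (0, 1):
                    rows.append((*hkl, sign, ds, img,
                                 float(rng.uniform(0.5, 2.0)), 0.1,
                                 i == 0, 1, 2.0 + i,
                                 rng.uniform(-1, 1), rng.uniform(-1, 1), 1.0))
    df = pd.DataFrame(rows, columns=[
        "h", "k", "l", "friedel_sign", "dataset_id", "image_id", "I", "sigI",
        "centric", "epsilon", "d", "det_x", "det_y", "wavelength"])
    return ReflectionTable.from_frame(df)


@pytest.fixture
def toy_graph() -> DatasetGraph:
    return DatasetGraph(["apo", "holo"], [GraphEdge("apo", "holo", 0.9)])
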