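"""Small builders used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

import embryomap as em


def count_matrix(arr, genes=None, cells=None, batch="b0", labels=None) -> em.CountMatrix:
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    meta = pd.DataFrame(
        {
            "batch": batch,
            "time_point": None,
            "label": labels if labels is not None else [None] * len(cells),
        },
        index=cells,
    )
    return em.CountMatrix(list(genes), list(cells), arr, meta)


def log_matrix(values, genes=None, cells=None, batch="b0") -> em.LogMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return em.LogMatrix(list(genes), list(cells), values, {"batch": batch})
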