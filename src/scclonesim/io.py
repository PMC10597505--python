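"""Plain-text artifact writers and readers.

Matrices go to TSV with a header row of mutation ids and one row of
integers per cell; labels and doublet flags to two-column TSVs.  Sparse
read-count matrices use (row, col, count) triplets.  Everything round-trips
through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_labels",
    "read_labels",
    "write_flags",
    "read_flags",
    "write_sparse_counts",
    "read_sparse_counts",
    "write_manifest",
    "read_manifest",
]


def write_matrix(values: np.ndarray, path, transpose: bool = False) -> None:
    """Write a cells x mutations integer matrix as TSV.

    ``transpose=True`` emits mutations x cells (the dialect expected by
    mutation-tree tools).
    """
    m = np.asarray(values)
    if transpose:
        m = m.T
    df = pd.DataFrame(m, columns=[f"m{j}" if not transpose else f"c{j}" for j in range(m.shape[1])])
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=np.int8)


def write_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame(
        {"cell_id": np.arange(len(labels)), "clone_id": np.asarray(labels)}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["clone_id"].to_numpy()


def write_flags(flags: np.ndarray, path) -> None:
    pd.DataFrame(
        {"cell_id": np.arange(len(flags)), "is_doublet": np.asarray(flags).astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_flags(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["is_doublet"].to_numpy().astype(bool)


def write_sparse_counts(counts: np.ndarray, path) -> None:
    """Write nonzero entries of an integer matrix as (row, col, count)."""
    r, c = np.nonzero(counts)
    pd.DataFrame({"row": r, "col": c, "count": counts[r, c]}).to_csv(path, sep="\t", index=False)


def read_sparse_counts(path, shape) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    out = np.zeros(shape, dtype=np.int8)
    out[df["row"], df["col"]] = df["count"]
    return out


def write_manifest(config: dict, path) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
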