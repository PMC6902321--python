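"""Plain-text interchange formats.

* pedigree: whitespace-delimited ``id sire dam birth_year sex`` with 1-based
  consecutive ids and 0 for an unknown parent;
* phenotypes: ``id value herd year season``;
* genotypes: ``id`` followed by one 0/1/2 allele count per marker;
* sparse symmetric matrices: 1-based coordinate triples of the lower
  triangle.

All writers and readers round-trip exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_genotypes",
    "read_genotypes",
    "write_sparse_lower",
    "read_sparse_lower",
]

_PED_COLS = ["id", "sire", "dam", "birth_year", "sex"]


def write_pedigree(pedigree, path) -> None:
    pedigree.to_dataframe().to_csv(path, sep=" ", header=False, index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=_PED_COLS)
    if df["id"].tolist() != list(range(1, len(df) + 1)):
        raise ValueError("pedigree ids must be 1-based and consecutive")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    out = phenotypes.copy()
    out["animal"] = out["animal"] + 1  # 1-based ids on disk
    out[["animal", "value", "herd", "year", "season"]].to_csv(
        path, sep=" ", header=False, index=False, float_format="%.10g"
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["animal", "value", "herd", "year", "season"]
    )
    df["animal"] = df["animal"] - 1
    return df


def write_genotypes(ids: np.ndarray, genotypes: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(np.asarray(ids) + 1, np.asarray(genotypes)):
            fh.write(f"{i} " + " ".join(map(str, row)) + "\n")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    mat = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return mat[:, 0] - 1, mat[:, 1:].astype(np.int8)


def write_sparse_lower(matrix: sp.spmatrix, path) -> None:
    coo = sp.tril(sp.coo_matrix(matrix))
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.17g}\n")


def read_sparse_lower(path, shape=None) -> sp.csc_matrix:
    trip = np.loadtxt(path, ndmin=2)
    i = trip[:, 0].astype(np.int64) - 1
    j = trip[:, 1].astype(np.int64) - 1
    v = trip[:, 2]
    n = shape or (int(max(i.max(), j.max())) + 1)
    low = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsc()
    upper = sp.triu(low.T, k=1)
    return (low + upper).tocsc()
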