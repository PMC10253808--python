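"""Population structure from GASMs.

The genetic similarity coefficient (GSC) between two inbred accessions is
the proportion of markers at which they carry the same allele.  The top
eigenvectors of the GSC matrix serve as fixed covariates correcting
population-structure bias in the association scan (default q = 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .gasm import GasmSet


@dataclass
class SimilarityMatrix:
    accession_ids: list[str]
    values: np.ndarray  # n x n, symmetric, diagonal 1, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries outside [0, 1]")
        self.values = v


@dataclass
class StructureCovariates:
    accession_ids: list[str]
    vectors: np.ndarray  # n x q, unit-norm columns
    eigenvalues: np.ndarray  # length q, descending

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def q(self) -> int:
        return self.vectors.shape[1]


def compute_gsc(gasm_set: GasmSet) -> SimilarityMatrix:
    """GSC(i, j) = mean over markers of 1[allele_i == allele_j].

    The allele-identity indicator suits a fully homozygous panel; partial
    allele-sharing weights for heterozygotes are unnecessary here.
    """
    if not gasm_set.markers:
        raise ValueError("empty GasmSet")
    n = len(gasm_set.accession_ids)
    if n < 2:
        raise ValueError("need at least 2 accessions")
    total = np.zeros((n, n), dtype=np.float64)
    for m in gasm_set:
        a = m.assignment
        total += a[:, None] == a[None, :]
    values = total / len(gasm_set.markers)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(gasm_set.accession_ids), values)


def top_eigenvectors(gsc: SimilarityMatrix, q: int = 10) -> StructureCovariates:
    """Leading q eigenpairs of the GSC matrix, unit-norm and sign-fixed.

    The sign convention makes the largest-magnitude entry of each vector
    positive, so results are reproducible across LAPACK builds.
    """
    n = len(gsc.accession_ids)
    if q >= n:
        raise ValueError(f"q = {q} must be < number of accessions {n}")
    if q < 1:
        raise ValueError("q must be >= 1")
    w, v = scipy.linalg.eigh(gsc.values, subset_by_index=(n - q, n - 1))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for k in range(q):
        idx = np.argmax(np.abs(v[:, k]))
        if v[idx, k] < 0:
            v[:, k] = -v[:, k]
    return StructureCovariates(list(gsc.accession_ids), v, w)


def write_structure(cov: StructureCovariates, path: str | Path) -> None:
    df = pd.DataFrame(
        cov.vectors,
        index=pd.Index(cov.accession_ids, name="accession"),
        columns=[f"ev{k + 1}" for k in range(cov.q)],
    )
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{e:.10g}" for e in cov.eigenvalues) + "\n")
        df.to_csv(fh, sep="\t")


def read_structure(path: str | Path) -> StructureCovariates:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# eigenvalues"):
            raise ValueError(f"{path}: missing eigenvalue header")
        eigenvalues = np.array([float(x) for x in header.split("\t")[1:]])
        df = pd.read_csv(fh, sep="\t", index_col="accession")
    return StructureCovariates([str(a) for a in df.index], df.to_numpy(), eigenvalues)
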