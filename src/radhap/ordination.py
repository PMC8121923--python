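"""Genetic distances and principal coordinates analysis (classical MDS).

The distance is the uncorrected p-distance (proportion of differing
alignment columns); PCoA is classical scaling of the squared-distance
matrix: B = -1/2 J D^2 J with J the centering operator, eigendecomposed,
coordinates scaled by the square roots of the positive eigenvalues.
Negative eigenvalues (non-Euclidean distance matrices) are retained and
reported, never silently dropped. Axis signs are fixed deterministically:
the first nonzero loading of every axis is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from radhap.snp import SnpAlignment


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # individuals x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    truncated: bool = False  # fewer axes returned than requested


def p_distance(aln: SnpAlignment, exclude: set[str] | frozenset[str] = frozenset()) -> DistanceMatrix:
    """Pairwise proportion of differing columns, after dropping ``exclude``."""
    labels = [ind for ind in aln.individuals if ind not in exclude]
    if len(labels) < 2:
        raise ValueError("fewer than 2 individuals remain after exclusion")
    seqs = [np.frombuffer(aln.sequences[l].encode(), dtype=np.uint8) for l in labels]
    length = len(seqs[0])
    if length == 0:
        raise ValueError("empty alignment")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.count_nonzero(seqs[i] != seqs[j]) / length
    return DistanceMatrix(labels, d)


def jc_corrected_distance(aln: SnpAlignment, exclude: set[str] = frozenset()) -> DistanceMatrix:
    """Jukes-Cantor corrected distance: -3/4 ln(1 - 4p/3). Optional alternative metric."""
    pd = p_distance(aln, exclude)
    p = np.clip(pd.d, 0.0, 0.7499999)
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pd.labels, d)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Returns at most ``n_axes`` coordinate axes; if fewer eigenvalues are
    positive, returns those with ``truncated=True``. All eigenvalues are
    reported in descending order.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    D2 = dist.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals[0]), 1.0)
    n_pos = int(np.sum(eigvals > tol))
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])[None, :]
    for a in range(k):  # deterministic sign: first nonzero loading positive
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return PcoaResult(list(dist.labels), coords, eigvals, truncated=k < n_axes)


def write_coordinates(res: PcoaResult, path: str | Path) -> None:
    """TSV: eigenvalue header row, then one row per individual with axis coordinates."""
    k = res.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(f"axis{i + 1}" for i in range(k)) + "\n")
        fh.write("#eigenvalues\t" + "\t".join(f"{v:.10g}" for v in res.eigenvalues) + "\n")
        for i, label in enumerate(res.labels):
            row = "\t".join(f"{v:.10g}" for v in res.coordinates[i])
            fh.write(f"{label}\t{row}\n")


def read_coordinates(path: str | Path) -> PcoaResult:
    """Round-trip reader for :func:`write_coordinates` output."""
    labels, rows, eigvals = [], [], None
    with open(path) as fh:
        header = fh.readline()
        k = len(header.strip().split("\t")) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#eigenvalues":
                eigvals = np.array([float(v) for v in parts[1:]])
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if eigvals is None:
        raise ValueError(f"missing eigenvalue row in {path}")
    return PcoaResult(labels, np.array(rows).reshape(len(labels), k), eigvals)
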