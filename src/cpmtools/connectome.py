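"""Functional-connectivity matrices and edge bookkeeping.

An FC matrix is the node-by-node Pearson correlation matrix of regional
fMRI time series: symmetric, unit diagonal, off-diagonal entries in
[-1, 1]. Edges (unordered node pairs i < j) are stored in row-major
upper-triangle order, 0-based — the single edge-ordering convention used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FCMatrix",
    "fc_from_timeseries",
    "vectorize_edges",
    "devectorize",
    "n_edges",
    "edge_pairs",
    "pair_to_flat",
    "flat_to_pair",
]

_SYMMETRY_TOL = 1e-10


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) arrays of the upper triangle in flat-edge order."""
    return np.triu_indices(n_nodes, k=1)


def pair_to_flat(i: int, j: int, n_nodes: int) -> int:
    """Flat edge position of the unordered pair {i, j}."""
    if i == j:
        raise ValueError("an edge needs two distinct nodes")
    if i > j:
        i, j = j, i
    if j >= n_nodes or i < 0:
        raise ValueError(f"node pair ({i}, {j}) out of range for {n_nodes} nodes")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def flat_to_pair(k: int, n_nodes: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_flat`."""
    if not 0 <= k < n_edges(n_nodes):
        raise ValueError(f"flat index {k} out of range for {n_nodes} nodes")
    # solve for the row: k lies in row i's block of (n-1-i) entries
    i = int(n_nodes - 2 - np.floor(
        (np.sqrt(4 * n_nodes * (n_nodes - 1) - 8 * k - 7) - 1) / 2))
    j = k - i * (2 * n_nodes - i - 1) // 2 + i + 1
    return i, int(j)


@dataclass(frozen=True)
class FCMatrix:
    """Validated symmetric correlation matrix for one subject.

    Raises ``ValueError`` on construction if the array is not square,
    symmetric (within 1e-10), unit-diagonal, or has off-diagonal entries
    outside [-1, 1].
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {v.shape}")
        if not np.all(np.abs(v - v.T) <= _SYMMETRY_TOL):
            raise ValueError("FC matrix is not symmetric within 1e-10")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("FC matrix diagonal must be exactly 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ValueError("off-diagonal FC values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other) -> bool:  # value equality, for round-trip tests
        return isinstance(other, FCMatrix) and np.array_equal(self.values, other.values)


def fc_from_timeseries(ts: np.ndarray) -> FCMatrix:
    """Pearson-correlation FC matrix from a node-by-time series array.

    Parameters
    ----------
    ts : array, shape (n_nodes, n_timepoints)
        Preprocessed regional time series; every node must have nonzero
        variance and there must be at least 3 time points.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"time series must be 2-D (nodes x time), got {ts.ndim}-D")
    if ts.shape[1] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series at node(s) {constant.tolist()}")
    c = np.corrcoef(ts)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)  # absorb floating-point drift
    return FCMatrix(c)


def vectorize_edges(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector (length n(n-1)/2) in flat-edge order."""
    v = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    iu, ju = edge_pairs(v.shape[0])
    return v[iu, ju].copy()


def devectorize(edges: np.ndarray, n_nodes: int) -> FCMatrix:
    """Rebuild a symmetric unit-diagonal FC matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    expected = n_edges(n_nodes)
    if edges.shape != (expected,):
        raise ValueError(
            f"edge vector has length {edges.size}, expected {expected} for {n_nodes} nodes")
    m = np.eye(n_nodes)
    iu, ju = edge_pairs(n_nodes)
    m[iu, ju] = edges
    m[ju, iu] = edges
    return FCMatrix(m)
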