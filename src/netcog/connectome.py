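"""Connectome matrices, edge masks and their file formats.

A connectome is an 85x85 symmetric nonnegative matrix for one
participant in one weighting: SC (streamline count), FA (fractional
anisotropy, unitless in [0, 1]), MD (mean diffusivity, 1e-3 mm^2/s) or
SD (streamline density, streamlines per mm^3). Where a participant has
no streamlines on an edge (SC = 0) the FA/MD entries for that edge are
zero as well, since diffusion values are sampled along streamlines.

Files are plain text: dense 85x85 delimited matrices (TSV default,
comma accepted) with no header, or a long-format edge table with header
``participant_id,i,j,weight``. Edge masks are CSV with header ``i,j``,
i < j, sorted ascending. All indices are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import N_NODES, N_PAIRS

WEIGHTINGS = ("SC", "FA", "MD", "SD")

#: Canonical order of the 3570 unordered node pairs: i ascending, then j.
_TRIU = np.triu_indices(N_NODES, k=1)


def edge_pairs() -> np.ndarray:
    """(3570, 2) int array of all unordered pairs in canonical order."""
    return np.column_stack(_TRIU)


def pair_to_edge_index(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Map unordered pairs (i < j) to their canonical edge-vector position."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(i >= j):
        raise ValueError("pairs must satisfy i < j")
    if np.any(i < 0) or np.any(j >= N_NODES):
        raise ValueError("node index out of atlas range")
    # offset of row i in the upper triangle, then position of j within the row
    return i * (2 * N_NODES - i - 1) // 2 + (j - i - 1)


def matrix_to_edge_vector(W: np.ndarray) -> np.ndarray:
    """Upper-triangle entries of W in canonical edge order (length 3570)."""
    return np.asarray(W)[_TRIU]


def edge_vector_to_matrix(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`matrix_to_edge_vector`; returns a symmetric matrix."""
    v = np.asarray(v)
    if v.shape[-1] != N_PAIRS:
        raise ValueError(f"edge vector must have length {N_PAIRS}")
    W = np.zeros(v.shape[:-1] + (N_NODES, N_NODES), dtype=v.dtype)
    W[..., _TRIU[0], _TRIU[1]] = v
    W[..., _TRIU[1], _TRIU[0]] = v
    return W


@dataclass
class Connectome:
    """One participant's weighted network in one weighting."""

    participant_id: str
    weighting: str
    W: np.ndarray

    def __post_init__(self) -> None:
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        W = np.asarray(self.W, dtype=float)
        if W.shape != (N_NODES, N_NODES):
            raise ValueError(f"matrix must be {N_NODES}x{N_NODES}, got {W.shape}")
        dev = np.abs(W - W.T).max()
        if dev > 1e-9:
            raise ValueError(f"matrix asymmetric: max |W - W.T| = {dev:.3e}")
        # symmetrize from the upper triangle so downstream arithmetic is exact
        W = np.triu(W, k=1)
        W = W + W.T
        if W.min() < 0:
            raise ValueError("negative edge weight")
        if self.weighting == "FA" and W.max() > 1.0 + 1e-12:
            raise ValueError(f"FA weight {W.max():.4f} exceeds 1")
        self.W = W

    def edge_vector(self) -> np.ndarray:
        return matrix_to_edge_vector(self.W)


@dataclass(frozen=True)
class EdgeMask:
    """Set of unordered node pairs defining a reference network."""

    edges: frozenset[tuple[int, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < N_NODES):
                raise ValueError(f"invalid edge ({i}, {j})")

    @classmethod
    def from_pairs(cls, pairs, provenance: str = "") -> "EdgeMask":
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        return cls(norm, provenance)

    def __len__(self) -> int:
        return len(self.edges)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        """Deterministic serialization order: i ascending, then j."""
        return sorted(self.edges)

    def indicator(self) -> np.ndarray:
        """Boolean length-3570 vector over the canonical edge order."""
        ind = np.zeros(N_PAIRS, dtype=bool)
        if self.edges:
            pairs = np.array(self.sorted_pairs())
            ind[pair_to_edge_index(pairs[:, 0], pairs[:, 1])] = True
        return ind

    def matrix(self) -> np.ndarray:
        """Boolean 85x85 symmetric indicator matrix."""
        return edge_vector_to_matrix(self.indicator().astype(np.uint8)).astype(bool)


@dataclass
class NodeVolumes:
    """Per-participant grey matter region volumes (mm^3), atlas order."""

    participant_id: str
    vol: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vol, dtype=float)
        if v.shape != (N_NODES,):
            raise ValueError(f"expected {N_NODES} volumes, got {v.shape}")
        if np.any(v <= 0):
            raise ValueError("region volumes must be positive")
        self.vol = v


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(first_line: str) -> str:
    return "," if first_line.count(",") >= first_line.count("\t") else "\t"


def load_connectome(path: str | os.PathLike, weighting: str,
                    participant_id: str | None = None) -> Connectome:
    """Read a dense matrix file or long-format edge table.

    Long-format rows are mirrored to both triangles; pairs listed twice
    must agree. Dense matrices must be symmetric to 1e-9.
    """
    path = os.fspath(path)
    with open(path) as f:
        first = f.readline()
    if "participant_id" in first:  # long format with header
        df = pd.read_csv(path)
        expected = ["participant_id", "i", "j", "weight"]
        if list(df.columns) != expected:
            raise ValueError(f"long-format header must be {expected}")
        ids = df["participant_id"].unique()
        if len(ids) > 1:
            raise ValueError("long-format file contains multiple participants")
        pid = participant_id or str(ids[0])
        W = np.zeros((N_NODES, N_NODES))
        for row in df.itertuples(index=False):
            i, j, w = int(row.i), int(row.j), float(row.weight)
            if i == j:
                raise ValueError("self-pairs not allowed")
            W[i, j] = w
            W[j, i] = w
        return Connectome(pid, weighting, W)
    delim = _sniff_delimiter(first)
    W = np.loadtxt(path, delimiter=delim)
    if W.shape != (N_NODES, N_NODES):
        raise ValueError(f"matrix file is {W.shape}, expected square {N_NODES}")
    pid = participant_id or os.path.splitext(os.path.basename(path))[0]
    return Connectome(pid, weighting, W)


def write_connectome(c: Connectome, path: str | os.PathLike) -> None:
    """Write a dense TSV matrix with full floating-point round-trip precision."""
    np.savetxt(os.fspath(path), c.W, delimiter="\t", fmt="%.17g")


def load_mask(path: str | os.PathLike) -> EdgeMask:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["i", "j"]:
        raise ValueError("mask file must have header 'i,j'")
    return EdgeMask.from_pairs(
        zip(df["i"].astype(int), df["j"].astype(int)),
        provenance=f"loaded from {os.path.basename(os.fspath(path))}",
    )


def write_mask(m: EdgeMask, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as f:
        f.write("i,j\n")
        for i, j in m.sorted_pairs():
            f.write(f"{i},{j}\n")


# ---------------------------------------------------------------------------
# Operations


def apply_mask(c: Connectome, m: EdgeMask) -> Connectome:
    """Zero every entry outside the mask; entries inside are untouched."""
    W = np.where(m.matrix(), c.W, 0.0)
    return Connectome(c.participant_id, c.weighting, W)


def streamline_density(c: Connectome, v: NodeVolumes) -> Connectome:
    """Normalize streamline counts by summed endpoint region volumes.

    SD[i, j] = SC[i, j] / (vol[i] + vol[j]), the volumetric correction
    used to separate macroscopic wiring capacity from brain-size scaling.
    """
    if c.weighting != "SC":
        raise ValueError("streamline density is defined on SC-weighted networks")
    denom = v.vol[:, None] + v.vol[None, :]
    W = c.W / denom
    np.fill_diagonal(W, 0.0)
    return Connectome(c.participant_id, "SD", W)
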