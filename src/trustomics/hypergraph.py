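"""KNN similarity hypergraphs and their normalized Laplacian.

Each sample is a vertex, and one hyperedge is centred on every vertex:
the vertex itself plus its k-1 nearest neighbours under cosine
similarity (or smallest Euclidean distance in the ablation variant).
The resulting n x n incidence matrix G, the vertex/hyperedge degree
diagonals Dv and De, and the normalized operator

    Lh = Dv^{-1/2} G De^{-1} G^T Dv^{-1/2}

describe the structure; Lh is the smoothing operand of the hypergraph
convolution.  With all hyperedges of size k, Dv^{-1} G De^{-1} G^T is
row-stochastic, so Lh is symmetric positive semidefinite with spectrum
in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics.pairwise import cosine_similarity

__all__ = ["HypergraphStructure", "cosine_similarity_matrix",
           "euclidean_distance_matrix", "build_incidence",
           "hypergraph_laplacian", "simple_graph_adjacency_laplacian",
           "build_hypergraph", "dump_structure"]


@dataclass
class HypergraphStructure:
    """Incidence matrix, degree vectors, and (optionally) the Laplacian.

    ``incidence[v, e]`` is 1 when vertex v belongs to hyperedge e; the
    hyperedge with column index v is the one centred on vertex v.
    """

    incidence: np.ndarray
    vertex_degrees: np.ndarray
    edge_degrees: np.ndarray
    laplacian: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity with diagonal fixed to 1.

    Zero-norm rows have undefined cosine; their off-diagonal similarity
    is set to 0 and the self-similarity to 1 so downstream KNN selection
    stays well defined.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    S = cosine_similarity(X)  # zero rows yield 0 similarity everywhere
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def euclidean_distance_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return squareform(pdist(X, metric="euclidean"))


def _knn_rows(S: np.ndarray, k: int, mode: str) -> np.ndarray:
    """Row v -> the k member vertices of the hyperedge centred on v.

    Self always included first; the remaining k-1 slots go to the most
    similar (or least distant) other vertices, ties broken by ascending
    vertex index.
    """
    n = S.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    if mode not in ("similarity", "distance"):
        raise ValueError(f"mode must be 'similarity' or 'distance', got {mode!r}")
    keys = S.astype(np.float64).copy()
    if mode == "distance":
        keys = -keys
    np.fill_diagonal(keys, np.inf)  # self first regardless of stored diagonal
    members = np.empty((n, k), dtype=np.intp)
    idx = np.arange(n)
    for v in range(n):
        # lexsort: primary key descending score, secondary ascending index
        order = np.lexsort((idx, -keys[v]))
        members[v] = order[:k]
    return members


def build_incidence(S: np.ndarray, k: int, mode: str = "similarity"
                    ) -> HypergraphStructure:
    """Build the n x n incidence matrix from a similarity/distance matrix.

    Column e_v holds the hyperedge centred on vertex v, so every column
    sums to k; k=1 gives the identity (self-only hyperedges) and k=n the
    all-ones matrix.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    members = _knn_rows(S, k, mode)
    G = np.zeros((n, n), dtype=np.float64)
    for v in range(n):
        G[members[v], v] = 1.0
    return HypergraphStructure(
        incidence=G,
        vertex_degrees=G.sum(axis=1).astype(np.intp),
        edge_degrees=G.sum(axis=0).astype(np.intp))


def hypergraph_laplacian(structure: HypergraphStructure) -> np.ndarray:
    """Lh = Dv^{-1/2} G De^{-1} G^T Dv^{-1/2}; stored on the structure."""
    G = structure.incidence
    dv = structure.vertex_degrees.astype(np.float64)
    de = structure.edge_degrees.astype(np.float64)
    if (dv < 1).any() or (de < 1).any():
        raise ValueError("all vertex and hyperedge degrees must be >= 1")
    dv_isqrt = 1.0 / np.sqrt(dv)
    B = (dv_isqrt[:, None] * G) / de[None, :]
    Lh = B @ (dv_isqrt[:, None] * G).T
    # enforce exact symmetry against round-off
    Lh = 0.5 * (Lh + Lh.T)
    structure.laplacian = Lh
    return Lh


def simple_graph_adjacency_laplacian(S: np.ndarray, k: int,
                                     mode: str = "similarity") -> np.ndarray:
    """Normalized KNN-graph adjacency D^{-1/2} A D^{-1/2} (ablation variant).

    A contains self-loops and each vertex's k-1 nearest neighbours,
    symmetrized by A <- max(A, A^T); this smoothing operator plays the
    role Lh plays for the hypergraph.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    members = _knn_rows(S, k, mode)
    A = np.zeros((n, n), dtype=np.float64)
    for v in range(n):
        A[v, members[v]] = 1.0
    A = np.maximum(A, A.T)
    d_isqrt = 1.0 / np.sqrt(A.sum(axis=1))
    out = d_isqrt[:, None] * A * d_isqrt[None, :]
    return 0.5 * (out + out.T)


def build_hypergraph(X: np.ndarray, k: int, similarity: str = "cosine"
                     ) -> HypergraphStructure:
    """Convenience: features -> similarity/distance -> incidence -> Laplacian."""
    if similarity == "cosine":
        S, mode = cosine_similarity_matrix(X), "similarity"
    elif similarity == "euclidean":
        S, mode = euclidean_distance_matrix(X), "distance"
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    structure = build_incidence(S, k, mode)
    hypergraph_laplacian(structure)
    return structure


def dump_structure(structure: HypergraphStructure, out_dir: str | Path,
                   prefix: str = "hypergraph") -> None:
    """Debug dump of G and Lh as MatrixMarket sparse files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / f"{prefix}_incidence.mtx",
                 sparse.csr_matrix(structure.incidence))
    if structure.laplacian is not None:
        spio.mmwrite(out_dir / f"{prefix}_laplacian.mtx",
                     sparse.coo_matrix(structure.laplacian))
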