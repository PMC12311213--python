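"""Patient-similarity graphs for transductive node classification.

Each patient is a node carrying the selected (standardized) feature vector;
an undirected edge joins two patients of the same cohort when the cosine
similarity of their feature vectors reaches a threshold. The propagation
operator of the graph convolution is the symmetric normalization with
self-loops,

    P = D̃^(-1/2) (A + I) D̃^(-1/2),

where D̃ is the degree matrix of A + I. Isolated nodes keep their self-loop
so every patient is classifiable; cohorts never share edges (one graph per
hospital cohort).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine


@dataclass
class NodeTable:
    """Per-cohort node attributes: ids, selected features, binary labels.

    With d selected features the underlying tabular object has d + 2
    columns (features + unique id + target class).
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = self.X.shape[0]
        if len(self.ids) != n or self.y.shape[0] != n:
            raise ValueError("ids, X and y must agree in length")
        if len(set(self.ids)) != n:
            raise ValueError("node ids must be unique")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1] + 2


@dataclass
class PatientGraph:
    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    S: np.ndarray                 # cosine similarity matrix
    edges: list[tuple[int, int]]  # i < j pairs
    A: np.ndarray                 # 0/1 adjacency, zero diagonal
    p_hat: np.ndarray             # normalized propagation matrix
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def a_tilde(self) -> np.ndarray:
        return self.A + np.eye(self.n_nodes)

    @property
    def d_tilde(self) -> np.ndarray:
        return np.diag(self.a_tilde.sum(axis=1))

    def p_hat_sparse(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.p_hat)


def cosine_similarity_matrix(X: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Pairwise cosine similarity with an exactly-unit diagonal.

    A zero-norm row has no direction, so it is rejected with the offending
    row id in the message.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(f"zero-norm feature vector for {name}; cosine similarity undefined")
    S = _sk_cosine(X)
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def build_edges(S: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """All pairs (i, j), i < j, with S_ij >= threshold (inclusive).

    Self-pairs are never edges; self-loops enter only through A + I.
    """
    if not -1.0 <= threshold <= 1.0 + 1e-12:
        # thresholds above 1 are allowed as an explicit "no edges" request
        pass
    S = np.asarray(S)
    iu, ju = np.triu_indices_from(S, k=1)
    hit = S[iu, ju] >= threshold
    return list(zip(iu[hit].tolist(), ju[hit].tolist()))


def edges_to_adjacency(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    A = np.zeros((n, n))
    if edges:
        idx = np.asarray(edges)
        A[idx[:, 0], idx[:, 1]] = 1.0
        A[idx[:, 1], idx[:, 0]] = 1.0
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization with self-loops.

    Rows of an isolated node reduce to the standard basis vector, so the
    operator is well defined on every graph; the spectrum lies in [-1, 1].
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal (self-loops are added here)")
    if not np.all(np.isin(A, [0.0, 1.0])):
        raise ValueError("adjacency must be 0/1")
    a_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)


def assemble_graph(node_table: NodeTable, threshold: float) -> PatientGraph:
    """Build the full per-cohort graph at one similarity threshold."""
    S = cosine_similarity_matrix(node_table.X, node_table.ids)
    edges = build_edges(S, threshold)
    A = edges_to_adjacency(edges, node_table.X.shape[0])
    return PatientGraph(
        ids=node_table.ids,
        X=node_table.X,
        y=node_table.y,
        S=S,
        edges=edges,
        A=A,
        p_hat=normalize_adjacency(A),
        threshold=threshold,
    )


def graph_summary(graph: PatientGraph) -> dict:
    n = graph.n_nodes
    n_edges = len(graph.edges)
    n_comp = connected_components(sp.csr_matrix(graph.A), directed=False)[0]
    density = n_edges / (n * (n - 1) / 2) if n > 1 else 0.0
    return {
        "n_nodes": n,
        "n_edges": n_edges,
        "n_components": int(n_comp),
        "density": float(density),
        "threshold": float(graph.threshold),
    }


def export_components(graph: PatientGraph, out_dir: str | Path) -> dict:
    """Write the edge list (TSV: source_id, target_id, similarity), the
    per-component node lists (JSON) and the summary (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    edge_path = out_dir / "edges.tsv"
    with open(edge_path, "w") as fh:
        fh.write("source_id\ttarget_id\tsimilarity\n")
        for i, j in graph.edges:
            fh.write(f"{graph.ids[i]}\t{graph.ids[j]}\t{graph.S[i, j]:.6f}\n")

    n_comp, labels = connected_components(sp.csr_matrix(graph.A), directed=False)
    comps: dict[str, list[str]] = {}
    for node, comp in enumerate(labels):
        comps.setdefault(str(int(comp)), []).append(graph.ids[node])
    comp_path = out_dir / "components.json"
    comp_path.write_text(json.dumps(comps, indent=1))

    summary = graph_summary(graph)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def write_adjacency_mtx(graph: PatientGraph, path: str | Path) -> Path:
    from scipy.io import mmwrite

    path = Path(path)
    mmwrite(str(path.with_suffix("")), sp.coo_matrix(graph.A), field="integer", symmetry="symmetric")
    return path.with_suffix(".mtx")


def read_adjacency_mtx(path: str | Path) -> np.ndarray:
    from scipy.io import mmread

    return np.asarray(mmread(str(path)).todense(), dtype=float)
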