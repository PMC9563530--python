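"""Protein–protein interaction network and boolean feature propagation.

The network is an undirected simple graph over genes.  Propagation uses
the self-loop-augmented adjacency Ã = A + I_N, and — because the GO
feature vectors are strictly 0/1 — replaces the sums of the ordinary
matrix product with logical ORs: entry (i, j) of the propagated matrix
is 1 iff any neighbour of i (including i itself through the self loop)
has feature j set.  Over binary inputs this equals sign(Ã·H) under
ordinary integer arithmetic, which is how it is computed here, sparsely;
N×N dense storage is never materialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected gene graph with sparse binary adjacency."""

    gene_order: list[str]
    adjacency: sp.csr_matrix  # A: symmetric, zero diagonal, int8

    @property
    def n(self) -> int:
        return len(self.gene_order)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def adjacency_with_self_loops(self) -> sp.csr_matrix:
        return add_self_loops(self)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_order)}

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]


def load_ppi(path: str | Path, drop_isolated: bool = True) -> PPINetwork:
    """Load an undirected edge list (2 or 3 tab-separated columns).

    Duplicate and reversed edges merge; self edges are dropped; a third
    column, if present, is a weight and is binarized (the propagation
    operator is defined on 0/1 adjacency only).  Node order is
    lexicographic.  ``drop_isolated`` removes degree-0 nodes, mirroring
    the usual cleaning of interaction databases.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    saw_weight = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}"
                )
            a, b = cols[0].strip(), cols[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: blank node ID")
            if len(cols) == 3:
                saw_weight = True
                if float(cols[2]) == 0.0:
                    continue
            nodes.update((a, b))
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))
    if saw_weight:
        logger.info("edge weights present in %s; binarized on load", path)
    if drop_isolated:
        connected = {g for e in edges for g in e}
        nodes &= connected
    if not nodes:
        raise ValueError(f"{path}: graph is empty after cleaning")
    gene_order = sorted(nodes)
    idx = {g: i for i, g in enumerate(gene_order)}
    if edges:
        ij = np.array([(idx[a], idx[b]) for a, b in edges if a in idx and b in idx])
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.ones(len(rows), dtype=np.int8)
    else:
        rows = cols = np.array([], dtype=int)
        data = np.array([], dtype=np.int8)
    A = sp.csr_matrix((data, (rows, cols)), shape=(len(gene_order),) * 2)
    return PPINetwork(gene_order, A)


def add_self_loops(network: PPINetwork) -> sp.csr_matrix:
    """Ã = A + I_N: diagonal all ones, off-diagonal identical to A."""
    n = network.n
    return (network.adjacency + sp.identity(n, dtype=np.int8, format="csr")).tocsr()


def _check_binary(M, name: str) -> None:
    data = M.data if sp.issparse(M) else np.asarray(M)
    if data.size and not np.isin(data, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")


def or_propagate(A: sp.spmatrix | np.ndarray, H: sp.spmatrix | np.ndarray):
    """Boolean matrix product: C_ij = 1 iff Σ_k A_ik·H_kj ≥ 1.

    Both operands must be strictly binary.  Returns sparse CSR when
    either input is sparse, else a dense int8 array.
    """
    _check_binary(A, "A")
    _check_binary(H, "H")
    if A.shape[1] != H.shape[0]:
        raise ValueError(f"inner dimensions disagree: {A.shape} x {H.shape}")
    sparse_out = sp.issparse(A) or sp.issparse(H)
    As = sp.csr_matrix(A, dtype=np.int64)
    Hs = sp.csr_matrix(H, dtype=np.int64)
    C = As @ Hs
    C.data = (C.data >= 1).astype(np.int8)
    C.eliminate_zeros()
    C = C.astype(np.int8)
    return C.tocsr() if sparse_out else np.asarray(C.todense())


def write_ppi(network: PPINetwork, prefix: str | Path) -> None:
    """Adjacency as MTX plus node order as TSV."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), network.adjacency.tocoo(), field="integer")
    prefix.with_name(prefix.name + ".nodes.tsv").write_text(
        "".join(f"{g}\n" for g in network.gene_order)
    )
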