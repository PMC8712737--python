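"""Random walk with restart, SVD embedding, and cosine similarity.

The random walk with restart (RWR) iterates ``p <- (1-r) T p + r p0`` on the
column-stochastic commixture matrix T; its fixed point
``p = r (I - (1-r) T)^{-1} p0`` measures network proximity to the seed
distribution.  Stacking the fixed points for unit seeds on every node gives
the proximity matrix, whose truncated SVD yields a shared low-dimensional
space: node i's SOURCE vector is row i of U_d S_d^{1/2} and its TARGET
vector is row i of V_d S_d^{1/2}, so dot(source_i, target_j) reconstructs
proximity P_ij.  Molecule-to-pathway relevance is the cosine between the
molecule's source vector and the pathway's target vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from pathmux.multiplex import CommixtureMatrix

logger = logging.getLogger(__name__)

#: below this size the linear system is solved directly instead of iterated
DENSE_SOLVE_MAX_N = 2000


class ConvergenceError(RuntimeError):
    """RWR power iteration failed to reach tolerance within max_iter."""


@dataclass
class ProximityMatrix:
    """Row i = stationary RWR distribution with unit seed on node i."""

    matrix: np.ndarray
    node_index: dict

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EmbeddingSpace:
    """Low-dimensional source/target vectors from truncated SVD.

    ``source_vectors[i]`` and ``target_vectors[i]`` are the length-d row and
    column factors of node i (scaled by the square root of the singular
    values, balancing norms between the two roles); the node order follows
    ``node_index``.
    """

    dimension: int
    source_vectors: np.ndarray
    target_vectors: np.ndarray
    singular_values: np.ndarray
    node_index: dict

    def source_vector(self, node: str) -> np.ndarray:
        return self.source_vectors[self.node_index[node]]

    def target_vector(self, node: str) -> np.ndarray:
        return self.target_vectors[self.node_index[node]]

    def __contains__(self, node: str) -> bool:
        return node in self.node_index

    def to_tsv(self, path) -> None:
        nodes = sorted(self.node_index, key=self.node_index.get)
        with open(path, "w") as fh:
            header = "node\trole\t" + "\t".join(
                f"v{k+1}" for k in range(self.dimension))
            fh.write(header + "\n")
            for role, vecs in (("source", self.source_vectors),
                               ("target", self.target_vectors)):
                for node in nodes:
                    v = vecs[self.node_index[node]]
                    fh.write(node + "\t" + role + "\t"
                             + "\t".join(f"{x:.10g}" for x in v) + "\n")


def _check_seed(seed: np.ndarray, n: int) -> np.ndarray:
    seed = np.asarray(seed, dtype=float).ravel()
    if seed.shape[0] != n:
        raise ValueError(f"seed length {seed.shape[0]} != matrix size {n}")
    if np.any(seed < 0) or abs(seed.sum() - 1.0) > 1e-8:
        raise ValueError("seed must be a probability vector summing to 1")
    return seed


def rwr(T: CommixtureMatrix, seed, r: float = 0.7, tol: float = 1e-10,
        max_iter: int = 10_000, method: str = "auto") -> np.ndarray:
    """Stationary RWR distribution for one seed distribution.

    method='auto' uses a direct dense solve of (I - (1-r)T) p = r p0 for
    n <= 2000 and power iteration above; 'iterative' and 'direct' force one
    path.  Iteration uses the L1 residual ||p - ((1-r)Tp + r p0)||_1 < tol
    and raises ConvergenceError instead of silently truncating.
    """
    if not 0 < r < 1:
        raise ValueError(f"restart probability must be in (0,1), got {r}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = T.matrix
    n = M.shape[0]
    p0 = _check_seed(seed, n)
    if method not in ("auto", "iterative", "direct"):
        raise ValueError(f"unknown method {method!r}")
    if method == "direct" or (method == "auto" and n <= DENSE_SOLVE_MAX_N):
        A = np.eye(n) - (1.0 - r) * M.toarray()
        p = np.linalg.solve(A, r * p0)
    else:
        p = p0.copy()
        for it in range(max_iter):
            p_next = (1.0 - r) * (M @ p) + r * p0
            if np.abs(p_next - p).sum() < tol:
                logger.debug("rwr converged in %d iterations", it + 1)
                p = p_next
                break
            p = p_next
        else:
            raise ConvergenceError(
                f"RWR did not converge within {max_iter} iterations "
                f"(tol={tol})")
    p = np.maximum(p, 0.0)
    s = p.sum()
    if abs(s - 1.0) > 1e-8:
        raise AssertionError(f"RWR result sums to {s}, expected 1")
    return p


def rwr_all(T: CommixtureMatrix, r: float = 0.7, tol: float = 1e-10,
            max_iter: int = 10_000, method: str = "auto") -> ProximityMatrix:
    """Proximity matrix: one RWR per node, rows indexed like the node index.

    For the direct path all fixed points solve one factorized linear system:
    P^T = r (I - (1-r)T)^{-1}.
    """
    M = T.matrix
    n = M.shape[0]
    if method == "direct" or (method == "auto" and n <= DENSE_SOLVE_MAX_N):
        A = np.eye(n) - (1.0 - r) * M.toarray()
        P = r * np.linalg.inv(A).T
        P = np.maximum(P, 0.0)
    else:
        P = np.empty((n, n))
        for i in range(n):
            seed = np.zeros(n)
            seed[i] = 1.0
            P[i] = rwr(T, seed, r=r, tol=tol, max_iter=max_iter, method=method)
    rowsums = P.sum(axis=1)
    if np.abs(rowsums - 1.0).max() > 1e-8:
        raise AssertionError("proximity rows do not sum to 1")
    return ProximityMatrix(matrix=P, node_index=dict(T.node_index))


def svd_embed(P: ProximityMatrix, d: int | None = None, *,
              symmetrize: bool = False, log1p: bool = False) -> EmbeddingSpace:
    """Truncated SVD of the proximity matrix into source/target vectors.

    d defaults to min(128, n-1).  The sign of each singular-vector pair is
    fixed by making the largest-magnitude component of the left vector
    positive, so embeddings are reproducible across runs and platforms.
    ``symmetrize`` replaces P by (P + P^T)/2 for role-free vectors; ``log1p``
    embeds log(1 + P) instead of the raw proximities.
    """
    A = P.matrix
    n = A.shape[0]
    if d is None:
        d = max(1, min(128, n - 1)) if n > 1 else 1
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension {d} must be in [1, {n}]")
    if symmetrize:
        A = 0.5 * (A + A.T)
    if log1p:
        A = np.log1p(A)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    U, s, Vt = U[:, :d], s[:d], Vt[:d]
    # deterministic sign convention
    for k in range(d):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    scale = np.sqrt(s)
    return EmbeddingSpace(
        dimension=d,
        source_vectors=U * scale,
        target_vectors=Vt.T * scale,
        singular_values=s,
        node_index=dict(P.node_index),
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; defined as 0 when either vector has zero norm."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        logger.warning("cosine of a zero vector defined as 0")
        return 0.0
    return float(np.dot(u, v) / (nu * nv))
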