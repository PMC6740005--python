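"""Node embeddings of the bipartite association network.

The primary embedder is SDNE (:mod:`nemii.sdne`); two deterministic
spectral baselines are provided for comparison:

* Laplacian Eigenmaps — generalized eigenvectors of ``L v = λ D v``
  with the smallest nonzero eigenvalues, which place strongly connected
  nodes nearby.
* HOPE — truncated SVD of the Katz similarity
  ``S = (I - βₖ G)⁻¹ βₖ G``, preserving high-order proximities; each
  node's source and target factors are concatenated.

``dimension_sweep`` re-embeds one network at several dimensions for the
flat-performance-versus-dimension diagnostic.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .data_model import BipartiteAdjacency
from .sdne import (  # noqa: F401  (re-exported: one embedding surface)
    EmbeddingMatrix,
    SDNEConfig,
    TrainingReport,
    build_penalty_matrix,
    first_order_loss,
    reg_loss,
    second_order_loss,
    total_loss,
    train_sdne,
)

__all__ = [
    "EmbeddingMatrix",
    "SDNEConfig",
    "TrainingReport",
    "build_penalty_matrix",
    "first_order_loss",
    "second_order_loss",
    "reg_loss",
    "total_loss",
    "train_sdne",
    "embed_laplacian",
    "embed_hope",
    "dimension_sweep",
]


def _as_matrix(G) -> tuple[np.ndarray, list[str]]:
    if isinstance(G, BipartiteAdjacency):
        return np.asarray(G.G, dtype=float), G.node_ids
    A = np.asarray(G, dtype=float)
    return A, [str(i) for i in range(A.shape[0])]


def _components(A: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(A != 0, directed=False)
    return [np.nonzero(labels == c)[0] for c in range(labels.max() + 1)]


def embed_laplacian(G, d: int) -> EmbeddingMatrix:
    """Laplacian Eigenmaps embedding of width ``d``.

    Solves ``L v = λ D v`` (``L = D - G``) and keeps the ``d``
    eigenvectors with smallest nonzero eigenvalues, normalised so
    ``Yᵀ D Y = I``.  A disconnected graph is embedded per component
    (isolated nodes land at the origin) with a warning.
    """
    A, node_ids = _as_matrix(G)
    N = A.shape[0]
    if N < d + 1:
        raise ValueError(f"need >= d+1 = {d + 1} nodes, got {N}")
    comps = _components(A)
    if len(comps) > 1:
        warnings.warn(
            f"graph has {len(comps)} connected components; embedding per component",
            stacklevel=2,
        )
    # pool each component's nonzero-eigenvalue spectrum, zero-padded to N
    pooled: list[tuple[float, np.ndarray]] = []
    for idx in comps:
        if len(idx) < 2:
            continue  # isolated node: no nontrivial spectrum
        sub = A[np.ix_(idx, idx)]
        D = np.diag(sub.sum(axis=1))
        L = D - sub
        vals, vecs = scipy.linalg.eigh(L, D)
        for lam, v in zip(vals, vecs.T):
            if lam > 1e-9:  # skip the trivial constant eigenvector
                full = np.zeros(N)
                full[idx] = v
                pooled.append((float(lam), full))
    pooled.sort(key=lambda t: t[0])
    if len(pooled) < d:
        warnings.warn(
            f"only {len(pooled)} nonzero eigenpairs available for d={d}; zero-padding",
            stacklevel=2,
        )
    Y = np.zeros((N, d))
    for k, (_, v) in enumerate(pooled[:d]):
        Y[:, k] = v
    return EmbeddingMatrix(Y, node_ids)


def katz_similarity(A: np.ndarray, beta_k: float) -> np.ndarray:
    """Katz proximity ``S = (I - βₖ A)⁻¹ βₖ A``; requires βₖ < 1/ρ(A)."""
    A = np.asarray(A, dtype=float)
    rho = max(abs(np.linalg.eigvals(A)))
    if rho > 0 and beta_k >= 1.0 / rho:
        raise ValueError(
            f"Katz decay {beta_k} >= 1/spectral radius ({1.0 / rho:.4g}); series diverges"
        )
    N = A.shape[0]
    return np.linalg.solve(np.eye(N) - beta_k * A, beta_k * A)


def embed_hope(G, d: int, beta_k: float | None = None) -> EmbeddingMatrix:
    """HOPE embedding: truncated SVD of the Katz similarity matrix.

    The top ``d/2`` singular triples give source factors ``U√Σ`` and
    target factors ``V√Σ``, concatenated per node to width ``d``
    (``d`` must be even).  ``beta_k`` defaults to half the divergence
    threshold ``1/ρ(G)``.
    """
    if d % 2 != 0:
        raise ValueError("HOPE width d must be even (d/2 source + d/2 target)")
    A, node_ids = _as_matrix(G)
    if beta_k is None:
        rho = max(abs(np.linalg.eigvals(A)))
        beta_k = 0.5 / rho if rho > 0 else 0.5
    S = katz_similarity(A, beta_k)
    U, sig, Vt = np.linalg.svd(S)
    k = d // 2
    root = np.sqrt(sig[:k])
    U_s = U[:, :k] * root
    U_t = Vt[:k].T * root
    return EmbeddingMatrix(np.hstack([U_s, U_t]), node_ids)


def dimension_sweep(
    G,
    method: str = "sdne",
    dims: list[int] = (32, 64, 128, 256, 512),
    seed: int = 0,
    **kwargs,
) -> dict[int, EmbeddingMatrix]:
    """Embed one network at several dimensions with a shared seed base."""
    out: dict[int, EmbeddingMatrix] = {}
    for dim in dims:
        if method == "sdne":
            cfg = SDNEConfig(d=dim, seed=seed, **kwargs)
            out[dim], _ = train_sdne(G, cfg)
        elif method == "le":
            out[dim] = embed_laplacian(G, dim)
        elif method == "hope":
            out[dim] = embed_hope(G, dim, **kwargs)
        else:
            raise ValueError(f"unknown embedding method {method!r}")
    return out
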