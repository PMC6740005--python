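"""Structural Deep Network Embedding (SDNE) for the bipartite network.

SDNE is a semi-supervised deep autoencoder over the rows of the
adjacency matrix: node ``i`` enters as ``x_i = G_{i,:}``, is encoded
through ``K`` sigmoid layers into a low-dimensional vector ``y_i`` and
decoded back into a reconstruction ``x̂_i``.  Training minimises

    L_mix = L_2nd + alpha * L_1st + nu * L_reg

where the second-order term ``L_2nd = ||(X̂ - X) ⊙ B||_F²`` forces nodes
with similar neighbourhoods to similar codes (``B`` up-weights observed
edges by ``beta > 1`` so the sparse 1-cells are not drowned out by
zeros), the first-order term ``L_1st = Σ_ij G_ij ||y_i - y_j||²``
(ordered pairs, so each undirected edge counts twice) pulls directly
linked nodes together, and ``L_reg`` is an L2 penalty on the weight
matrices.  Optimisation is full-batch Adam with manual gradients; the
network is small enough (hundreds of nodes) that this is both fast and
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import BipartiteAdjacency


@dataclass
class SDNEConfig:
    """Hyperparameters of the SDNE autoencoder.

    ``hidden_layers`` are encoder widths ending in the embedding
    dimension ``d``; the decoder mirrors them.  ``alpha`` weighs the
    first-order loss, ``beta`` (> 1) is the reconstruction penalty on
    observed edges, ``nu`` the L2 regularisation weight.
    """

    d: int = 128
    hidden_layers: list[int] | None = None
    alpha: float = 0.05
    beta: float = 5.0
    nu: float = 1e-4
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.beta <= 1:
            raise ValueError("beta must be > 1")
        if self.hidden_layers is None:
            # one intermediate layer; widened for large d so widths still decrease
            self.hidden_layers = [max(256, 2 * self.d), self.d]
        if self.hidden_layers[-1] != self.d:
            raise ValueError("last hidden layer width must equal d")
        if any(a < b for a, b in zip(self.hidden_layers, self.hidden_layers[1:])):
            raise ValueError("hidden layer widths must decrease toward d")

    @classmethod
    def small_network(cls, d: int = 16, seed: int = 0, **overrides) -> "SDNEConfig":
        """Profile for networks of a few hundred nodes or less.

        Small sparse graphs need a narrower bottleneck, a stronger
        first-order pull and a larger step size to converge than the
        paper-scale defaults.
        """
        kw = dict(
            d=d,
            hidden_layers=[4 * d, d],
            alpha=10.0,
            learning_rate=1e-2,
            epochs=800,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class EmbeddingMatrix:
    """(m+n) x d node embeddings, rows ordered as the bipartite adjacency."""

    NE: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.NE = np.asarray(self.NE, dtype=float)
        if self.NE.shape[0] != len(self.node_ids):
            raise ValueError("embedding row count does not match node count")
        if not np.isfinite(self.NE).all():
            raise ValueError("embedding contains NaN/Inf")

    @property
    def d(self) -> int:
        return self.NE.shape[1]

    def to_tsv(self, path) -> None:
        from .data_model import write_matrix_tsv

        cols = [f"e{k}" for k in range(self.d)]
        write_matrix_tsv(self.NE, self.node_ids, cols, path)


@dataclass
class TrainingReport:
    """Per-epoch loss trajectory of one SDNE fit."""

    seed: int
    first_order: list[float] = field(default_factory=list)
    second_order: list[float] = field(default_factory=list)
    regularization: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.total[-1]


# ---------------------------------------------------------------------------
# Loss components (also used standalone in tests / diagnostics)


def build_penalty_matrix(G: np.ndarray, beta: float) -> np.ndarray:
    """B_ij = beta where G_ij != 0, else 1 (requires beta > 1)."""
    if beta <= 1:
        raise ValueError("beta must be > 1")
    G = np.asarray(G)
    return np.where(G != 0, float(beta), 1.0)

def first_order_loss(G: np.ndarray, Y: np.ndarray) -> float:
    """Sum over ordered pairs of G_ij * ||y_i - y_j||^2."""
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape[0] != G.shape[1] or G.shape[0] != Y.shape[0]:
        raise ValueError("G must be square with one row per embedding row")
    Gs = 0.5 * (G + G.T)  # ||y_i - y_j||² is symmetric in (i, j)
    lap = np.diag(Gs.sum(axis=1)) - Gs
    # Σ_ij G_ij ||y_i - y_j||² = 2 tr(Yᵀ L Y)
    return float(2.0 * np.sum(lap * (Y @ Y.T)))

def second_order_loss(X: np.ndarray, X_hat: np.ndarray, B: np.ndarray) -> float:
    """||(X_hat - X) ⊙ B||_F^2."""
    X, X_hat, B = (np.asarray(a, dtype=float) for a in (X, X_hat, B))
    if not (X.shape == X_hat.shape == B.shape):
        raise ValueError("X, X_hat and B must share a shape")
    return float(np.sum(((X_hat - X) * B) ** 2))

def reg_loss(weights: list[np.ndarray]) -> float:
    """0.5 * sum of squared Frobenius norms over all weight matrices."""
    return 0.5 * float(sum(np.sum(W**2) for W in weights))

def total_loss(
    G: np.ndarray,
    X: np.ndarray,
    X_hat: np.ndarray,
    Y: np.ndarray,
    weights: list[np.ndarray],
    cfg: SDNEConfig,
) -> float:
    """L_mix = L_2nd + alpha * L_1st + nu * L_reg."""
    B = build_penalty_matrix(G, cfg.beta)
    return (
        second_order_loss(X, X_hat, B)
        + cfg.alpha * first_order_loss(G, Y)
        + cfg.nu * reg_loss(weights)
    )


# ---------------------------------------------------------------------------
# Training

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Autoencoder:
    """Mirrored sigmoid MLP with Glorot-uniform init."""

    def __init__(self, n_input: int, hidden: list[int], rng: np.random.Generator):
        widths = [n_input] + list(hidden) + list(reversed(hidden[:-1])) + [n_input]
        self.widths = widths
        self.n_encoder = len(hidden)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths, widths[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        for W, b in zip(self.W, self.b):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def backward(
        self,
        acts: list[np.ndarray],
        d_out: np.ndarray,
        d_bottleneck: np.ndarray,
        nu: float,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients w.r.t. weights/biases given dL/dX_hat and the extra
        dL/dY injected at the bottleneck (first-order term)."""
        n_layers = len(self.W)
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        delta = d_out * acts[-1] * (1.0 - acts[-1])  # sigmoid derivative
        for k in range(n_layers - 1, -1, -1):
            gW[k] = acts[k].T @ delta + nu * self.W[k]
            gb[k] = delta.sum(axis=0)
            if k > 0:
                d_prev = delta @ self.W[k].T
                if k == self.n_encoder:  # acts[k] is the bottleneck Y
                    d_prev = d_prev + d_bottleneck
                delta = d_prev * acts[k] * (1.0 - acts[k])
        return gW, gb


def train_sdne(
    G: BipartiteAdjacency | np.ndarray, cfg: SDNEConfig
) -> tuple[EmbeddingMatrix, TrainingReport]:
    """Fit the SDNE autoencoder on a bipartite adjacency.

    Returns the bottleneck activations as the (m+n) x d embedding matrix
    together with the per-epoch loss trajectory.  Deterministic for a
    fixed ``cfg.seed``.  Degree-zero nodes (possible after fold-wise
    edge removal) enter as all-zero rows and pass through unmodified.
    """
    if isinstance(G, BipartiteAdjacency):
        node_ids = G.node_ids
        A = np.asarray(G.G, dtype=float)
    else:
        A = np.asarray(G, dtype=float)
        node_ids = [str(i) for i in range(A.shape[0])]
    N = A.shape[0]
    if N == 0:
        raise ValueError("empty adjacency")
    if cfg.d >= N:
        warnings.warn(f"embedding dimension {cfg.d} >= node count {N}", stacklevel=2)

    X = A
    B = build_penalty_matrix(A, cfg.beta)
    B2 = B * B
    deg = A.sum(axis=1)
    lap = np.diag(deg) - A

    rng = np.random.default_rng(cfg.seed)
    net = _Autoencoder(N, list(cfg.hidden_layers), rng)
    report = TrainingReport(seed=cfg.seed)

    # Adam state
    lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    mW = [np.zeros_like(W) for W in net.W]
    vW = [np.zeros_like(W) for W in net.W]
    mb = [np.zeros_like(b) for b in net.b]
    vb = [np.zeros_like(b) for b in net.b]

    for epoch in range(cfg.epochs + 1):
        acts = net.forward(X)
        Y = acts[net.n_encoder]
        X_hat = acts[-1]

        l2nd = second_order_loss(X, X_hat, B)
        l1st = first_order_loss(A, Y)
        lreg = reg_loss(net.W)
        lmix = l2nd + cfg.alpha * l1st + cfg.nu * lreg
        if not np.isfinite(lmix):
            raise FloatingPointError(
                f"SDNE loss diverged at epoch {epoch} (L_mix={lmix})"
            )
        report.second_order.append(l2nd)
        report.first_order.append(l1st)
        report.regularization.append(lreg)
        report.total.append(lmix)
        if epoch == cfg.epochs:
            break

        d_out = 2.0 * (X_hat - X) * B2
        d_bottleneck = cfg.alpha * 4.0 * (lap @ Y)
        gW, gb = net.backward(acts, d_out, d_bottleneck, cfg.nu)

        t = epoch + 1
        for k in range(len(net.W)):
            mW[k] = b1 * mW[k] + (1 - b1) * gW[k]
            vW[k] = b2 * vW[k] + (1 - b2) * gW[k] ** 2
            net.W[k] -= lr * (mW[k] / (1 - b1**t)) / (np.sqrt(vW[k] / (1 - b2**t)) + eps)
            mb[k] = b1 * mb[k] + (1 - b1) * gb[k]
            vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
            net.b[k] -= lr * (mb[k] / (1 - b1**t)) / (np.sqrt(vb[k] / (1 - b2**t)) + eps)

    acts = net.forward(X)
    return EmbeddingMatrix(acts[net.n_encoder], node_ids), report
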