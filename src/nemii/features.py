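"""Per-pair feature assembly.

A miRNA-disease pair (i, j) is described by up to three feature blocks,
concatenated in a fixed order:

1. the miRNA's family-membership row ``Z_i,:`` (width t),
2. the disease's semantic-similarity row ``SS_j,:`` (width n),
3. the pair's node embeddings ``NE_i,:`` and ``NE_{m+j},:`` (width 2d).

The five combination schemes toggle these blocks: (1) embedding only,
(2) family + disease similarity, (3) embedding + family,
(4) embedding + disease similarity, (5) all three.

Training sets follow the semi-supervised protocol: positives are the
1-cells of the training association matrix; every other pair is an
unlabeled cell treated as negative (no subsampling), even though
held-out positives hide among them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

COMBINATIONS = {
    1: dict(use_embedding=True, use_family=False, use_disease_sim=False),
    2: dict(use_embedding=False, use_family=True, use_disease_sim=True),
    3: dict(use_embedding=True, use_family=True, use_disease_sim=False),
    4: dict(use_embedding=True, use_family=False, use_disease_sim=True),
    5: dict(use_embedding=True, use_family=True, use_disease_sim=True),
}


@dataclass
class FeatureConfig:
    """Which feature blocks enter the pair vector."""

    use_family: bool = True
    use_disease_sim: bool = True
    use_embedding: bool = True

    def __post_init__(self) -> None:
        if not (self.use_family or self.use_disease_sim or self.use_embedding):
            raise ValueError("at least one feature block must be enabled")

    @classmethod
    def from_combination(cls, label: int) -> "FeatureConfig":
        if label not in COMBINATIONS:
            raise ValueError(f"combination label must be 1..5, got {label}")
        return cls(**COMBINATIONS[label])

    def width(self, t: int, n: int, d: int) -> int:
        return (
            (t if self.use_family else 0)
            + (n if self.use_disease_sim else 0)
            + (2 * d if self.use_embedding else 0)
        )

    def block_offsets(self, t: int, n: int, d: int) -> dict[str, tuple[int, int]]:
        """Documented [start, stop) offsets of each enabled block."""
        out: dict[str, tuple[int, int]] = {}
        pos = 0
        if self.use_family:
            out["family"] = (pos, pos + t)
            pos += t
        if self.use_disease_sim:
            out["disease_sim"] = (pos, pos + n)
            pos += n
        if self.use_embedding:
            out["mirna_embedding"] = (pos, pos + d)
            out["disease_embedding"] = (pos + d, pos + 2 * d)
        return out


@dataclass
class PairFeatureMatrix:
    """Feature rows for (miRNA, disease) pairs with binary labels."""

    X: np.ndarray
    y: np.ndarray
    pairs: np.ndarray  # (n_rows, 2) int array of (miRNA index, disease index)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.pairs)):
            raise ValueError("rows, labels and pair index must align")


def pair_vector(
    i: int,
    j: int,
    Z: np.ndarray,
    SS: np.ndarray,
    NE: np.ndarray | None,
    cfg: FeatureConfig,
) -> np.ndarray:
    """Feature vector of pair (miRNA i, disease j): [Z_i | SS_j | NE_i | NE_{m+j}]."""
    m = Z.shape[0]
    if not (0 <= i < m) or not (0 <= j < SS.shape[0]):
        raise IndexError(f"pair index ({i}, {j}) out of range")
    blocks = []
    if cfg.use_family:
        blocks.append(Z[i])
    if cfg.use_disease_sim:
        blocks.append(SS[j])
    if cfg.use_embedding:
        if NE is None:
            raise ValueError("embedding block enabled but no embedding given")
        blocks.append(NE[i])
        blocks.append(NE[m + j])
    return np.concatenate([np.asarray(b, dtype=float) for b in blocks])


def build_training_set(
    A_train: np.ndarray,
    Z: np.ndarray,
    SS: np.ndarray,
    NE: np.ndarray | None,
    cfg: FeatureConfig,
) -> PairFeatureMatrix:
    """All m*n pairs in row-major order; label 1 iff a training association.

    Built blockwise (tiled family/similarity rows plus embedding rows
    broadcast over the grid) — equivalent to calling ``pair_vector`` per
    pair but vectorised.
    """
    A_train = np.asarray(A_train)
    m, n = A_train.shape
    if A_train.sum() == 0:
        raise ValueError("training set has no positive pairs")
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    blocks = []
    if cfg.use_family:
        blocks.append(np.asarray(Z, dtype=float)[ii])
    if cfg.use_disease_sim:
        blocks.append(np.asarray(SS, dtype=float)[jj])
    if cfg.use_embedding:
        if NE is None:
            raise ValueError("embedding block enabled but no embedding given")
        NE = np.asarray(NE, dtype=float)
        blocks.append(NE[ii])
        blocks.append(NE[m + jj])
    X = np.hstack(blocks)
    y = A_train[ii, jj].astype(np.int8)
    return PairFeatureMatrix(X, y, np.column_stack([ii, jj]))
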