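"""Synthetic miRNA-disease data with planted block structure.

Emulates the three real inputs — association edge list, family table,
disease hierarchy — so every pipeline stage is testable without
downloads:

* miRNAs and diseases are partitioned into matched blocks; a pair
  within a matched block is associated with probability ``p_in``,
  otherwise ``p_out`` (a bipartite stochastic block model, standing in
  for the community structure of the real association network);
* each miRNA joins its block's family with probability
  ``family_purity``, otherwise a random family (families correlate with
  network blocks the way miRBase families track shared targets);
* each disease receives a MeSH-style tree number rooted at its block's
  code, so same-block diseases share ancestors and get high semantic
  similarity while cross-block ancestries are disjoint.

Defaults (m=60, n=40, 6 blocks, p_in=0.3, p_out=0.01) give a strongly
structured network that is large enough for stable AUC yet embeds in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_model import (
    AssociationDataset,
    DiseaseOntologyInput,
    FamilyTable,
)


@dataclass
class SyntheticConfig:
    m: int = 60
    n: int = 40
    t: int = 6
    n_blocks: int = 6
    p_in: float = 0.3
    p_out: float = 0.01
    family_purity: float = 0.8
    dag_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_blocks < 1 or self.m < self.n_blocks or self.n < self.n_blocks:
            raise ValueError("need at least one miRNA and disease per block")
        if self.t < self.n_blocks:
            raise ValueError("need at least one family per block")


@dataclass
class GroundTruth:
    """Planted block assignment (remainders go to the last block)."""

    mirna_block: np.ndarray
    disease_block: np.ndarray


def _block_assign(count: int, n_blocks: int) -> np.ndarray:
    per = count // n_blocks
    blocks = np.repeat(np.arange(n_blocks), per)
    return np.concatenate([blocks, np.full(count - len(blocks), n_blocks - 1)])


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[AssociationDataset, FamilyTable, DiseaseOntologyInput, GroundTruth]:
    """Generate the three input structures plus the planted blocks."""
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(cfg.m)]
    disease_ids = [f"dis-{j:04d}" for j in range(cfg.n)]
    mb = _block_assign(cfg.m, cfg.n_blocks)
    db = _block_assign(cfg.n, cfg.n_blocks)

    same = mb[:, None] == db[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.m, cfg.n)) < prob).astype(np.int8)
    # every node keeps >= 1 association so filtering/embedding see no empty rows
    for i in np.nonzero(A.sum(axis=1) == 0)[0]:
        A[i, rng.choice(np.nonzero(db == mb[i])[0])] = 1
    for j in np.nonzero(A.sum(axis=0) == 0)[0]:
        A[rng.choice(np.nonzero(mb == db[j])[0]), j] = 1

    family_ids = [f"fam-{k:03d}" for k in range(cfg.t)]
    Z = np.zeros((cfg.m, cfg.t), dtype=np.int8)
    for i in range(cfg.m):
        if rng.random() < cfg.family_purity:
            fam = mb[i] % cfg.t
        else:
            fam = rng.integers(cfg.t)
        Z[i, fam] = 1

    # MeSH-style tree numbers: block root code + random path, depth <= dag_depth
    tree_numbers: dict[str, list[str]] = {}
    for j, did in enumerate(disease_ids):
        depth = int(rng.integers(1, cfg.dag_depth + 1))
        segs = [f"B{db[j]:02d}"] + [
            f"{int(rng.integers(1, 4)):03d}" for _ in range(depth - 1)
        ]
        tree_numbers[did] = [".".join(segs)]
    onto = DiseaseOntologyInput(tree_numbers=tree_numbers)

    ds = AssociationDataset(mirna_ids, disease_ids, A)
    fam = FamilyTable(mirna_ids, family_ids, Z)
    return ds, fam, onto, GroundTruth(mb, db)


def planted_signal_check(ds: AssociationDataset, truth: GroundTruth) -> float:
    """AUC of the block-membership oracle scorer against the realised A.

    Scores a pair 1 iff miRNA and disease share a block; the resulting
    AUC is the separability ceiling downstream pipeline assertions can
    reach on this dataset.
    """
    oracle = (
        truth.mirna_block[:, None] == truth.disease_block[None, :]
    ).astype(float)
    labels = ds.A.ravel()
    if labels.min() == labels.max():
        raise ValueError("association matrix has a single class")
    return float(roc_auc_score(labels, oracle.ravel()))


def write_inputs(
    ds: AssociationDataset,
    fam: FamilyTable,
    onto: DiseaseOntologyInput,
    outdir,
) -> dict[str, str]:
    """Write the three input files in the exact TSV formats the loaders read."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "families": outdir / "families.tsv",
        "ontology": outdir / "ontology.tsv",
    }
    with open(paths["associations"], "w") as fh:
        fh.write("miRNA\tdisease\n")
        for mirna, disease in ds.pairs():
            fh.write(f"{mirna}\t{disease}\n")
    with open(paths["families"], "w") as fh:
        fh.write("miRNA\tfamily\n")
        ii, kk = np.nonzero(fam.Z)
        for i, k in zip(ii, kk):
            fh.write(f"{fam.mirna_ids[i]}\t{fam.family_ids[k]}\n")
    with open(paths["ontology"], "w") as fh:
        fh.write("disease\ttree_number\n")
        for did, codes in onto.tree_numbers.items():
            for code in codes:
                fh.write(f"{did}\t{code}\n")
    return {k: str(v) for k, v in paths.items()}
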