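"""Semi-supervised cross-validation protocol, metrics, and experiments.

The evaluation protocol for positive-unlabeled link prediction:

1. Known associations (1-cells of ``A``) are randomly and equally
   divided into five subsets.
2. For each fold, the held-out fifth is zeroed out of the training
   matrix; the bipartite network is rebuilt and the embedder retrained
   on the reduced network, so no information about held-out links leaks
   through the embedding.
3. The classifier trains on all m*n pairs of the reduced matrix
   (1-cells positive, everything else negative) and scores every pair
   that is 0 in the training matrix; a scored pair is a true positive
   iff it was held out.
4. Fold scores are pooled per run; runs (default 10) are aggregated as
   mean ± std.

Metrics: AUPR (step-wise average precision — no optimistic
interpolation on the heavy imbalance), AUC (rank statistic with tie
averaging), and the five thresholded metrics F1/ACC/REC/SPEC/PRE at a
configurable score threshold (default 0.5).

Experiments: feature-combination comparison, association-matrix
sparsification, removed-association recovery, per-disease metrics, and
full-data candidate ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .classifier import RFConfig, oob_scores, train_rf
from .data_model import AssociationDataset, build_adjacency
from .embedding import SDNEConfig, embed_hope, embed_laplacian, train_sdne
from .features import FeatureConfig, build_training_set


@dataclass
class PipelineConfig:
    """Everything one fold needs: embedder, features, classifier, threshold."""

    sdne: SDNEConfig = field(default_factory=SDNEConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    embedding_method: str = "sdne"  # sdne | le | hope
    threshold: float = 0.5


@dataclass
class FoldPlan:
    """One fold of one run: held-out positives and the reduced matrix."""

    run: int
    fold: int
    held_out: np.ndarray  # (k, 2) pair indices
    A_train: np.ndarray
    seed: int


@dataclass
class MetricSet:
    AUPR: float
    AUC: float
    F1: float
    ACC: float
    REC: float
    SPEC: float
    PRE: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("AUPR", "AUC", "F1", "ACC", "REC", "SPEC", "PRE")
        }


@dataclass
class ExperimentResult:
    label: str
    per_run: list[MetricSet]

    def mean(self) -> dict[str, float]:
        return {
            k: float(np.mean([r.as_dict()[k] for r in self.per_run]))
            for k in self.per_run[0].as_dict()
        }

    def std(self) -> dict[str, float]:
        return {
            k: float(np.std([r.as_dict()[k] for r in self.per_run]))
            for k in self.per_run[0].as_dict()
        }

    def summary(self) -> dict[str, str]:
        mu, sd = self.mean(), self.std()
        return {k: f"{mu[k]:.4f} ± {sd[k]:.4f}" for k in mu}


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """All seven metrics from a pooled score/label set.

    AUC is the rank statistic (ties averaged); AUPR the step-wise
    average-precision estimator.  When no pair is called positive at
    the threshold, PRE and F1 are defined as 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels must contain both classes")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    acc = (tp + tn) / len(labels)
    rec = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    if tp + fp == 0:
        warnings.warn("no predicted positives at threshold; PRE and F1 set to 0")
        pre = f1 = 0.0
    else:
        pre = tp / (tp + fp)
        f1 = 2 * pre * rec / (pre + rec) if (pre + rec) > 0 else 0.0
    return MetricSet(aupr, auc, f1, acc, rec, spec, pre, threshold)


# ---------------------------------------------------------------------------
# Cross-validation protocol


def five_fold_split(
    ds: AssociationDataset, seed: int, run: int = 0, n_folds: int = 5
) -> list[FoldPlan]:
    """Randomly partition the positives into near-equal folds.

    For fold f, ``A_train`` is the association matrix with that fold's
    cells zeroed.
    """
    positives = np.column_stack(np.nonzero(ds.A))
    if len(positives) < n_folds:
        raise ValueError(f"need >= {n_folds} positives, got {len(positives)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(positives))
    chunks = np.array_split(perm, n_folds)
    plans = []
    for f, chunk in enumerate(chunks):
        held = positives[chunk]
        A_train = ds.A.copy()
        A_train[held[:, 0], held[:, 1]] = 0
        plans.append(FoldPlan(run=run, fold=f, held_out=held, A_train=A_train, seed=seed))
    return plans


def _embed(A_train: np.ndarray, ds: AssociationDataset, cfg: PipelineConfig):
    train_ds = AssociationDataset(list(ds.mirna_ids), list(ds.disease_ids), A_train)
    adj = build_adjacency(train_ds)
    if cfg.embedding_method == "sdne":
        emb, _ = train_sdne(adj, cfg.sdne)
    elif cfg.embedding_method == "le":
        emb = embed_laplacian(adj, cfg.sdne.d)
    elif cfg.embedding_method == "hope":
        emb = embed_hope(adj, cfg.sdne.d)
    else:
        raise ValueError(f"unknown embedding method {cfg.embedding_method!r}")
    return emb


def evaluate_fold(
    plan: FoldPlan,
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train on the reduced matrix, score every 0-cell of ``A_train``.

    Returns (scores, labels, pairs) over the evaluation set: all pairs
    absent from the training matrix, labeled 1 iff held out.
    """
    NE = None
    if cfg.features.use_embedding:
        NE = _embed(plan.A_train, ds, cfg).NE
    feats = build_training_set(plan.A_train, Z, SS, NE, cfg.features)
    rf_cfg = RFConfig(
        n_trees=cfg.rf.n_trees,
        seed=cfg.rf.seed + plan.seed + plan.fold,
        class_weighting=cfg.rf.class_weighting,
        max_features=cfg.rf.max_features,
        max_depth=cfg.rf.max_depth,
    )
    model = train_rf(feats, rf_cfg)

    # every evaluation pair sat in training as a negative: score out-of-bag
    eval_mask = feats.y == 0  # pairs that are 0 in A_train
    scores = oob_scores(model, feats.X)[eval_mask]
    pairs = feats.pairs[eval_mask]
    held = {(int(i), int(j)) for i, j in plan.held_out}
    labels = np.array([1 if (int(i), int(j)) in held else 0 for i, j in pairs], dtype=np.int8)
    return scores, labels, pairs


def run_cv(
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
    runs: int = 10,
    master_seed: int = 0,
    label: str = "cv",
) -> ExperimentResult:
    """R runs of five-fold CV; fold scores pooled per run, mean ± std over runs."""
    per_run = []
    for r in range(runs):
        run_seed = master_seed + r  # per-run seeds derived for audit
        plans = five_fold_split(ds, seed=run_seed, run=r)
        all_scores, all_labels = [], []
        for plan in plans:
            s, l, _ = evaluate_fold(plan, ds, Z, SS, cfg)
            all_scores.append(s)
            all_labels.append(l)
        per_run.append(
            compute_metrics(
                np.concatenate(all_scores), np.concatenate(all_labels), cfg.threshold
            )
        )
    return ExperimentResult(label, per_run)


def pooled_cv_scores(
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
    master_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One run of five-fold CV, returning the pooled (scores, labels, pairs)."""
    plans = five_fold_split(ds, seed=master_seed)
    all_s, all_l, all_p = [], [], []
    for plan in plans:
        s, l, p = evaluate_fold(plan, ds, Z, SS, cfg)
        all_s.append(s)
        all_l.append(l)
        all_p.append(p)
    return np.concatenate(all_s), np.concatenate(all_l), np.vstack(all_p)


# ---------------------------------------------------------------------------
# Experiments


def remove_associations(
    ds: AssociationDataset, fraction: float, seed: int
) -> tuple[AssociationDataset, np.ndarray]:
    """Randomly remove a share of the known associations (seeded)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    positives = np.column_stack(np.nonzero(ds.A))
    k = round(fraction * len(positives))
    rng = np.random.default_rng(seed)
    removed = positives[rng.choice(len(positives), size=k, replace=False)]
    A = ds.A.copy()
    A[removed[:, 0], removed[:, 1]] = 0
    if A.sum() == 0:
        raise ValueError("removal emptied the positive set")
    return AssociationDataset(list(ds.mirna_ids), list(ds.disease_ids), A), removed


def sparsification_experiment(
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
    fractions: list[float] = (0.1, 0.2, 0.3),
    runs: int = 10,
    master_seed: int = 0,
) -> dict[float, ExperimentResult]:
    """CV performance after removing 10/20/30% of known associations."""
    out = {}
    for frac in fractions:
        if frac == 0:
            reduced = ds
        else:
            reduced, _ = remove_associations(ds, frac, seed=master_seed + int(frac * 1000))
        out[frac] = run_cv(
            reduced, Z, SS, cfg, runs=runs, master_seed=master_seed,
            label=f"sparsify_{frac:g}",
        )
    return out


def recovery_experiment(
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
    fraction: float = 0.1,
    master_seed: int = 0,
    scorer=None,
) -> dict[str, float]:
    """What share of removed associations is re-scored as positive?

    One model is trained on the remaining positives (negatives = full
    complement); the removed pairs are scored and
    ``REC = fraction scored >= threshold``.  ``scorer`` may replace the
    trained model (callable pairs -> scores) for oracle plug-ins.
    """
    reduced, removed = remove_associations(ds, fraction, seed=master_seed)
    if scorer is not None:
        scores = np.asarray([scorer(int(i), int(j)) for i, j in removed], dtype=float)
        return {
            "fraction": fraction,
            "n_removed": len(removed),
            "recall": float(np.mean(scores >= cfg.threshold)),
        }
    NE = None
    if cfg.features.use_embedding:
        NE = _embed(reduced.A, ds, cfg).NE
    feats = build_training_set(reduced.A, Z, SS, NE, cfg.features)
    model = train_rf(feats, cfg.rf)
    all_scores = oob_scores(model, feats.X)
    flat = removed[:, 0] * ds.n + removed[:, 1]  # rows are in row-major pair order
    scores = all_scores[flat]
    other_neg = np.setdiff1d(np.nonzero(feats.y == 0)[0], flat)
    return {
        "fraction": fraction,
        "n_removed": len(removed),
        "recall": float(np.mean(scores >= cfg.threshold)),
        "removed_scores": scores.tolist(),
        "complement_scores": all_scores[other_neg].tolist(),
    }


def per_disease_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    pairs: np.ndarray,
    disease_index: int,
    threshold: float = 0.5,
) -> MetricSet | None:
    """Metrics restricted to one disease's column of the pooled CV scores.

    Returns ``None`` when the disease has no held-out positives (metrics
    undefined).
    """
    mask = pairs[:, 1] == disease_index
    sub_labels = labels[mask]
    if mask.sum() == 0 or sub_labels.sum() in (0, len(sub_labels)):
        return None
    return compute_metrics(scores[mask], sub_labels, threshold)


def rank_candidates(
    ds: AssociationDataset,
    Z: np.ndarray,
    SS: np.ndarray,
    cfg: PipelineConfig,
    k: int = 10,
    disease: str | None = None,
) -> list[tuple[str, str, float]]:
    """Score all unknown pairs with a model trained on every known
    association and return the top-k candidates (ties broken by id).

    ``disease`` restricts candidates to one disease's column.
    """
    NE = None
    if cfg.features.use_embedding:
        NE = _embed(ds.A, ds, cfg).NE
    feats = build_training_set(ds.A, Z, SS, NE, cfg.features)
    mask = feats.y == 0
    if disease is not None:
        j = ds.disease_ids.index(disease)
        mask = mask & (feats.pairs[:, 1] == j)
    model = train_rf(feats, cfg.rf)
    scores = oob_scores(model, feats.X)[mask]
    pairs = feats.pairs[mask]
    rows = [
        (ds.mirna_ids[int(i)], ds.disease_ids[int(j)], float(s))
        for (i, j), s in zip(pairs, scores)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows[: max(k, 0)]
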