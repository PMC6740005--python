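"""Random-forest scoring of miRNA-disease pairs.

The classification engine is a random forest (default 350 trees,
bootstrap samples, random feature subsets per node).  Because the
pair set is heavily imbalanced — a few thousand known associations
against the full m*n complement — a weighted variant assigns each
class the weight ``w_i = n_samples / (2 * n_i)``, so the minority
positives count as much as the majority in impurity and voting.
A pair's association score is the mean predicted probability of the
positive class over trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import PairFeatureMatrix


@dataclass
class RFConfig:
    n_trees: int = 350
    seed: int = 0
    class_weighting: str = "uniform"  # "uniform" or "balanced_half"
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None  # None: grow to purity

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.class_weighting not in ("uniform", "balanced_half"):
            raise ValueError("class_weighting must be 'uniform' or 'balanced_half'")


def compute_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """(w_0, w_1) with w_i = n_samples / (2 * n_i); both classes required."""
    labels = np.asarray(labels)
    n = len(labels)
    n1 = int((labels == 1).sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * n0), n / (2.0 * n1)


def train_rf(features: PairFeatureMatrix, cfg: RFConfig) -> RandomForestClassifier:
    """Fit the (optionally class-weighted) random forest on pair features."""
    y = np.asarray(features.y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    class_weight = None
    if cfg.class_weighting == "balanced_half":
        w0, w1 = compute_class_weights(y)
        class_weight = {0: w0, 1: w1}
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        max_depth=cfg.max_depth,
        class_weight=class_weight,
        random_state=cfg.seed,
        oob_score=True,
        n_jobs=1,
    )
    model.fit(features.X, y)
    return model


def oob_scores(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Out-of-bag association scores for the rows the forest trained on.

    In the semi-supervised protocol every scored pair was present in
    training (almost always as a negative); the full forest would score
    such rows with the trees that memorised them in-bag.  Out-of-bag
    scores are the standard unbiased estimate for training points.
    Rows with no out-of-bag vote (possible with few trees) fall back to
    the full-forest score.
    """
    pos_col = int(np.nonzero(model.classes_ == 1)[0][0])
    oob = model.oob_decision_function_[:, pos_col]
    missing = ~np.isfinite(oob)
    if missing.any():
        oob = oob.copy()
        oob[missing] = model.predict_proba(np.asarray(X)[missing])[:, pos_col]
    return oob


def predict_scores(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Association scores in [0, 1]: mean per-tree probability of class 1."""
    X = np.asarray(X)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {X.shape[1]} != model width {model.n_features_in_}"
        )
    proba = model.predict_proba(X)
    pos_col = int(np.nonzero(model.classes_ == 1)[0][0])
    return proba[:, pos_col]
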