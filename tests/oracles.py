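"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive algorithms (path enumeration, concordant
pair counting) so they share no code with the library paths they check.
"""

import numpy as np

from nemii.disease_similarity import DiseaseDAG


def all_downward_paths(dag: DiseaseDAG, start: str) -> list[int]:
    """Lengths of every directed path from ``start`` down to the target."""
    lengths = []

    def walk(node, depth):
        if node == dag.target:
            lengths.append(depth)
        for child in dag.children[node]:
            walk(child, depth + 1)

    walk(start, 0)
    return lengths


def brute_contribution(dag: DiseaseDAG, d: str) -> float:
    """max over downward paths of delta^len (0 if no path reaches target)."""
    lengths = all_downward_paths(dag, d)
    if not lengths:
        return 0.0
    return max(dag.delta**ell for ell in lengths)


def brute_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    num = sum(brute_contribution(dag_i, d) + brute_contribution(dag_j, d) for d in shared)
    den = sum(brute_contribution(dag_i, d) for d in dag_i.nodes) + sum(
        brute_contribution(dag_j, d) for d in dag_j.nodes
    )
    return num / den


def bfs_min_path_length(dag: DiseaseDAG, d: str) -> int | None:
    """Shortest downward path length from d to the target (BFS)."""
    frontier = [(d, 0)]
    seen = set()
    while frontier:
        node, depth = frontier.pop(0)
        if node == dag.target:
            return depth
        if node in seen:
            continue
        seen.add(node)
        frontier.extend((c, depth + 1) for c in dag.children[node])
    return None


def random_dag(rng: np.random.Generator, n_nodes: int, delta: float = 0.5) -> DiseaseDAG:
    """Random ancestor DAG: every node has a directed path down to node 0."""
    names = [f"n{k}" for k in range(n_nodes)]
    edges = set()
    for k in range(1, n_nodes):
        # each new node becomes parent of >= 1 earlier node
        n_children = int(rng.integers(1, min(k, 3) + 1))
        for child in rng.choice(k, size=n_children, replace=False):
            edges.add((names[k], names[int(child)]))
    return DiseaseDAG(names[0], set(names), edges, delta)


def brute_auc(scores, labels) -> float:
    """Concordant-pair AUC with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def hand_confusion_metrics(scores, labels, threshold=0.5) -> dict[str, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = np.sum(pred & (labels == 1))
    fp = np.sum(pred & (labels == 0))
    fn = np.sum(~pred & (labels == 1))
    tn = np.sum(~pred & (labels == 0))
    acc = (tp + tn) / len(labels)
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"ACC": acc, "REC": rec, "SPEC": spec, "PRE": pre, "F1": f1}
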