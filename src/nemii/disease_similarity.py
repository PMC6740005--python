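"""MeSH-style DAG semantic similarity between diseases.

Each disease ``D`` induces a directed acyclic graph ``DAG_D = (V_D, E_D)``
containing ``D`` and all its ancestors in the hierarchy, with edges from
parent to child.  Every node ``d`` of the DAG contributes a decayed
semantic score to ``D``::

    S_D(D) = 1
    S_D(d) = max{ delta * S_D(d') : d' a child of d within the DAG }

with decay ``delta`` (default 0.5), so a node's contribution is
``delta ** (shortest downward path length to D)``.  The semantic value
``SV_D = sum_d S_D(d)`` and the pairwise similarity is the share of
contribution mass on shared ancestors::

    SS(Di, Dj) = sum_{d in V_i ^ V_j} (S_Di(d) + S_Dj(d)) / (SV_i + SV_j)

which is symmetric, 1 on the diagonal and 0 for diseases with disjoint
ancestries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DiseaseOntologyInput

DEFAULT_DELTA = 0.5


@dataclass
class DiseaseDAG:
    """The ancestor DAG of one target disease.

    ``nodes`` includes the target; ``children`` maps each node to its
    children *within the DAG*.  Nodes are disease ids where the dataset
    has a disease owning the hierarchy code, otherwise the raw code
    string (contribution still flows through un-studied hierarchy
    positions).
    """

    target: str
    nodes: set[str]
    edges: set[tuple[str, str]]  # (parent, child)
    delta: float = DEFAULT_DELTA
    children: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        if self.target not in self.nodes:
            raise ValueError(f"target {self.target!r} not in DAG node set")
        self.children = {v: set() for v in self.nodes}
        for p, c in self.edges:
            self.children[p].add(c)

    def contribution(self, d: str) -> float:
        """Semantic contribution S_D(d) of node ``d`` to the target."""
        if d not in self.nodes:
            raise KeyError(f"{d!r} not in DAG of {self.target!r}")
        memo: dict[str, float] = {self.target: 1.0}

        def rec(v: str) -> float:
            if v in memo:
                return memo[v]
            kids = self.children[v]
            if not kids:
                # node with no downward path to the target contributes nothing
                memo[v] = 0.0
                return 0.0
            memo[v] = max(self.delta * rec(c) for c in kids)
            return memo[v]

        return rec(d)

    def contributions(self) -> dict[str, float]:
        return {d: self.contribution(d) for d in self.nodes}

    def semantic_value(self) -> float:
        """SV_D: total contribution over all DAG nodes (>= 1)."""
        return sum(self.contributions().values())


def _ancestor_closure_edges(
    disease: str, edges: list[tuple[str, str]]
) -> tuple[set[str], set[tuple[str, str]]]:
    parents: dict[str, set[str]] = {}
    for p, c in edges:
        parents.setdefault(c, set()).add(p)
    nodes = {disease}
    stack = [disease]
    while stack:
        v = stack.pop()
        for p in parents.get(v, ()):
            if p not in nodes:
                nodes.add(p)
                stack.append(p)
    induced = {(p, c) for p, c in edges if p in nodes and c in nodes}
    return nodes, induced


def build_dag(
    disease: str, onto: DiseaseOntologyInput, delta: float = DEFAULT_DELTA
) -> DiseaseDAG:
    """Build the ancestor DAG of one disease from the ontology input.

    Tree-number mode: every proper dot-prefix of each of the disease's
    codes is an ancestor; prefixes owned by a dataset disease are
    identified by that disease id, others by the code itself.  Multiple
    tree numbers merge into a single DAG (union of ancestor closures).

    Edge-list mode: ``V_D`` is the ancestor closure of the disease and
    ``E_D`` the induced edge set; cycles are fatal.
    """
    if onto.mode == "tree":
        codes = onto.tree_numbers.get(disease)
        if not codes:
            raise KeyError(f"disease {disease!r} has no tree numbers")
        owner: dict[str, str] = {}
        for d, cs in onto.tree_numbers.items():
            for c in cs:
                owner[c] = d

        def name(code: str) -> str:
            return owner.get(code, code)

        nodes = {disease}
        edges: set[tuple[str, str]] = set()
        for code in codes:
            parts = code.split(".")
            chain = [".".join(parts[: k + 1]) for k in range(len(parts))]
            labels = [name(c) for c in chain[:-1]] + [disease]
            nodes.update(labels)
            for a, b in zip(labels, labels[1:]):
                if a != b:
                    edges.add((a, b))
        return DiseaseDAG(disease, nodes, edges, delta)

    nodes, edges = _ancestor_closure_edges(disease, onto.edges)
    if disease not in nodes:
        raise KeyError(f"disease {disease!r} not in ontology edge list")
    _check_acyclic(nodes, edges)
    return DiseaseDAG(disease, nodes, edges, delta)


def _check_acyclic(nodes: set[str], edges: set[tuple[str, str]]) -> None:
    order = {v: 0 for v in nodes}  # 0=unseen 1=active 2=done
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for p, c in edges:
        children[p].append(c)

    def visit(v: str) -> None:
        if order[v] == 1:
            raise ValueError("cycle detected in disease ontology edge list")
        if order[v] == 2:
            return
        order[v] = 1
        for c in children[v]:
            visit(c)
        order[v] = 2

    for v in nodes:
        visit(v)


def semantic_contribution(dag: DiseaseDAG, d: str) -> float:
    """S_D(d): decayed contribution of node ``d`` to the DAG's target."""
    return dag.contribution(d)


def semantic_value(dag: DiseaseDAG) -> float:
    """SV_D = sum of S_D(d) over all DAG nodes."""
    return dag.semantic_value()


def semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """SS(Di, Dj): shared-ancestor contribution share in [0, 1]."""
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    ci = dag_i.contributions()
    cj = dag_j.contributions()
    num = sum(ci[d] + cj[d] for d in shared)
    return num / (dag_i.semantic_value() + dag_j.semantic_value())


def similarity_matrix(
    diseases: list[str], onto: DiseaseOntologyInput, delta: float = DEFAULT_DELTA
) -> "SimilarityMatrix":
    """Pairwise semantic-similarity matrix SS over the given diseases."""
    dags = [build_dag(d, onto, delta) for d in diseases]
    n = len(diseases)
    SS = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            SS[i, j] = SS[j, i] = semantic_similarity(dags[i], dags[j])
    return SimilarityMatrix(list(diseases), SS)


@dataclass
class SimilarityMatrix:
    """n x n symmetric disease semantic-similarity matrix with unit diagonal."""

    disease_ids: list[str]
    SS: np.ndarray

    def __post_init__(self) -> None:
        self.SS = np.asarray(self.SS, dtype=float)
        n = len(self.disease_ids)
        if self.SS.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    def to_tsv(self, path) -> None:
        from .data_model import write_matrix_tsv

        write_matrix_tsv(self.SS, self.disease_ids, self.disease_ids, path)
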