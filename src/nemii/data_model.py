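"""Input tables, filtering, and the bipartite association network.

The prediction task starts from three flat tables:

* an association edge list (miRNA id, disease id) of experimentally
  confirmed miRNA-disease associations,
* a family membership table (miRNA id, family id) giving each miRNA's
  miRBase family,
* a disease ontology description: either per-disease MeSH-style tree
  numbers (dot-separated hierarchy codes) or an explicit parent->child
  edge list.

These become an m x n binary association matrix ``A`` and the
(m+n) x (m+n) symmetric bipartite adjacency ``G = [[0, A], [A^T, 0]]``
whose rows feed the network embedding.  miRNAs without family
information and diseases without an ontology record are removed before
modelling, together with their associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class DataError(ValueError):
    """Raised for malformed or empty input tables."""


@dataclass
class AssociationDataset:
    """Known miRNA-disease associations as a binary matrix.

    ``mirna_ids`` index the rows of ``A`` and ``disease_ids`` the
    columns; both are sorted lexicographically so every derived matrix
    (adjacency, embeddings, features) has a reproducible row order.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        m, n = self.A.shape
        if m != len(self.mirna_ids) or n != len(self.disease_ids):
            raise DataError("association matrix shape does not match id lists")
        if len(set(self.mirna_ids)) != m or len(set(self.disease_ids)) != n:
            raise DataError("duplicate identifiers")
        if not np.isin(self.A, (0, 1)).all():
            raise DataError("association matrix must be binary")

    @property
    def m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """The association edge list implied by the 1-cells of ``A``."""
        ii, jj = np.nonzero(self.A)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(ii, jj)]


@dataclass
class BipartiteAdjacency:
    """Symmetric adjacency of the miRNA-disease bipartite network.

    Node order is miRNAs first (indices ``0..m-1``) then diseases
    (``m..m+n-1``), matching :class:`AssociationDataset` ordering so
    embedding rows are attributable to nodes.
    """

    G: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    @property
    def m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    @property
    def node_ids(self) -> list[str]:
        return list(self.mirna_ids) + list(self.disease_ids)

    @property
    def association_block(self) -> np.ndarray:
        """The upper-right m x n block (equals A bit-exactly)."""
        return self.G[: self.m, self.m :]


@dataclass
class FamilyTable:
    """Binary miRNA x family membership matrix Z."""

    mirna_ids: list[str]
    family_ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        if self.Z.shape != (len(self.mirna_ids), len(self.family_ids)):
            raise DataError("family matrix shape does not match id lists")

    @property
    def t(self) -> int:
        return len(self.family_ids)


@dataclass
class DiseaseOntologyInput:
    """Disease hierarchy, as tree numbers or an explicit edge list.

    Exactly one of the two representations is populated.  In
    tree-number mode ``tree_numbers`` maps a disease id to its
    dot-separated MeSH-style codes; every proper dot-prefix of a code
    is an ancestor.  In edge-list mode ``edges`` holds (parent, child)
    pairs over disease ids.
    """

    tree_numbers: dict[str, list[str]] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mode(self) -> str:
        return "tree" if self.tree_numbers else "edges"

    def annotated_diseases(self) -> set[str]:
        if self.tree_numbers:
            return {d for d, codes in self.tree_numbers.items() if codes}
        out: set[str] = set()
        for p, c in self.edges:
            out.add(p)
            out.add(c)
        return out


# ---------------------------------------------------------------------------
# TSV loading


def _read_tsv_rows(path: str | Path, min_cols: int = 2) -> list[list[str]]:
    path = Path(path)
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # optional single header line, detected by a non-data sentinel
            if lineno == 1 and fields[0].strip().lower() in {
                "mirna",
                "disease",
                "parent",
                "mirna_id",
                "disease_id",
            }:
                continue
            if len(fields) < min_cols:
                raise DataError(f"{path}:{lineno}: expected >= {min_cols} tab-separated fields")
            rows.append([f.strip() for f in fields])
    if not rows:
        raise DataError(f"{path}: no data rows")
    return rows


def load_associations(path: str | Path) -> AssociationDataset:
    """Load a miRNA-disease association edge list from TSV.

    Identifiers are deduplicated and sorted lexicographically;
    ``A_ij = 1`` iff the pair occurs in the file.  Duplicate edges are
    collapsed with a warning.
    """
    rows = _read_tsv_rows(path)
    pairs = [(r[0], r[1]) for r in rows]
    unique = set(pairs)
    if len(unique) < len(pairs):
        warnings.warn(
            f"{len(pairs) - len(unique)} duplicate association edge(s) removed",
            stacklevel=2,
        )
    return dataset_from_pairs(sorted(unique))


def dataset_from_pairs(pairs: Sequence[tuple[str, str]]) -> AssociationDataset:
    """Build an :class:`AssociationDataset` from unique (miRNA, disease) pairs."""
    if not pairs:
        raise DataError("no association pairs")
    mirnas = sorted({p[0] for p in pairs})
    diseases = sorted({p[1] for p in pairs})
    mi = {mid: i for i, mid in enumerate(mirnas)}
    di = {did: j for j, did in enumerate(diseases)}
    A = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for mirna, disease in pairs:
        A[mi[mirna], di[disease]] = 1
    return AssociationDataset(mirnas, diseases, A)


def load_family_table(path: str | Path, mirna_ids: Sequence[str] | None = None) -> FamilyTable:
    """Load a miRNA-family membership table from TSV.

    When ``mirna_ids`` is given, rows are aligned to that ordering
    (miRNAs absent from the file get an all-zero row); otherwise the
    miRNAs found in the file, sorted, define the rows.
    """
    rows = _read_tsv_rows(path)
    memberships = sorted({(r[0], r[1]) for r in rows})
    if mirna_ids is None:
        mirna_ids = sorted({m for m, _ in memberships})
    families = sorted({f for _, f in memberships})
    mi = {mid: i for i, mid in enumerate(mirna_ids)}
    fi = {fam: j for j, fam in enumerate(families)}
    Z = np.zeros((len(mirna_ids), len(families)), dtype=np.int8)
    for mirna, fam in memberships:
        if mirna in mi:
            Z[mi[mirna], fi[fam]] = 1
    return FamilyTable(list(mirna_ids), families, Z)


def load_ontology(path: str | Path, mode: str = "tree") -> DiseaseOntologyInput:
    """Load the disease hierarchy.

    ``mode='tree'``: rows are ``disease<TAB>tree_number``.
    ``mode='edges'``: rows are ``parent<TAB>child``.
    """
    rows = _read_tsv_rows(path)
    if mode == "tree":
        tn: dict[str, list[str]] = {}
        for disease, code, *_ in rows:
            tn.setdefault(disease, [])
            if code not in tn[disease]:
                tn[disease].append(code)
        return DiseaseOntologyInput(tree_numbers=tn)
    if mode == "edges":
        edges = sorted({(r[0], r[1]) for r in rows})
        return DiseaseOntologyInput(edges=edges)
    raise ValueError(f"unknown ontology mode {mode!r}")


# ---------------------------------------------------------------------------
# Filtering and adjacency construction


def filter_dataset(
    ds: AssociationDataset,
    fam: FamilyTable,
    onto: DiseaseOntologyInput,
) -> tuple[AssociationDataset, FamilyTable, DiseaseOntologyInput, dict[str, int]]:
    """Drop miRNAs without family information and diseases without an
    ontology record, consistently across all three structures.

    Returns the filtered triple plus a report of how many miRNAs,
    diseases and associations were removed.  Idempotent.
    """
    fam_lookup = {mid: i for i, mid in enumerate(fam.mirna_ids)}
    keep_m = [
        mid
        for mid in ds.mirna_ids
        if mid in fam_lookup and fam.Z[fam_lookup[mid]].sum() > 0
    ]
    annotated = onto.annotated_diseases()
    keep_d = [did for did in ds.disease_ids if did in annotated]
    if not keep_m or not keep_d:
        raise DataError("filtering removed every miRNA or every disease")

    mrows = [ds.mirna_ids.index(mid) for mid in keep_m]
    dcols = [ds.disease_ids.index(did) for did in keep_d]
    A = ds.A[np.ix_(mrows, dcols)]
    if A.sum() == 0:
        raise DataError("filtering removed every association")
    new_ds = AssociationDataset(keep_m, keep_d, A)

    keep_frows = [fam_lookup[mid] for mid in keep_m]
    Z = fam.Z[keep_frows]
    keep_fcols = np.nonzero(Z.sum(axis=0) > 0)[0]
    new_fam = FamilyTable(keep_m, [fam.family_ids[j] for j in keep_fcols], Z[:, keep_fcols])

    if onto.mode == "tree":
        # keep the full hierarchy: codes of off-dataset diseases still shape DAGs
        new_onto = DiseaseOntologyInput(
            tree_numbers={d: list(c) for d, c in onto.tree_numbers.items()}
        )
    else:
        new_onto = DiseaseOntologyInput(edges=list(onto.edges))

    report = {
        "mirnas_removed": ds.m - new_ds.m,
        "diseases_removed": ds.n - new_ds.n,
        "associations_removed": ds.n_associations - new_ds.n_associations,
    }
    return new_ds, new_fam, new_onto, report


def build_adjacency(ds: AssociationDataset) -> BipartiteAdjacency:
    """Construct ``G = [[0, A], [A^T, 0]]``, the symmetric bipartite adjacency."""
    m, n = ds.A.shape
    G = np.zeros((m + n, m + n), dtype=np.int8)
    G[:m, m:] = ds.A
    G[m:, :m] = ds.A.T
    return BipartiteAdjacency(G, list(ds.mirna_ids), list(ds.disease_ids))


# ---------------------------------------------------------------------------
# Persistence


def write_associations(ds: AssociationDataset, path: str | Path) -> None:
    """Write the association edge list back out as TSV (sorted pairs)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("miRNA\tdisease\n")
        for mirna, disease in ds.pairs():
            fh.write(f"{mirna}\t{disease}\n")


def write_matrix_tsv(
    M: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str], path: str | Path
) -> None:
    """Persist a matrix as dense headered TSV for inspection."""
    import pandas as pd

    pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )
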