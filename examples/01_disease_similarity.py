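"""Semantic similarity between diseases from a MeSH-style hierarchy.

Builds a tiny disease hierarchy by hand, computes each disease's
ancestor DAG, the decayed semantic contributions, and the pairwise
similarity matrix.
"""

from nemii.data_model import DiseaseOntologyInput
from nemii.disease_similarity import build_dag, semantic_value, similarity_matrix

# a small oncology-flavoured hierarchy: tree numbers are dot-separated
# hierarchy codes; every proper prefix of a code is an ancestor
onto = DiseaseOntologyInput(
    tree_numbers={
        "neoplasms": ["C04"],
        "digestive neoplasms": ["C04.588"],
        "liver neoplasms": ["C04.588.274"],
        "stomach neoplasms": ["C04.588.945"],
        "lung diseases": ["C08"],
    }
)

diseases = sorted(onto.tree_numbers)
for d in diseases:
    dag = build_dag(d, onto)
    print(f"{d}: {len(dag.nodes)} DAG nodes, semantic value SV = {semantic_value(dag):.3f}")

sim = similarity_matrix(diseases, onto)
print("\npairwise semantic similarity (delta = 0.5):")
header = " ".join(f"{d[:12]:>13}" for d in diseases)
print(f"{'':22}{header}")
for i, d in enumerate(diseases):
    row = " ".join(f"{sim.SS[i, j]:13.3f}" for j in range(len(diseases)))
    print(f"{d[:20]:>20}  {row}")

# liver and stomach neoplasms share the ancestors C04.588 and C04, so
# their similarity is high; lung diseases share no ancestor with the
# neoplasms and score 0.
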