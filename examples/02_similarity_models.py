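"""The similarity models, on small hand-checkable inputs.

Covers the annotation-set Jaccard similarity, the two disease semantic
similarity models on MeSH-style ancestor DAGs, the Gaussian interaction
profile (GIP) kernel, and the weighted integration of sources.
"""

import math

import numpy as np

import trilink as tl

# --- Jaccard similarity over side-effect profiles -------------------------
sets = tl.AnnotationSets(
    {"aspirin": {"nausea", "rash"}, "ibuprofen": {"rash", "ulcer"}, "novel": set()},
    kind="side_effect",
)
idx = tl.EntityIndex(["aspirin", "ibuprofen", "novel"])
jac = tl.jaccard_similarity(sets, idx)
print(f"Jaccard(aspirin, ibuprofen) = {jac.values[0, 1]:.4f}  (share 1 of 3 side effects)")
print(f"Jaccard(aspirin, novel)     = {jac.values[0, 2]:.4f}  (no annotations -> 0)")

# --- disease semantic similarity on ancestor DAGs -------------------------
# two lung diseases share a parent term; a third disease does not
dags = {
    "asthma": tl.DiseaseDAG("asthma", frozenset(), frozenset({("asthma", "lung disease")})),
    "copd": tl.DiseaseDAG("copd", frozenset(), frozenset({("copd", "lung disease")})),
    "gout": tl.DiseaseDAG("gout", frozenset(), frozenset({("gout", "joint disease")})),
}
didx = tl.EntityIndex(["asthma", "copd", "gout"])
ss1 = tl.semantic_similarity_m1(dags, didx, delta=0.5)
print(f"semantic model 1 (shared parent, delta=0.5) = {ss1.values[0, 1]:.4f}  (= 1/3)")
ss2 = tl.semantic_similarity_m2(dags, didx, base=math.e)
print(f"semantic model 2 (information content)      = {ss2.values[0, 1]:.4f}")
print(f"model 2 for the unrelated pair (asthma, gout) = {ss2.values[0, 2]:.4f}")

# --- GIP kernel on disease interaction profiles ---------------------------
B = np.eye(2)  # two diseases with orthogonal single-miRNA profiles
kd = tl.gip_kernel_disease(B, gamma_prime=1.0)
print(f"GIP kernel, orthogonal unit profiles = {kd.values[0, 1]:.5f}  (= exp(-2))")

# --- weighted integration --------------------------------------------------
m_lo = np.array([[1.0, 0.2], [0.2, 1.0]])
m_hi = np.array([[1.0, 0.6], [0.6, 1.0]])
merged = tl.integrate_mirna_similarity(m_lo, m_hi, index=tl.EntityIndex(["m1", "m2"]))
print(f"integrated miRNA similarity of 0.2 and 0.6 at equal weight = {merged.values[0, 1]:.2f}")
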