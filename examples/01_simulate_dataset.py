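"""Generate a synthetic triple-layer dataset with planted cluster structure.

Entities (small molecules, miRNAs, diseases) are assigned to latent blocks;
similarity is high within blocks, and associations preferentially connect
matching blocks.  The printed degree summaries show the Dataset-1-like
regime: associations concentrate on a minority of "active" entities while
the rest have none.
"""

import numpy as np

import trilink as tl

spec = tl.SyntheticSpec(seed=0)
data = tl.generate(spec)

print(f"universe: {data.universe.ns} SMs x {data.universe.nm} miRNAs x {data.universe.nd} diseases")
print(f"planted SM-miRNA associations:    {data.A.n_associations}")
print(f"planted miRNA-disease associations: {data.B.n_associations}")

sm_deg = data.A.values.sum(axis=1).astype(int)
print(f"SMs with at least one association: {(sm_deg > 0).sum()} of {spec.ns}")
print(f"max SM degree: {sm_deg.max()}, mean degree of active SMs: {sm_deg[sm_deg > 0].mean():.1f}")

rows, cols = np.nonzero(data.A.values)
coherent = (data.labels["sm"][rows] == data.labels["mirna"][cols]).mean()
print(f"fraction of associations joining matching blocks: {coherent:.2f}")

dense = tl.generate(spec, regime="dense")
print(f"dense regime (every entity associated): {dense.A.shape[0]} SMs x {dense.A.shape[1]} miRNAs")
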