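"""WGCNA-style module detection: Spearman -> adjacency -> TOM -> clusters.

Three correlated blocks are planted; the pipeline recovers them, names a
hub per module (highest intramodular connectivity), and summarizes each
module by its eigen-metabolite (PC1 of the standardized submatrix).
"""

import numpy as np
import pandas as pd

from dualtraj.network import (
    detect_modules,
    hub_metabolite,
    module_scores,
    soft_adjacency,
    spearman_matrix,
    topological_overlap,
)

rng = np.random.default_rng(0)
cols = {}
for b, size in enumerate((20, 15, 10), start=1):
    factor = rng.normal(0, 1, 80)
    for j in range(size):
        cols[f"block{b}_{j:02d}"] = (np.sqrt(0.8) * factor
                                     + np.sqrt(0.2) * rng.normal(0, 1, 80))
panel = pd.DataFrame(cols)

cor = spearman_matrix(panel)
adj = soft_adjacency(cor, beta=6, signed=True)
tom = topological_overlap(adj)
assignment = detect_modules(tom)
hubs = hub_metabolite(assignment, adj)
scores, varex = module_scores(panel, assignment)

for mod in sorted(hubs):
    members = assignment.modules[assignment.modules == mod]
    print(f"module {mod}: {len(members)} metabolites, hub {hubs[mod]}, "
          f"PC1 explains {varex[mod]:.0%}")
# Module ids are ordered by decreasing size, so module 1 is the planted
# 20-member block; with loading 0.8 PC1 explains most of each block.
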