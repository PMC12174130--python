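"""The two optimization stages on a 3-unit, 2-indicator toy block.

Units a and b each excel at one indicator; unit c is strictly inside their
convex hull and cannot reach 100 even under its own most favorable weights.
The Stage-2 common weights compromise between the units' best cases.
"""

import numpy as np

from ldikit import NormalizedMatrix, brute_force_dea_oracle, common_scores, cp_common_weights, dea_ideal_scores

block = NormalizedMatrix(
    unit_ids=["a", "b", "c"],
    indicator_ids=["x", "y"],
    values=np.array([[100.0, 20.0], [20.0, 100.0], [50.0, 50.0]]),
)

ideal = dea_ideal_scores(block)
print("stage-1 ideal scores (most favorable weights per unit):", np.round(ideal.s_star, 2))
print("grid-oracle check for unit c:", round(brute_force_dea_oracle(block, 2, grid_n=10_000), 2))

weights = cp_common_weights(block, ideal)
print("stage-2 common weights:", np.round(weights.w, 4), f"(L2 objective {weights.objective_value:.4f})")
print("common scores under one shared weighting:", np.round(common_scores(block, weights), 2))
# Common scores never exceed the ideal scores: the shared weights live in
# every unit's stage-1 feasible region.
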