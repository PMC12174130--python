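"""Full DEA-CP pipeline on a synthetic 31-unit, 65-indicator matrix.

The generator mirrors the study layout (six blocks of 9/21/7/13/11/4 leaf
indicators) with planted per-block abilities and mild multiplicative noise.
Each block is scored by Stage-1 benefit-of-the-doubt DEA followed by
Stage-2 compromise-programming common weights; the composite aggregates the
six block indices with the block weights and classifies units into five
security zones.
"""

from collections import Counter

from ldikit import SyntheticScenario, build_scheme, generate_matrix, run_pipeline

scenario = SyntheticScenario(seed=7)  # defaults: 31 units x 65 indicators, noise_sd 0.05
matrix, truth = generate_matrix(scenario)
scheme = build_scheme(scenario)
result, blocks = run_pipeline(matrix, scheme)

frame = result.to_frame().sort_values("rank")
print(frame[["ldi", "rank", "zone"]].head(5))
print("...")
print(frame[["ldi", "rank", "zone"]].tail(3))
print("zone counts:", dict(Counter(result.zone)))
print("stage-2 objectives per block:", [f"{b.cp_objective:.2e}" for b in blocks])
# The best unit scores 100.00 by construction; small stage-2 objectives mean
# one common weighting nearly reaches every unit's own best-case DEA score.
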