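"""Recovery of planted structure as measurement noise grows.

With no noise every block is exactly rank-1 after orientation and
normalization: compromise programming reaches each unit's ideal DEA score
exactly (objective 0) and the recovered ranking equals the planted one.
Increasing multiplicative noise degrades rank recovery gracefully.
"""

import numpy as np

from ldikit import SyntheticScenario, run_scenario

layout = dict(n_units=10, block_sizes=(3, 4, 2))
for noise in (0.0, 0.05, 0.2):
    rhos = []
    for seed in range(10):
        _, metrics = run_scenario(SyntheticScenario(**layout, noise_sd=noise, seed=seed))
        rhos.append(metrics.rank_correlation)
    print(f"noise_sd {noise:4.2f}: median rank correlation {np.median(rhos):.3f} over 10 seeds")
# Rank correlation compares the planted composite ability ordering with the
# recovered composite index ordering (1.0 = identical).
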