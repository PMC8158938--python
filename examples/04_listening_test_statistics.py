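"""Simulate an ABX listening-test cohort and run the repeated-measures ANOVA.

Builds a synthetic full study design (15 wall pairs x 2 distances x 3
impulse-response configurations), simulates 14 listeners whose accuracy
rises with the pair's spectral-difference SNQ2 — more discriminable at
5 m than at 0.8 m — scores the trials, and analyzes the discrimination
fractions with the three-way within-subject ANOVA.
"""

import numpy as np
import pandas as pd

from echowall import abx_stats, synthetic_data

rng = np.random.default_rng(0)
textures = ["flat", "circular_convex", "aperture", "parabolic_concave", "crenelated", "staircase"]
rows = []
for dist in (0.81, 5.03):
    for conf in ("normal", "rdld_plus6", "reflections_only"):
        boost = (2.0 if dist > 1 else 1.0) * (1.4 if conf != "normal" else 1.0)
        for i, a in enumerate(textures):
            for b in textures[i + 1 :]:
                rows.append({"pair_i": a, "pair_j": b, "distance": dist, "configuration": conf,
                             "snq2": boost * rng.uniform(0.5, 4.0)})
snq = pd.DataFrame(rows)

model = synthetic_data.ListenerModel(sensitivity=1.0, seed=1)
trials = synthetic_data.simulate_experiment(model, snq)
scored = abx_stats.score_trials(trials)
print(f"{len(trials)} trials; overall DF = {abx_stats.pooled_df(scored):.3f} (chance = 0.5)")

by_distance = abx_stats.compute_df(scored, ["distance"])
print(by_distance[["distance", "df", "n_trials"]].round(3).to_string(index=False))

pairwise = synthetic_data.pairwise_df_table(scored)
res = abx_stats.anova_from_pairwise(pairwise)
print("\nthree-way repeated-measures ANOVA on per-texture DFs:")
print(res.report())
print("\nthe distance effect is the built-in 5 m advantage; eta_p^2 is the")
print("fraction of (effect + error) variance the factor explains within subjects")
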