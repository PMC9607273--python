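"""GA recovery and y-scrambling study on the calibrated synthetic preset.

Over 20 data seeds of the 30×100 preset (4 planted descriptors, noise
calibrated in analysis/00): does GA-MLR return exactly the planted
4-subset?  Misses are classified as search failures (GA fitness below
the planted subset's Q²LOO) or identifiability losses (a rival subset
genuinely scores higher).  Also records y-scrambling behaviour of the
planted model per seed.

Writes results/synthetic_recovery.json.
"""

import json

import numpy as np

from ponqsar.modeling import GAConfig, ga_select
from ponqsar.synthetic import pon1_like
from ponqsar.validation import q2_loo, y_scramble

N_SEEDS = 20

rows = []
for seed in range(N_SEEDS):
    m, y, truth = pon1_like(seed)
    ranked = ga_select(m, y, GAConfig(seed=1000 + seed))
    planted = set(truth["informative_names"])
    found = set(ranked[0].descriptor_names)
    X = np.column_stack([m.column(n) for n in truth["informative_names"]])
    planted_fit = q2_loo(X, y)[0]
    res = y_scramble(X, y, iterations=100, seed=7)
    if found == planted:
        outcome = "recovered"
    elif ranked[0].fitness < planted_fit - 1e-9:
        outcome = "search_failure"
    else:
        outcome = "identifiability_loss"
    rows.append(
        {
            "seed": seed,
            "outcome": outcome,
            "ga_fitness": ranked[0].fitness,
            "planted_fitness": planted_fit,
            "overlap": len(found & planted),
            "true_r2": res.r2_unscrambled,
            "scrambled_mean_r2": res.mean_r2,
        }
    )

n_rec = sum(r["outcome"] == "recovered" for r in rows)
n_search = sum(r["outcome"] == "search_failure" for r in rows)
n_ident = sum(r["outcome"] == "identifiability_loss" for r in rows)
print(f"recovery: {n_rec}/{N_SEEDS} "
      f"({n_search} search failure(s), {n_ident} identifiability loss(es))")
print("identifiability losses are seeds where a rival 4-subset genuinely "
      "outscores the planted one in cross-validation — no search "
      "algorithm recovers those")
print(f"mean true-model R² = {np.mean([r['true_r2'] for r in rows]):.3f}; "
      f"mean scrambled R² = "
      f"{np.mean([r['scrambled_mean_r2'] for r in rows]):.3f}")

out = {
    "n_seeds": N_SEEDS,
    "recovered": n_rec,
    "search_failures": n_search,
    "identifiability_losses": n_ident,
    "per_seed": rows,
}
with open("results/synthetic_recovery.json", "w") as fh:
    json.dump(out, fh, indent=2)
print("wrote results/synthetic_recovery.json")
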