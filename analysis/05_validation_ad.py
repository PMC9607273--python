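"""Applicability domain and y-scrambling of the GA-selected models.

For each isozyme: Williams-plot classification of all 30 substrates
against the GA model from analysis/04 (training leverages, critical hat
3(p+1)/n, ±3σ standardized-residual cutoffs), plus y-scrambling of the
selected descriptor subset.

Writes results/ad_{q,r}.csv, results/williams_{q,r}.png and
results/yscramble_summary.json.
"""

import json

import numpy as np

from ponqsar.dataset import load_pon1, log_response
from ponqsar.descriptors import DescriptorMatrix
from ponqsar.domain import plot_williams, williams, write_ad_report
from ponqsar.modeling import MLRModel
from ponqsar.validation import y_scramble

matrix = DescriptorMatrix.read_csv("results/descriptors_pon1.csv")
cset = load_pon1()

summary = {}
for iso in ("Q", "R"):
    model = MLRModel.from_json(f"runs/ga_{iso.lower()}/model.json")
    y = log_response(cset, iso)
    records, table = williams(model, matrix, y)
    write_ad_report(records, f"results/ad_{iso.lower()}.csv")
    plot_williams(
        records, f"results/williams_{iso.lower()}.png",
        title=f"{iso} isozyme (GA model)",
    )
    outliers = [r for r in records if r.category != "in_domain"]
    print(
        f"{iso}: h* = {records[0].h_star:.3f}; "
        f"{len(outliers)} outlier(s): "
        + (", ".join(f"{r.compound_id} ({r.category})" for r in outliers)
           or "none")
    )

    train_idx = [cset.ids.index(i) for i in model.train_ids]
    X = np.column_stack([matrix.column(n) for n in model.descriptor_names])
    res = y_scramble(X[train_idx], y[train_idx], iterations=500, seed=3)
    summary[iso] = {
        "r2_unscrambled": res.r2_unscrambled,
        "q2_unscrambled": res.q2_unscrambled,
        "mean_scrambled_r2": res.mean_r2,
        "mean_scrambled_q2": res.mean_q2,
    }
    print(
        f"{iso}: y-scrambling over 500 permutations: mean R² = "
        f"{res.mean_r2:.3f} vs unscrambled {res.r2_unscrambled:.3f}"
    )

with open("results/yscramble_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print("wrote results/ad_{q,r}.csv, williams_{q,r}.png, yscramble_summary.json")
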