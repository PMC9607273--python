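"""Overview of the packaged 30-substrate PON1 dataset.

Loads the packaged table, applies the log10 response transform for both
isozymes, derives the 5-periodic ordered train/test split, and compares
it with the printed test-set flags.  Writes results/dataset_overview.csv.
"""

import numpy as np

from ponqsar.dataset import load_pon1, log_response
from ponqsar.modeling import ordered_split

cset = load_pon1()
print(f"{len(cset)} substrates; reference compound: {cset[0].name} "
      f"(rate 100 → log response {log_response(cset, 'Q')[0]:.1f})")

frame = cset.to_frame()
for iso in ("Q", "R"):
    y = log_response(cset, iso)
    frame[f"log_rate_{iso.lower()}"] = y
    train, test = ordered_split(y, 5)
    rule = np.zeros(len(cset), dtype=int)
    rule[test] = 1
    frame[f"rule_test_{iso.lower()}"] = rule
    printed = cset.test_mask(iso).astype(int)
    agree = int((rule == printed).sum())
    print(
        f"isozyme {iso}: rule-based split {len(train)}/{len(test)} "
        f"(train/test); printed flags mark {printed.sum()}; "
        f"flag agreement on {agree}/30 compounds"
    )

ratio = frame.loc[frame.name == "delta-Valerolactone", "rate_q"].iloc[0] / \
    frame.loc[frame.name == "gamma-Butyrolactone", "rate_q"].iloc[0]
print(f"Q-isozyme δ-valerolactone/γ-butyrolactone rate ratio: {ratio:.1f} "
      "(small ring-size changes swing the rate >30-fold)")

frame.to_csv("results/dataset_overview.csv", index=False)
print("wrote results/dataset_overview.csv")
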