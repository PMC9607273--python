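"""Evaluate the packaged published models on the computed descriptors.

Applies the fixed four-descriptor equations (no refitting) to the
descriptor matrix from analysis/02 and reports the full fitting /
internal / external criteria under the rule-based 80:20 split.

Because the packaged coefficients belong to a proprietary descriptor
dialect while the matrix here comes from the open re-implementation,
these numbers are qualitative reference output: they show the pipeline
mechanics, not a reproduction of the original fit statistics.

Writes results/fixture_validation_{q,r}.json and fixture_predictions.csv.
"""

import pandas as pd

from ponqsar.dataset import load_pon1, log_response
from ponqsar.descriptors import DescriptorMatrix
from ponqsar.pipeline import evaluate_fixture

matrix = DescriptorMatrix.read_csv("results/descriptors_pon1.csv")
cset = load_pon1()

frame = pd.DataFrame({"id": cset.ids, "name": [r.name for r in cset]})
for iso in ("Q", "R"):
    yhat, report = evaluate_fixture(iso, matrix, lmo_iterations=1000, seed=1)
    frame[f"log_rate_{iso.lower()}"] = log_response(cset, iso)
    frame[f"pred_{iso.lower()}"] = yhat
    report.to_json(f"results/fixture_validation_{iso.lower()}.json")
    print(f"--- {iso} isozyme, published equation on open descriptors ---")
    print(report.format())

frame.to_csv("results/fixture_predictions.csv", index=False)
print("wrote results/fixture_validation_{q,r}.json, fixture_predictions.csv")
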