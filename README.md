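# ponqsar

QSAR modelling of the hydrolysis rates of the human paraoxonase-1 (PON1)
Q and R isozymes.

PON1 is a Ca²⁺-dependent serum hydrolase whose two position-192 variants
(Gln192 "Q", Arg192 "R") hydrolyze lactones, aryl esters and
organophosphates at markedly different, substrate-dependent rates. This
package is for modellers who want to relate those rate differences to
computable properties of the substrate: it regresses the log relative
hydrolysis rate (phenyl acetate ≡ 100) of 30 substrates on 3D molecular
descriptors,

    log A = b0 + Σ_j b_j · d_j ,

selecting the descriptor subset with a genetic algorithm scored by
leave-one-out Q² (GA-MLR), and validating with R²/Q²LOO/Q²LMO, external
prediction, y-scrambling and a Williams-plot applicability domain
(leverage h = x(XᵀX)⁻¹xᵀ against h* = 3(p+1)/n, ±3σ residual cutoffs).

Included:

- the 30-substrate dataset with curated SMILES, per-isozyme rates and
  test-set flags (`ponqsar.load_pon1()`);
- the two published four-descriptor model equations as read-only fixtures
  (`ponqsar.load_fixture_model("Q"|"R")`);
- open implementations, from their literature definitions, of every
  descriptor family those models use: mass-weighted 3D-MoRSE signals,
  the WHIM accessibility index E1 (vdW-volume weighted), GETAWAY H
  autocorrelations, and SIC0 — computed on seeded RDKit conformers;
- GA-MLR model search, the full validation battery, and the AD analysis;
- a synthetic-data generator with planted sparse signal so every stage is
  testable end-to-end (`ponqsar.pon1_like`).

## Worked example

```python
import numpy as np
from ponqsar import (load_pon1, log_response, load_fixture_model,
                     ordered_split, predict, critical_hat)

cset = load_pon1()
y = log_response(cset, "Q")          # log10 rates; phenyl acetate -> 2.0
train, test = ordered_split(y, 5)    # every 5th by descending response
print(len(cset), len(train), len(test))   # 30 24 6

model = load_fixture_model("Q")
print(model.descriptor_names)        # ['Mor10m', 'Mor17m', 'E1v', 'H8m']
print(predict(model, np.zeros((1, 4)))[0])   # -0.487  (model intercept)
print(critical_hat(p=4, n=24))       # 0.625  (structural-outlier cutoff)
```

Output: `30 24 6`, the four descriptor names, `-0.487`, `0.625`.

Running the GA re-search on descriptors computed by this package
(`python analysis/02_compute_descriptors.py` then
`python analysis/04_ga_model_search.py`) prints, for the Q isozyme,

```
Fitting criteria
  R2 tr = 0.834, R2 adj = 0.799, RMSE = 0.352, MAE tr = 0.288,
  CCC tr = 0.909, s = 0.396, F = 23.834
Internal validation criteria
  Q2 LOO = 0.746, RMSE cv = 0.436, MAE cv = 0.359,
  Q2 LMO = 0.720, CCC cv = 0.862
```

i.e. a four-descriptor model of the Q-isozyme rates with R² ≈ 0.83 and
cross-validated Q² ≈ 0.75 — the same fit-quality regime as the published
models, from an independent open descriptor dialect (absolute descriptor
values differ from the proprietary toolchain's, so coefficients and
selected subsets differ too; see `docs/methods.md`).

## Command line

```bash
ponqsar fixtures                       # print the packaged equations
ponqsar descriptors --names Mor10m,Mor17m,E1v,H8m --seed 42 --out d.csv
ponqsar train --descriptor-file d.csv --isozyme Q --mode ga --ga-seed 7 \
              --outdir runs/q
ponqsar validate --descriptor-file d.csv --isozyme Q
ponqsar ad --descriptor-file d.csv --isozyme Q --out ad.csv --plot w.png
ponqsar simulate --seed 3 --out-prefix sim
```

## Analysis scripts

`analysis/` holds the numbered study drivers (noise calibration, dataset
overview, descriptor computation, fixture evaluation, GA search,
AD/y-scrambling, synthetic recovery study); each writes its tables under
`results/` and prints what it found.

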