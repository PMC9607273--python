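"""Compute the open-toolchain descriptor matrix for the PON1 set.

Embeds one minimized conformer per substrate (seeded) and evaluates the
implemented descriptor families: all 32 mass-weighted 3D-MoRSE signals,
the WHIM accessibility indices E1v/E1m, GETAWAY H autocorrelations of
lags 1–10, and SIC0 — a 45-column pool that contains every descriptor
of the published models.  Writes results/descriptors_pon1.csv.

Descriptor values are produced by an open conformer/descriptor dialect
(distance-geometry embedding + MMFF minimization), not by the
proprietary toolchain behind the published models, so absolute values
are expected to differ while the definitions match.
"""

from ponqsar.dataset import load_pon1
from ponqsar.descriptors import compute_descriptor_matrix

SEED = 2022

names = (
    [f"Mor{i:02d}m" for i in range(1, 33)]
    + ["E1v", "E1m"]
    + [f"H{k}m" for k in range(1, 11)]
    + ["SIC0"]
)

cset = load_pon1()
matrix = compute_descriptor_matrix(cset, names, seed=SEED)
constant = matrix.constant_columns()
print(f"computed {matrix.shape[0]}×{matrix.shape[1]} descriptor matrix "
      f"(seed {SEED}); constant columns: {constant or 'none'}")
matrix.write_csv("results/descriptors_pon1.csv")
print("wrote results/descriptors_pon1.csv")
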