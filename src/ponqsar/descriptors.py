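"""Molecular descriptors for PON1 substrate QSAR.

Implements, from their literature definitions, the four descriptor
families that appear in the final hydrolysis-rate models:

* 3D-MoRSE signals  Mor(s)_w = sum_{i<j} w_i w_j sin(s r_ij)/(s r_ij),
  with scattering parameter s = signal_index - 1 (Å⁻¹), so signal 1 is
  the s→0 limit where every sinc term is 1.
* WHIM directional accessibility E1_w: inverse kurtosis of the atom
  scores along the first weighted principal axis of the centered
  conformer.
* GETAWAY H autocorrelation H_k(w): sum of positive off-diagonal
  elements h_ij of the molecular influence matrix
  H = M (MᵀM)⁻¹ Mᵀ (M = centered coordinates) over atom pairs at
  topological distance k, weighted by w_i w_j.
* SIC0: Shannon entropy of the partition of atoms into element classes,
  normalized by log2(atom count).

Weights follow the carbon-normalized convention: atomic mass and
van-der-Waals volume are divided by the carbon value, so w(C) = 1.
Hydrogens are included throughout (their near-zero relative mass is what
makes mass-weighted MoRSE signals heavy-atom dominated).  Topological
distances are computed on the hydrogen-included bond graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .dataset import CompoundSet
from .geometry import Geometry, embed_conformer, vdw_volume

#: carbon reference values for the carbon-normalized relative weights
CARBON_MASS = 12.011
CARBON_VDW_VOLUME = vdw_volume("C")

Weighting = Literal["mass", "vdw_volume", "unweighted"]



class DescriptorError(ValueError):
    """Raised for invalid descriptor requests or degenerate geometries."""


def atom_weights(geom: Geometry, weighting: Weighting) -> np.ndarray:
    """Per-atom weights normalized to carbon."""
    if weighting == "mass":
        return geom.masses / CARBON_MASS
    if weighting == "vdw_volume":
        return geom.vdw_volumes / CARBON_VDW_VOLUME
    if weighting == "unweighted":
        return np.ones(geom.n_atoms)
    raise DescriptorError(f"unknown weighting {weighting!r}")


# ----------------------------------------------------------------- 3D-MoRSE

MORSE_MAX_SIGNAL = 32


def morse(
    geom: Geometry, signal_index: int, weighting: Weighting = "mass"
) -> float:
    """3D-MoRSE signal at s = signal_index - 1 Å⁻¹.

    The sum runs over all unordered atom pairs; sin(s·r)/(s·r) → 1 as
    s → 0, so signal 1 reduces to the sum of weight products.
    """
    if not 1 <= signal_index <= MORSE_MAX_SIGNAL:
        raise DescriptorError(
            f"signal_index {signal_index} outside 1..{MORSE_MAX_SIGNAL}"
        )
    if geom.n_atoms < 2:
        raise DescriptorError("3D-MoRSE needs at least 2 atoms")
    w = atom_weights(geom, weighting)
    s = float(signal_index - 1)
    d = geom.distance_matrix()
    iu = np.triu_indices(geom.n_atoms, k=1)
    r = d[iu]
    ww = (w[:, None] * w[None, :])[iu]
    if s == 0.0:
        return float(ww.sum())
    return float((ww * np.sin(s * r) / (s * r)).sum())


# --------------------------------------------------------------------- WHIM


def whim_E1(geom: Geometry, weighting: Weighting = "vdw_volume") -> float:
    """First-axis WHIM directional accessibility index E1.

    Weighted PCA of the conformer: scores t along the first principal
    axis of the weighted covariance of centered coordinates; E1 is the
    inverse of the weighted kurtosis of t.  Rotation/translation
    invariant by construction.
    """
    n = geom.n_atoms
    if n < 4:
        raise DescriptorError("WHIM needs at least 4 atoms")
    w = atom_weights(geom, weighting)
    sw = w.sum()
    m = geom.centered(weights=w)
    cov = (m * w[:, None]).T @ m / sw
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # collinear geometry: no spread off the first axis
    if evals[1] <= 1e-10 * max(evals[0], 1.0):
        raise DescriptorError(
            "degenerate (collinear) geometry: WHIM axes undefined"
        )
    t = m @ evecs[:, 0]
    lam = evals[0]
    if lam <= 0:
        raise DescriptorError("zero first-axis variance")
    kurt = float((w * t**4).sum() / sw / lam**2)
    return 1.0 / kurt


# ------------------------------------------------------------------ GETAWAY


def influence_matrix(geom: Geometry) -> np.ndarray:
    """Molecular influence matrix H = M (MᵀM)⁻¹ Mᵀ of centered coords.

    A rank-3 projection: its diagonal sums to 3 for any non-planar
    geometry.  Raises for rank-deficient (planar/linear) coordinates.
    """
    m = geom.centered()
    gram = m.T @ m
    rank = np.linalg.matrix_rank(gram, tol=1e-8)
    if rank < 3:
        raise DescriptorError(
            "rank-deficient coordinate matrix: influence matrix undefined"
        )
    return m @ np.linalg.solve(gram, m.T)


def topological_distances(geom: Geometry) -> np.ndarray:
    """All-pairs shortest-path lengths on the (hydrogen-included) graph."""
    return shortest_path(geom._adjacency(), method="D", unweighted=True)


def getaway_H(
    geom: Geometry,
    lag: int,
    weighting: Weighting = "mass",
    positive_only: bool = True,
) -> float:
    """GETAWAY H autocorrelation of the given topological lag.

    Sums h_ij·w_i·w_j over atom pairs exactly ``lag`` bonds apart;
    following the published definition only positive h_ij contribute
    (set ``positive_only=False`` to keep all elements).  Returns 0 when
    the graph diameter is below the lag.
    """
    if lag < 1:
        raise DescriptorError("lag must be >= 1")
    if geom.n_atoms < 4:
        raise DescriptorError("GETAWAY needs at least 4 atoms")
    topo = topological_distances(geom)
    finite = topo[np.isfinite(topo)]
    if finite.max() < lag:
        return 0.0
    h = influence_matrix(geom)
    w = atom_weights(geom, weighting)
    iu = np.triu_indices(geom.n_atoms, k=1)
    at_lag = topo[iu] == lag
    hij = h[iu]
    if positive_only:
        at_lag = at_lag & (hij > 0)
    return float((hij[at_lag] * (w[:, None] * w[None, :])[iu][at_lag]).sum())


# --------------------------------------------------------------------- SIC0


def sic0(geom: Geometry) -> float:
    """Structural information content of order 0.

    Atoms (hydrogens included) are partitioned by element; SIC0 is the
    Shannon entropy of the class sizes divided by log2(n), giving 0 for
    a homoatomic molecule and 1 when every atom is a distinct element.
    """
    n = geom.n_atoms
    if n < 2:
        raise DescriptorError("SIC0 undefined for a single atom")
    _, counts = np.unique(geom.elements, return_counts=True)
    p = counts / n
    ic0 = float(-(p * np.log2(p)).sum())
    return ic0 / np.log2(n)


# -------------------------------------------------------- name registry

_MORSE_RE = re.compile(r"^Mor(\d{2})([mu])$")
_WHIM_RE = re.compile(r"^E1([vm])$")
_GETAWAY_RE = re.compile(r"^H(\d+)m$")

KNOWN_PATTERNS = (
    "MorNNm / MorNNu (3D-MoRSE signal NN, mass / unweighted)",
    "E1v / E1m (WHIM first-axis accessibility, vdW volume / mass)",
    "HKm (GETAWAY H autocorrelation of lag K, mass)",
    "SIC0 (structural information content, order 0)",
)


def resolve_descriptor(name: str) -> Callable[[Geometry], float]:
    """Map a descriptor name to its computing function."""
    m = _MORSE_RE.match(name)
    if m:
        idx = int(m.group(1))
        weighting = "mass" if m.group(2) == "m" else "unweighted"
        return lambda g: morse(g, idx, weighting)
    m = _WHIM_RE.match(name)
    if m:
        weighting = "vdw_volume" if m.group(1) == "v" else "mass"
        return lambda g: whim_E1(g, weighting)
    m = _GETAWAY_RE.match(name)
    if m:
        lag = int(m.group(1))
        return lambda g: getaway_H(g, lag)
    if name == "SIC0":
        return sic0
    raise DescriptorError(
        f"unknown descriptor name {name!r}; known families: "
        + "; ".join(KNOWN_PATTERNS)
    )


# ----------------------------------------------------- descriptor matrix


@dataclass
class DescriptorMatrix:
    """Compounds × named descriptors, the design-matrix source."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.compound_ids), len(self.descriptor_names)
        if self.values.shape != (n, p):
            raise DescriptorError(
                f"values shape {self.values.shape} != ({n}, {p})"
            )
        if len(set(self.descriptor_names)) != p:
            raise DescriptorError("duplicate descriptor names")
        if not np.all(np.isfinite(self.values)):
            raise DescriptorError("missing/non-finite descriptor values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise DescriptorError(f"no descriptor column {name!r}") from None
        return self.values[:, j]

    def constant_columns(self) -> list[str]:
        sd = self.values.std(axis=0)
        return [n for n, s in zip(self.descriptor_names, sd) if s == 0.0]

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        cols = [self.column(n) for n in names]
        return DescriptorMatrix(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=np.column_stack(cols),
            provenance={n: self.provenance.get(n, "unknown") for n in names},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, provenance: str = "user-supplied"
    ) -> "DescriptorMatrix":
        return cls(
            compound_ids=[str(i) for i in df.index],
            descriptor_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            provenance={str(c): provenance for c in df.columns},
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls.from_frame(df)


def compute_descriptor_matrix(
    cset: CompoundSet,
    names: Sequence[str],
    seed: int = 42,
    extra: pd.DataFrame | None = None,
    n_confs: int | None = None,
) -> DescriptorMatrix:
    """Embed every compound once and evaluate the named descriptors.

    ``extra`` supplies user columns (e.g. quantum-chemical descriptors)
    indexed by compound id; names found there are taken from the table
    instead of being computed.  Deterministic given ``seed``.
    """
    names = list(names)
    if not names:
        raise DescriptorError("empty descriptor specification")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DescriptorError(f"duplicate descriptor name(s): {dupes}")

    extra_cols = set() if extra is None else set(map(str, extra.columns))
    funcs: dict[str, Callable[[Geometry], float]] = {}
    for name in names:
        if name not in extra_cols:
            funcs[name] = resolve_descriptor(name)

    kwargs = {} if n_confs is None else {"n_confs": n_confs}
    rows = []
    for rec in cset:
        geom = embed_conformer(
            rec.smiles, seed=seed, label=rec.compound_id, **kwargs
        )
        row = []
        for name in names:
            if name in funcs:
                row.append(funcs[name](geom))
            else:
                row.append(float(extra.loc[rec.compound_id, name]))
        rows.append(row)

    provenance = {
        n: ("user-supplied" if n in extra_cols else "computed") for n in names
    }
    return DescriptorMatrix(
        compound_ids=cset.ids,
        descriptor_names=names,
        values=np.array(rows),
        provenance=provenance,
    )
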