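"""3D conformer embedding and the Geometry container.

The 3D descriptor families used here (3D-MoRSE, WHIM, GETAWAY) are
conformation dependent, so descriptor values carry the provenance of the
geometry they were computed on.  This module produces a single
minimized conformer per compound by distance-geometry embedding (ETKDGv3)
followed by force-field minimization (MMFF94, falling back to UFF where
MMFF parameters are missing), picking the lowest-energy conformer of a
small seeded ensemble.  The procedure is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

_PT = Chem.GetPeriodicTable()

#: number of embedding attempts kept in the seeded ensemble
DEFAULT_N_CONFS = 5


class GeometryError(ValueError):
    """Raised for invalid or degenerate molecular geometries."""


def vdw_volume(symbol: str) -> float:
    """Spherical van-der-Waals volume (Å³) from the element's vdW radius."""
    r = _PT.GetRvdw(_PT.GetAtomicNumber(symbol))
    return 4.0 / 3.0 * np.pi * r**3


@dataclass
class Geometry:
    """An embedded conformer: coordinates plus per-atom properties.

    coords are in Å; masses in u; vdw_volumes in Å³; bonds is an
    undirected edge list over atom indices.
    """

    coords: np.ndarray
    elements: list[str]
    masses: np.ndarray
    vdw_volumes: np.ndarray
    bonds: list[tuple[int, int]]
    embed_seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.vdw_volumes = np.asarray(self.vdw_volumes, dtype=float)
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise GeometryError(f"coords must be ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if n >= 2:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.5:
                raise GeometryError(
                    f"atoms closer than 0.5 Å (min distance {d.min():.3f})"
                )
        if n >= 2 and not self._connected():
            raise GeometryError("bond graph is not connected")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def _adjacency(self) -> csr_matrix:
        n = self.n_atoms
        if not self.bonds:
            return csr_matrix((n, n))
        rows, cols = zip(*self.bonds)
        data = np.ones(len(self.bonds))
        a = csr_matrix((data, (rows, cols)), shape=(n, n))
        return a + a.T

    def _connected(self) -> bool:
        ncomp, _ = connected_components(self._adjacency(), directed=False)
        return ncomp == 1

    def centered(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Coordinates centered on the (optionally weighted) centroid."""
        if weights is None:
            center = self.coords.mean(axis=0)
        else:
            w = np.asarray(weights, dtype=float)
            center = (w[:, None] * self.coords).sum(axis=0) / w.sum()
        return self.coords - center

    def transformed(
        self, rotation: np.ndarray, translation: np.ndarray
    ) -> "Geometry":
        """A rigidly moved copy (used by invariance checks)."""
        return Geometry(
            coords=self.coords @ np.asarray(rotation).T + translation,
            elements=list(self.elements),
            masses=self.masses.copy(),
            vdw_volumes=self.vdw_volumes.copy(),
            bonds=list(self.bonds),
            embed_seed=self.embed_seed,
            label=self.label,
        )

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def _geometry_from_mol(
    mol: Chem.Mol, conf_id: int, seed: int | None, label: str
) -> Geometry:
    conf = mol.GetConformer(conf_id)
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    volumes = np.array([vdw_volume(s) for s in elements])
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    return Geometry(
        coords=coords,
        elements=elements,
        masses=masses,
        vdw_volumes=volumes,
        bonds=bonds,
        embed_seed=seed,
        label=label,
    )


def embed_conformer(
    smiles: str,
    seed: int = 42,
    n_confs: int = DEFAULT_N_CONFS,
    label: str = "",
) -> Geometry:
    """Embed and minimize a single lowest-energy conformer.

    Hydrogens are added explicitly (they carry weight in the descriptor
    formulas).  ``n_confs`` seeded ETKDG embeddings are each minimized and
    the lowest-energy one is returned; identical inputs give identical
    coordinates.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GeometryError(
            f"unparseable SMILES for compound {label or smiles!r}"
        )
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.useRandomCoords = False
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        raise GeometryError(
            f"conformer embedding failed for compound {label or smiles!r}"
        )
    energies = []
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    for cid, (converged, energy) in zip(conf_ids, results):
        energies.append((energy, cid))
    best = min(energies)[1]
    return _geometry_from_mol(mol, best, seed, label or smiles)


def geometry_from_arrays(
    coords,
    elements,
    bonds,
    masses=None,
    vdw_volumes=None,
    label: str = "",
) -> Geometry:
    """Construct a Geometry directly from arrays (testing / SDF import)."""
    elements = list(elements)
    if masses is None:
        masses = [_PT.GetAtomicWeight(_PT.GetAtomicNumber(s)) for s in elements]
    if vdw_volumes is None:
        vdw_volumes = [vdw_volume(s) for s in elements]
    return Geometry(
        coords=np.asarray(coords, dtype=float),
        elements=elements,
        masses=np.asarray(masses, dtype=float),
        vdw_volumes=np.asarray(vdw_volumes, dtype=float),
        bonds=[tuple(b) for b in bonds],
        label=label,
    )


def read_sdf(path) -> list[Geometry]:
    """Read user-supplied 3D geometries from an SDF; coordinates as-is."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise GeometryError(f"unreadable molecule at SDF index {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        out.append(_geometry_from_mol(mol, 0, None, name))
    return out
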