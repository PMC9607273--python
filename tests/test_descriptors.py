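"""Descriptor operators against brute-force oracles and invariances."""

import math

import networkx as nx
import numpy as np
import pytest
from conftest import make_random_geometry, random_rotation
from hypothesis import given, settings, strategies as st

from ponqsar.dataset import load_pon1, CompoundSet
from ponqsar.descriptors import (
    DescriptorError,
    DescriptorMatrix,
    atom_weights,
    compute_descriptor_matrix,
    getaway_H,
    influence_matrix,
    morse,
    resolve_descriptor,
    sic0,
    whim_E1,
)
from ponqsar.geometry import geometry_from_arrays


# ------------------------------------------------------- brute-force oracles


def morse_bruteforce(geom, signal_index, weighting="mass"):
    w = atom_weights(geom, weighting)
    s = signal_index - 1
    total = 0.0
    for i in range(geom.n_atoms):
        for j in range(i + 1, geom.n_atoms):
            r = float(np.linalg.norm(geom.coords[i] - geom.coords[j]))
            sinc = 1.0 if s == 0 else math.sin(s * r) / (s * r)
            total += w[i] * w[j] * sinc
    return total


def getaway_bruteforce(geom, lag, weighting="mass"):
    g = nx.Graph(geom.bonds)
    g.add_nodes_from(range(geom.n_atoms))
    sp = dict(nx.all_pairs_shortest_path_length(g))
    h = influence_matrix(geom)
    w = atom_weights(geom, weighting)
    total = 0.0
    for i in range(geom.n_atoms):
        for j in range(i + 1, geom.n_atoms):
            if sp[i].get(j) == lag and h[i, j] > 0:
                total += h[i, j] * w[i] * w[j]
    return total


# ------------------------------------------------------------------ 3D-MoRSE


class TestMorse:
    def test_signal_one_is_weight_product_sum(self, random_geometry):
        w = atom_weights(random_geometry, "mass")
        expected = (np.outer(w, w).sum() - (w**2).sum()) / 2
        assert morse(random_geometry, 1) == pytest.approx(expected, rel=1e-12)

    def test_two_atom_closed_form(self):
        geom = geometry_from_arrays(
            [[0, 0, 0], [1.0, 0, 0]], ["C", "C"], [(0, 1)]
        )
        assert morse(geom, 2, "unweighted") == pytest.approx(
            math.sin(1.0), rel=1e-12
        )

    @given(seed=st.integers(0, 500), signal=st.integers(1, 32))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_bruteforce_double_loop(self, seed, signal):
        geom = make_random_geometry(np.random.default_rng(seed), n_atoms=6)
        assert morse(geom, signal) == pytest.approx(
            morse_bruteforce(geom, signal), rel=1e-10, abs=1e-12
        )

    def test_signal_out_of_range(self, random_geometry):
        with pytest.raises(DescriptorError):
            morse(random_geometry, 0)
        with pytest.raises(DescriptorError):
            morse(random_geometry, 33)


# ---------------------------------------------------------------------- WHIM


class TestWhimE1:
    def test_rigid_motion_invariance(self, random_geometry):
        rng = np.random.default_rng(2)
        moved = random_geometry.transformed(
            random_rotation(rng), np.array([5.0, 5.0, 5.0])
        )
        assert whim_E1(moved) == pytest.approx(
            whim_E1(random_geometry), abs=1e-9
        )

    def test_equal_weights_against_eigen_oracle(self, random_geometry):
        """Unit weights: independent eigen-solve + kurtosis computation."""
        geom = random_geometry
        n = geom.n_atoms
        m = geom.coords - geom.coords.mean(axis=0)
        cov = np.cov(m.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        t = m @ evecs[:, np.argmax(evals)]
        kurt = (t**4).mean() / t.var() ** 2
        assert whim_E1(geom, weighting="unweighted") == pytest.approx(
            1.0 / kurt, rel=1e-9
        )

    def test_collinear_geometry_rejected(self):
        coords = [[float(i), 0, 0] for i in range(4)]
        geom = geometry_from_arrays(
            coords, ["C"] * 4, [(0, 1), (1, 2), (2, 3)]
        )
        with pytest.raises(DescriptorError, match="collinear|degenerate"):
            whim_E1(geom)

    def test_positive(self, gbl_geom):
        assert whim_E1(gbl_geom) > 0


# ------------------------------------------------------------------- GETAWAY


class TestGetawayH:
    def test_short_graph_gives_zero(self, gbl_geom):
        # heavy-atom ring + hydrogens: diameter < 8
        assert getaway_H(gbl_geom, 8) == 0.0

    def test_influence_trace_is_three(self, random_geometry):
        h = influence_matrix(random_geometry)
        assert np.trace(h) == pytest.approx(3.0, abs=1e-9)

    def test_long_lactone_matches_bruteforce(self, undecalactone_geom):
        val = getaway_H(undecalactone_geom, 8)
        assert val > 0
        assert val == pytest.approx(
            getaway_bruteforce(undecalactone_geom, 8), rel=1e-10
        )

    @given(seed=st.integers(0, 300), lag=st.integers(1, 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bruteforce_random_chains(self, seed, lag):
        geom = make_random_geometry(np.random.default_rng(seed), n_atoms=7)
        assert getaway_H(geom, lag) == pytest.approx(
            getaway_bruteforce(geom, lag), rel=1e-10, abs=1e-12
        )

    def test_rank_deficient_coordinates_rejected(self):
        coords = [[0, 0, 0], [1.2, 0, 0], [0, 1.2, 0], [1.2, 1.2, 0]]
        geom = geometry_from_arrays(
            coords, ["C"] * 4, [(0, 1), (1, 3), (0, 2)]
        )
        with pytest.raises(DescriptorError, match="rank"):
            getaway_H(geom, 2)


# ---------------------------------------------------------------------- SIC0


class TestSic0:
    def test_homoatomic_is_zero(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.8]]
        geom = geometry_from_arrays(coords, ["C"] * 3, [(0, 1), (1, 2)])
        assert sic0(geom) == 0.0

    def test_all_distinct_is_one(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.8], [4.0, 1.0, 0]]
        geom = geometry_from_arrays(
            coords, ["C", "N", "O", "S"], [(0, 1), (1, 2), (2, 3)]
        )
        assert sic0(geom) == pytest.approx(1.0)

    def test_gbl_hand_entropy(self, gbl_geom):
        # classes {C:4, H:6, O:2} of 12 atoms
        p = np.array([4, 6, 2]) / 12
        expected = -(p * np.log2(p)).sum() / np.log2(12)
        assert sic0(gbl_geom) == pytest.approx(expected, rel=1e-12)

    def test_single_atom_rejected(self):
        geom = geometry_from_arrays([[0, 0, 0]], ["C"], [])
        with pytest.raises(DescriptorError):
            sic0(geom)


# ------------------------------------------------- invariance across families


@pytest.mark.parametrize(
    "func",
    [
        lambda g: morse(g, 10),
        lambda g: morse(g, 17),
        whim_E1,
        lambda g: getaway_H(g, 3),
    ],
    ids=["Mor10m", "Mor17m", "E1v", "H3m"],
)
def test_rigid_motion_invariance_all_families(func):
    rng = np.random.default_rng(31)
    geom = make_random_geometry(rng, n_atoms=9)
    moved = geom.transformed(random_rotation(rng), rng.uniform(-4, 4, 3))
    assert func(moved) == pytest.approx(func(geom), abs=1e-9)


# ------------------------------------------------------------------- matrix


class TestDescriptorMatrix:
    def test_unknown_name_lists_known_families(self):
        with pytest.raises(DescriptorError, match="MoRSE|known"):
            resolve_descriptor("Bogus99")

    def test_small_matrix_on_packaged_subset(self, pon1):
        subset = CompoundSet(records=list(pon1.records[:4]))
        m = compute_descriptor_matrix(
            subset, ["Mor10m", "SIC0"], seed=5, n_confs=1
        )
        assert m.shape == (4, 2)
        assert m.provenance == {"Mor10m": "computed", "SIC0": "computed"}
        # bit-for-bit reproducible with the same seed
        again = compute_descriptor_matrix(
            subset, ["Mor10m", "SIC0"], seed=5, n_confs=1
        )
        np.testing.assert_array_equal(m.values, again.values)

    def test_empty_and_duplicate_specs_rejected(self, pon1):
        with pytest.raises(DescriptorError, match="empty"):
            compute_descriptor_matrix(pon1, [], seed=1)
        with pytest.raises(DescriptorError, match="duplicate"):
            compute_descriptor_matrix(pon1, ["SIC0", "SIC0"], seed=1)

    def test_user_supplied_columns(self, pon1):
        import pandas as pd

        subset = CompoundSet(records=list(pon1.records[:4]))
        extra = pd.DataFrame(
            {"HOMO": [1.0, 2.0, 3.0, 4.0]}, index=subset.ids
        )
        m = compute_descriptor_matrix(
            subset, ["SIC0", "HOMO"], seed=5, extra=extra, n_confs=1
        )
        assert m.provenance["HOMO"] == "user-supplied"
        np.testing.assert_array_equal(m.column("HOMO"), [1, 2, 3, 4])

    def test_csv_round_trip(self, tmp_path):
        m = DescriptorMatrix(
            ["a", "b"], ["X1", "X2"], np.array([[1.0, 2.0], [3.0, 4.0]])
        )
        p = tmp_path / "m.csv"
        m.write_csv(p)
        again = DescriptorMatrix.read_csv(p)
        assert again.compound_ids == m.compound_ids
        np.testing.assert_allclose(again.values, m.values)
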