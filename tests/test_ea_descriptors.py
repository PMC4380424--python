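"""Edge-adjacency spectra against line-graph closed forms and a brute-force
characteristic-polynomial oracle."""

import numpy as np
import pytest

from metastab import chem_graph, ea_descriptors
from metastab.chem_graph import parse_smiles
from metastab.ea_descriptors import (
    DescriptorNameError,
    compute_named,
    descriptor_table,
    edge_adjacency_matrix,
    family_names,
    parse_descriptor_name,
    spectral_descriptors,
)


def charpoly_eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Independent spectrum oracle: roots of the characteristic polynomial."""
    coeffs = np.poly(matrix)
    roots = np.roots(coeffs)
    assert np.allclose(roots.imag, 0, atol=1e-6)
    return np.sort(roots.real)[::-1]


def path_adjacency(m: int) -> np.ndarray:
    a = np.zeros((m, m))
    for i in range(m - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return a


def cycle_adjacency(m: int) -> np.ndarray:
    a = path_adjacency(m)
    a[0, m - 1] = a[m - 1, 0] = 1.0
    return a


class TestEdgeAdjacencyMatrix:
    def test_benzene_unweighted_is_six_cycle(self, benzene):
        # the line graph of a cycle is the same cycle
        mat = edge_adjacency_matrix(benzene, "none").entries
        assert mat.shape == (6, 6)
        assert np.array_equal(np.sort(mat.sum(axis=1)), np.full(6, 2.0))
        ev = np.sort(np.linalg.eigvalsh(mat))
        expected = np.sort(2 * np.cos(2 * np.pi * np.arange(6) / 6))
        assert np.allclose(ev, expected, atol=1e-10)

    def test_butane_unweighted_is_three_path(self, butane):
        # the line graph of the 4-path is the 3-path
        mat = edge_adjacency_matrix(butane, "none").entries
        perm_free = np.sort(np.linalg.eigvalsh(mat))
        assert np.allclose(
            perm_free, np.sort(np.linalg.eigvalsh(path_adjacency(3))), atol=1e-12
        )

    def test_benzene_bo_augmented_closed_form(self, benzene):
        # all weights 1.5: matrix is 1.5*(C6 adjacency) + 1.5*I
        mat = edge_adjacency_matrix(benzene, "bo", augmented=True).entries
        expected_ev = 1.5 * (np.sort(np.linalg.eigvalsh(cycle_adjacency(6))) + 1)
        assert np.allclose(np.sort(np.linalg.eigvalsh(mat)), expected_ev, atol=1e-10)

    def test_diagonal_zero_unless_augmented(self, benzene):
        ea = edge_adjacency_matrix(benzene, "bo", augmented=False)
        aea = edge_adjacency_matrix(benzene, "bo", augmented=True)
        assert np.all(np.diag(ea.entries) == 0)
        assert np.allclose(np.diag(aea.entries), 1.5)

    def test_offdiagonal_sparsity_matches_bond_incidence(self):
        g = parse_smiles("CC(C)CC")
        mat = edge_adjacency_matrix(g, "none").entries
        endpoints = [set(b.atoms) for b in g.bonds]
        for i in range(len(endpoints)):
            for j in range(len(endpoints)):
                if i == j:
                    continue
                share = bool(endpoints[i] & endpoints[j])
                assert (mat[i, j] != 0) == share

    def test_single_bond_molecule(self):
        g = parse_smiles("CC")
        mat = edge_adjacency_matrix(g, "none")
        assert mat.entries.shape == (1, 1)
        assert mat.entries[0, 0] == 0.0


class TestSpectralDescriptors:
    def test_benzene_spmax_spdiam(self, benzene):
        d = spectral_descriptors(edge_adjacency_matrix(benzene, "none"))
        assert d["SpMax"] == pytest.approx(2.0, abs=1e-10)
        assert d["SpDiam"] == pytest.approx(4.0, abs=1e-10)

    def test_butane_spmax_is_sqrt2(self, butane):
        d = spectral_descriptors(edge_adjacency_matrix(butane, "none"))
        assert d["SpMax"] == pytest.approx(np.sqrt(2), abs=1e-10)

    def test_ethane_padding(self):
        g = parse_smiles("CC")
        d = spectral_descriptors(edge_adjacency_matrix(g, "none"))
        assert d["SpMax"] == 0.0
        assert d["SpDiam"] == 0.0
        assert d["Eig02"] == 0.0

    def test_eigenvalues_sorted_descending(self, benzene):
        d = spectral_descriptors(edge_adjacency_matrix(benzene, "bo"))
        eigs = [d[f"Eig{i:02d}"] for i in range(1, 7)]
        assert eigs == sorted(eigs, reverse=True)
        assert d["SpMax"] == eigs[0]
        assert d["SpDiam"] >= 0

    @pytest.mark.parametrize(
        "smiles",
        ["CCCC", "c1ccccc1", "CC(C)C", "C1CC1", "C=Cc1ccccc1", "CC(=O)OC"],
    )
    @pytest.mark.parametrize("scheme", ["none", "bo"])
    @pytest.mark.parametrize("augmented", [False, True])
    def test_against_charpoly_oracle(self, smiles, scheme, augmented):
        # all candidate molecules have <= 8 bonds, where polynomial root
        # finding is reliable to the comparison tolerance
        g = parse_smiles(smiles)
        mat = edge_adjacency_matrix(g, scheme, augmented)
        assert g.n_bonds <= 8
        assert np.allclose(
            mat.eigenvalues(), charpoly_eigenvalues(mat.entries), atol=1e-8
        )

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_linear_alkane_matches_path_closed_form(self, n):
        # line graph of the n-path is the (n-1)-path; spectrum 2cos(pi k / m+1)
        g = parse_smiles("C" * n)
        ev = edge_adjacency_matrix(g, "none").eigenvalues()
        m = n - 1
        closed = np.sort(2 * np.cos(np.pi * np.arange(1, m + 1) / (m + 1)))[::-1]
        assert np.allclose(ev, closed, atol=1e-10)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 8])
    def test_cycloalkane_matches_cycle_closed_form(self, n):
        g = parse_smiles("C1" + "C" * (n - 1) + "1")
        ev = edge_adjacency_matrix(g, "none").eigenvalues()
        closed = np.sort(2 * np.cos(2 * np.pi * np.arange(n) / n))[::-1]
        assert np.allclose(ev, closed, atol=1e-10)

    def test_weight_scaling_scales_spectrum(self, benzene):
        # all benzene bonds share one weight, so bo rescales the EA spectrum
        ev_none = edge_adjacency_matrix(benzene, "none").eigenvalues()
        ev_bo = edge_adjacency_matrix(benzene, "bo").eigenvalues()
        assert np.allclose(ev_bo, 1.5 * ev_none, atol=1e-10)


class TestComputeNamed:
    def test_benzene_named_values(self, benzene):
        v = compute_named(benzene, ["SpMax_EA", "SpMax_AEA(bo)"])
        assert v.values["SpMax_EA"] == pytest.approx(2.0, abs=1e-10)
        assert v.values["SpMax_AEA(bo)"] == pytest.approx(4.5, abs=1e-10)

    def test_eig01_equals_spmax(self, benzene, butane):
        for g in (benzene, butane):
            v = compute_named(g, ["Eig01_EA", "SpMax_EA"])
            assert v.values["Eig01_EA"] == v.values["SpMax_EA"]

    @pytest.mark.parametrize("bad", ["Eig1_EA", "SpMax_XX", "Eig00_EA",
                                     "SpMax_EA(xx)", "spmax_EA"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(DescriptorNameError, match="does not match"):
            parse_descriptor_name(bad)

    def test_name_grammar_roundtrip(self):
        assert parse_descriptor_name("Eig11_EA(bo)") == ("Eig", 11, False, "bo")
        assert parse_descriptor_name("SpDiam_AEA(ri)") == ("SpDiam", None, True, "ri")
        assert parse_descriptor_name("SpMax_EA") == ("SpMax", None, False, "none")

    def test_permutation_invariance(self):
        names = ["SpMax_EA", "SpDiam_AEA(bo)", "Eig03_EA(bo)", "Eig02_AEA"]
        a = compute_named(parse_smiles("CC(C)c1ccccc1O"), names).values
        b = compute_named(parse_smiles("Oc1ccccc1C(C)C"), names).values
        for n in names:
            assert a[n] == pytest.approx(b[n], abs=1e-10)

    def test_six_selected_descriptor_names_computable(self, benzene):
        selected = ["Eig11_EA(bo)", "Eig10_EA(bo)", "SpMax_AEA(ri)",
                    "Eig01_AEA(ri)", "SpDiam_AEA(ri)", "SpMax_EA"]
        v = compute_named(benzene, selected)
        assert set(v.values) == set(selected)
        assert all(np.isfinite(x) for x in v.values.values())

    def test_family_table_shape(self, benzene, butane):
        names = family_names()
        table = descriptor_table([("benzene", benzene), ("butane", butane)], names)
        assert table.shape == (2, len(names))
        assert list(table.columns) == names
        assert table.notna().all().all()
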