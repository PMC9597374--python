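import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from kinsig.chem_io import dataset_from_smiles, parse_smiles
from kinsig.featurize import (
    CLASS_PAIRS,
    DEFAULT_GRID,
    ConfigurationError,
    GraphError,
    MolecularGraph,
    UndefinedStatisticError,
    all_pairs_shortest_paths,
    assign_pharmacophores,
    build_graph,
    compare_distributions,
    csm_signature,
    descriptor_block,
    feature_names,
    featurize_dataset,
    load_pharmacophore_definitions,
    registry_checksum,
    ro5_veber_flags,
    signature_for_molecule,
)

from oracles import bfs_distances, ks_statistic_enumeration, signature_bruteforce


def _labels(smiles):
    g = assign_pharmacophores(build_graph(parse_smiles(smiles)))
    return [set(s) for s in g.labels]


class TestBuildGraph:
    @pytest.mark.parametrize(
        "smiles,nodes,edges", [("CCO", 3, 2), ("c1ccccc1", 6, 6), ("CC(C)C", 4, 3)]
    )
    def test_counts(self, smiles, nodes, edges):
        g = build_graph(parse_smiles(smiles))
        assert g.n_nodes == nodes
        assert len(g.edges) == edges

    def test_disconnected_input_rejected(self):
        with pytest.raises(GraphError, match="strip_to_largest_fragment"):
            build_graph(parse_smiles("CCO.CC"))

    def test_self_loops_and_multiedges_rejected(self):
        with pytest.raises(GraphError):
            MolecularGraph(n_nodes=2, edges=((0, 0),))
        with pytest.raises(GraphError):
            MolecularGraph(n_nodes=2, edges=((0, 1), (1, 0)))


class TestPharmacophoreAssignment:
    """Pins the labels produced by the shipped definition file (version 1);
    changing the definitions must be a deliberate act that updates these."""

    def test_ethanol_hydroxyl_is_donor_and_acceptor(self):
        labels = _labels("CCO")
        assert labels[2] == {"Donor", "Acceptor"}

    def test_benzene_carbons_all_aromatic(self):
        labels = _labels("c1ccccc1")
        assert all(s == {"Aromatic"} for s in labels)

    def test_tetrafluoromethane_pinned(self):
        labels = _labels("FC(F)(F)F")
        assert labels[1] == set()  # carbon bonded to halogens: no label
        assert all(s == {"Hydrophobe"} for i, s in enumerate(labels) if i != 1)

    def test_pyridine_nitrogen(self):
        labels = _labels("c1ccncc1")
        assert labels[3] == {"Acceptor", "Aromatic"}

    def test_pyrrole_nh_is_donor(self):
        labels = _labels("c1cc[nH]c1")
        assert labels[3] == {"Donor", "Aromatic"}

    def test_carboxylate_is_neg_ionizable(self):
        labels = _labels("CC(=O)O")
        assert "NegIonizable" in labels[3]

    def test_primary_aliphatic_amine_is_pos_ionizable(self):
        labels = _labels("CCN")
        assert "PosIonizable" in labels[2]

    def test_definitions_file_is_versioned(self):
        defs = load_pharmacophore_definitions()
        assert defs.version == "1"
        assert len(defs.checksum) == 64


class TestShortestPaths:
    def test_path_graph(self):
        g = MolecularGraph(n_nodes=3, edges=((0, 1), (1, 2)))
        d = all_pairs_shortest_paths(g)
        assert d[0, 2] == 2
        assert (d == d.T).all()
        assert (np.diag(d) == 0).all()

    def test_benzene_diameter(self):
        g = build_graph(parse_smiles("c1ccccc1"))
        assert all_pairs_shortest_paths(g).max() == 3

    def test_matches_bfs_oracle_on_random_trees(self, rng):
        for _ in range(10):
            n = 8
            # random tree: attach each node to a random earlier node
            edges = tuple((int(rng.integers(i)), i) for i in range(1, n))
            d = all_pairs_shortest_paths(MolecularGraph(n_nodes=n, edges=edges))
            for s in range(n):
                assert d[s].tolist() == bfs_distances(n, edges, s)


class TestSignature:
    def test_unlabeled_molecule_gives_zero_vector(self):
        g = MolecularGraph(
            n_nodes=3, edges=((0, 1), (1, 2)), labels=(frozenset(), frozenset(), frozenset())
        )
        assert csm_signature(g, (1, 2)).values.sum() == 0

    def test_single_labeled_atom_cannot_pair(self):
        # ethanol: O is {Donor, Acceptor} but pairs need two distinct atoms
        sig = signature_for_molecule(parse_smiles("CCO"), grid=(1, 2))
        col = CLASS_PAIRS.index(("Acceptor", "Donor"))
        assert (sig.values[:, col] == 0).all()

    def test_hand_built_toy_graph_matches_bruteforce(self):
        labels = (
            frozenset({"Donor"}),
            frozenset({"Acceptor", "Hydrophobe"}),
            frozenset(),
            frozenset({"Donor", "Acceptor"}),
            frozenset({"Aromatic"}),
        )
        edges = ((0, 1), (1, 2), (2, 3), (1, 4))
        g = MolecularGraph(n_nodes=5, edges=edges, labels=labels)
        grid = (1, 2, 3)
        expected = signature_bruteforce(5, edges, labels, grid, CLASS_PAIRS)
        assert (csm_signature(g, grid).values == expected).all()

    def test_matches_bruteforce_on_fixture_molecules(self, fixture_molecules):
        for mol in fixture_molecules:
            g = assign_pharmacophores(build_graph(mol))
            expected = signature_bruteforce(
                g.n_nodes, g.edges, g.labels, DEFAULT_GRID, CLASS_PAIRS
            )
            assert (csm_signature(g).values == expected).all(), mol.smiles_canonical

    def test_cumulative_monotonicity(self, fixture_molecules):
        for mol in fixture_molecules:
            sig = signature_for_molecule(mol)
            assert (np.diff(sig.values, axis=0) >= 0).all()

    def test_atom_order_invariance(self, fixture_molecules, rng):
        for mol in fixture_molecules:
            reference = signature_for_molecule(mol).values
            for _ in range(3):
                perm = rng.permutation(mol.heavy_atom_count).tolist()
                shuffled = Chem.MolToSmiles(
                    Chem.RenumberAtoms(mol.mol, perm), canonical=False
                )
                assert (
                    signature_for_molecule(parse_smiles(shuffled)).values == reference
                ).all(), mol.smiles_canonical

    @pytest.mark.parametrize("grid", [(), (0, 1), (2, 2), (3, 1)])
    def test_invalid_grids_rejected(self, grid):
        g = MolecularGraph(n_nodes=2, edges=((0, 1),), labels=(frozenset(), frozenset()))
        with pytest.raises(ConfigurationError):
            csm_signature(g, grid)


class TestDescriptors:
    def test_benzene(self):
        d = descriptor_block(parse_smiles("c1ccccc1"))
        assert d["HBD"] == 0 and d["HBA"] == 0
        assert d["TPSA"] == 0 and d["RotatableBonds"] == 0
        assert d["RingCount"] == 1

    def test_urea_fragment_count(self):
        d = descriptor_block(parse_smiles("NC(=O)N"))
        assert d["fr_urea"] == 1
        assert d["FCount"] == 0

    def test_fluorine_count(self):
        assert descriptor_block(parse_smiles("FC(F)(F)F"))["FCount"] == 4

    def test_sulfonamide_fragment_count(self):
        assert descriptor_block(parse_smiles("NS(=O)(=O)c1ccccc1"))["fr_sulfonamide"] == 1


class TestRuleFlags:
    def test_benzene_passes_all(self):
        flags = ro5_veber_flags(descriptor_block(parse_smiles("c1ccccc1")))
        assert flags["all_pass"]

    def test_hbd_boundary_is_strict(self):
        d = {"HBA": 0, "HBD": 5, "MolLogP": 0.0, "RotatableBonds": 0, "TPSA": 0.0}
        assert not ro5_veber_flags(d)["hbd_lt_5"]

    def test_tpsa_boundary_is_strict(self):
        d = {"HBA": 0, "HBD": 0, "MolLogP": 0.0, "RotatableBonds": 0, "TPSA": 140.0}
        assert not ro5_veber_flags(d)["tpsa_lt_140"]

    def test_inclusive_boundaries(self):
        d = {"HBA": 10, "HBD": 4, "MolLogP": 4.9, "RotatableBonds": 10, "TPSA": 139.9}
        assert ro5_veber_flags(d)["all_pass"]


class TestCompareDistributions:
    def test_identical_samples_have_zero_ks_distance(self):
        stat, _ = compare_distributions([1, 2, 3, 4], [1, 2, 3, 4], "ks")
        assert stat == 0.0

    def test_disjoint_supports_have_unit_ks_distance(self):
        stat, _ = compare_distributions([1, 2, 3], [10, 11, 12], "ks")
        assert stat == 1.0

    def test_ks_matches_ecdf_enumeration(self, rng):
        cases = [([1, 2, 3], [2, 3, 4])] + [
            (rng.normal(size=7).tolist(), rng.normal(size=5).tolist()) for _ in range(10)
        ]
        for x, y in cases:
            stat, _ = compare_distributions(x, y, "ks")
            assert stat == pytest.approx(ks_statistic_enumeration(x, y), abs=1e-12)

    def test_welch_requires_variance(self):
        with pytest.raises(UndefinedStatisticError):
            compare_distributions([1, 1, 1], [2, 2, 2], "welch_t")

    def test_welch_matches_scipy_semantics(self):
        stat, p = compare_distributions([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5], "welch_t")
        assert p < 1 and stat < 0


class TestFeaturizeDataset:
    def test_dimensions_and_column_order(self):
        ds = dataset_from_smiles(["CCO", "c1ccccc1", "NC(=O)N"])
        fm = featurize_dataset(ds)
        assert fm.X.shape == (3, 21 * len(DEFAULT_GRID) + 13)
        assert list(fm.X.columns) == feature_names(DEFAULT_GRID)
        assert fm.X.columns[0].startswith("sig_")
        assert fm.X.columns[-1] == "fr_Ar_N"

    def test_identical_molecules_give_identical_rows(self):
        fm = featurize_dataset(dataset_from_smiles(["CCO", "CCO"]))
        assert (fm.X.iloc[0] == fm.X.iloc[1]).all()

    def test_row_order_matches_dataset(self):
        a = featurize_dataset(dataset_from_smiles(["CCO", "c1ccccc1"]))
        b = featurize_dataset(dataset_from_smiles(["c1ccccc1", "CCO"]))
        assert (a.X.iloc[0].values == b.X.iloc[1].values).all()

    def test_checksum_depends_on_grid(self):
        assert registry_checksum((1, 2, 3)) != registry_checksum(DEFAULT_GRID)
        assert registry_checksum(DEFAULT_GRID) == registry_checksum(DEFAULT_GRID)
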