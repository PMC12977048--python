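import numpy as np
import pytest
from rdkit import Chem

from rxnforge import (add_virtual_node, build_cgr, drfp_fingerprint,
                      load_geometry_pair, parse_reaction_smiles, rwse,
                      tokenize_smiles)
from rxnforge.errors import (ConfigError, GeometryError, ParseError,
                             TokenizationError)
from rxnforge.representations import (CGR_EDGE_DIM, Vocabulary,
                                      _stable_hash)

from .conftest import SN2
from .oracles import rwse_bruteforce


class TestDRFP:
    def test_identity_reaction_is_all_zero(self, identity_rxn):
        assert drfp_fingerprint(identity_rxn).popcount() == 0

    def test_direction_symmetric(self, small_table):
        for rec in small_table.records[:5]:
            fwd = drfp_fingerprint(rec)
            rev = parse_reaction_smiles(
                rec.to_smiles().split(">>")[1] + ">>" + rec.to_smiles().split(">>")[0])
            assert np.array_equal(fwd.bits, drfp_fingerprint(rev).bits)

    def test_invariant_to_map_labels_and_molecule_order(self, sn2):
        permuted = parse_reaction_smiles(
            "[OH-:1].[CH3:3][Br:2]>>[Br-:2].[CH3:3][OH:1]")
        assert np.array_equal(drfp_fingerprint(sn2).bits,
                              drfp_fingerprint(permuted).bits)

    def test_radius0_bits_match_shingle_enumeration(self, sn2):
        """Independent oracle: enumerate per-atom radius-0 fragment SMILES with
        RDKit directly and hash their symmetric difference."""
        sides = ("[CH3:1][Br:2].[OH-:3]", "[CH3:1][OH:3].[Br-:2]")
        shingles = []
        for smi in sides:
            mol = Chem.MolFromSmiles(smi)
            for a in mol.GetAtoms():
                a.SetAtomMapNum(0)
            shingles.append({Chem.MolFragmentToSmiles(mol, atomsToUse=[a.GetIdx()])
                             for a in mol.GetAtoms()})
        expected_bits = {_stable_hash(s, 0) % 2048 for s in shingles[0] ^ shingles[1]}
        fp = drfp_fingerprint(sn2, radius=0, n_bits=2048, seed=0)
        assert set(np.flatnonzero(fp.bits)) == expected_bits
        assert fp.popcount() > 0

    def test_n_bits_must_be_power_of_two(self, sn2):
        with pytest.raises(ConfigError):
            drfp_fingerprint(sn2, n_bits=1000)


class TestTokenize:
    @pytest.mark.parametrize("smiles,tokens", [
        ("CC(=O)O", ["C", "C", "(", "=", "O", ")", "O"]),
        ("[CH3:1][Br:2]", ["[CH3:1]", "[Br:2]"]),
        ("Clc1ccccc1", ["Cl", "c", "1", "c", "c", "c", "c", "c", "1"]),
    ])
    def test_token_grammar(self, smiles, tokens):
        assert tokenize_smiles(smiles).tokens == tokens

    def test_unclosed_bracket_reports_position(self):
        with pytest.raises(TokenizationError, match="position 2"):
            tokenize_smiles("CC[Br")

    def test_molecule_boundaries_at_separators(self):
        seq = tokenize_smiles("CC.O>>CO")
        groups = [seq.tokens[a:b] for a, b in seq.molecule_boundaries]
        assert groups == [["C", "C"], ["O"], ["C", "O"]]

    def test_concatenation_identity_on_fixtures(self, small_table):
        for rec in small_table.records:
            smi = rec.to_smiles()
            assert "".join(tokenize_smiles(smi).tokens) == smi

    def test_vocabulary_unknown_maps_to_unk(self):
        train = [tokenize_smiles("CCO")]
        vocab = Vocabulary().fit(train)
        seq = vocab.encode(tokenize_smiles("CCS"))
        assert seq.vocab_ids[-1] == 0 and 0 not in seq.vocab_ids[:2]


class TestCGR:
    def test_sn2_union_graph(self, sn2):
        g = build_cgr(sn2)
        assert g.n_nodes == 3 and g.labels == [1, 2, 3]
        und = {frozenset((g.labels[g.edge_index[0, k]], g.labels[g.edge_index[1, k]]))
               for k in range(g.n_edges)}
        assert und == {frozenset({1, 2}), frozenset({1, 3})}
        # edge (1,2): single in reactants, absent in products; (1,3) converse
        for k in range(0, g.n_edges, 2):
            pair = frozenset((g.labels[g.edge_index[0, k]],
                              g.labels[g.edge_index[1, k]]))
            r_onehot = g.edge_features[k, :5]
            p_onehot = g.edge_features[k, 5:10]
            if pair == frozenset({1, 2}):
                assert r_onehot[1] == 1 and p_onehot[0] == 1
            else:
                assert r_onehot[0] == 1 and p_onehot[1] == 1
            assert g.edge_features[k, 10] == 1.0  # both bonds change

    def test_identity_reaction_zero_differences(self, identity_rxn):
        g = build_cgr(identity_rxn)
        assert np.all(g.node_features[:, -5:] == 0)
        assert g.n_edges == 0

    def test_unchanged_bonds_have_equal_states(self, small_table):
        g = build_cgr(small_table.records[0])
        for k in range(g.n_edges):
            r_onehot = g.edge_features[k, :5]
            p_onehot = g.edge_features[k, 5:10]
            changed = g.edge_features[k, 10]
            assert (not np.array_equal(r_onehot, p_onehot)) == bool(changed)

    def test_relabeling_permutes_rows(self, sn2):
        permuted = parse_reaction_smiles(
            "[CH3:3][Br:2].[OH-:1]>>[CH3:3][OH:1].[Br-:2]")
        a, b = build_cgr(sn2), build_cgr(permuted)
        # label map 1->3, 2->2, 3->1: row of label l in a equals row of its
        # image in b
        mapping = {1: 3, 2: 2, 3: 1}
        for l_old, l_new in mapping.items():
            assert np.allclose(a.node_features[a.labels.index(l_old)],
                               b.node_features[b.labels.index(l_new)])


class TestTransforms:
    def test_virtual_node_counts(self, sn2):
        g = build_cgr(sn2)
        vg = add_virtual_node(g)
        assert vg.n_nodes == g.n_nodes + 1
        assert vg.n_edges == g.n_edges + 2 * g.n_nodes
        assert vg.node_features[-1, -1] == 1.0

    def test_single_node_graph(self, identity_rxn):
        vg = add_virtual_node(build_cgr(identity_rxn))
        assert vg.n_nodes == 2 and vg.n_edges == 2

    def test_applying_twice_adds_two_virtual_nodes(self, sn2):
        vg2 = add_virtual_node(add_virtual_node(build_cgr(sn2)))
        assert vg2.n_nodes == build_cgr(sn2).n_nodes + 2


class TestRWSE:
    def test_two_node_bond(self, identity_rxn):
        r = parse_reaction_smiles("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        enc = rwse(build_cgr(r), 2)
        assert np.allclose(enc, [[0, 1], [0, 1]])

    def test_triangle(self):
        r = parse_reaction_smiles(
            "[CH2:1]1[CH2:2][CH2:3]1>>[CH2:1]1[CH2:2][CH2:3]1")
        enc = rwse(build_cgr(r), 2)
        assert np.allclose(enc, [[0, 0.5]] * 3)

    def test_isolated_node_all_zero(self, identity_rxn):
        assert np.allclose(rwse(build_cgr(identity_rxn), 4), 0)

    def test_matches_matrix_power_oracle(self, small_table):
        for rec in small_table.records[:20]:
            g = build_cgr(rec)
            assert np.allclose(rwse(g, 5),
                               rwse_bruteforce(g.undirected_adjacency(), 5))

    def test_rows_bounded(self, small_table):
        for rec in small_table.records[:10]:
            enc = rwse(build_cgr(rec), 6)
            assert np.all(enc >= 0) and np.all(enc <= 1)
            assert np.all(enc.sum(axis=1) <= 6.0)


class TestXYZ:
    def _write(self, path, elements, coords, n=None):
        lines = [str(n if n is not None else len(elements)), "comment"]
        lines += [f"{e} {x} {y} {z}" for e, (x, y, z) in zip(elements, coords)]
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    def test_matching_pair_loads(self, tmp_path):
        coords = [(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)]
        r = self._write(tmp_path / "r.xyz", ["C", "H", "O"], coords)
        t = self._write(tmp_path / "ts.xyz", ["C", "H", "O"], coords)
        pair = load_geometry_pair(r, t)
        assert pair.elements == ["C", "H", "O"] and pair.r_coords.shape == (3, 3)

    def test_count_mismatch(self, tmp_path):
        r = self._write(tmp_path / "r.xyz", ["C", "O", "H"],
                        [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        t = self._write(tmp_path / "ts.xyz", ["C", "O", "H", "H"],
                        [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        with pytest.raises(GeometryError, match="count"):
            load_geometry_pair(r, t)

    def test_element_order_mismatch(self, tmp_path):
        coords = [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        r = self._write(tmp_path / "r.xyz", ["C", "H", "O"], coords)
        t = self._write(tmp_path / "ts.xyz", ["C", "O", "H"], coords)
        with pytest.raises(GeometryError, match="element"):
            load_geometry_pair(r, t)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nC 0 0 0\nO 1 nope 0\n")
        with pytest.raises(ParseError, match="line 4"):
            load_geometry_pair(str(path), str(path))


def test_edge_feature_width_constant(small_table):
    dims = {build_cgr(r).edge_features.shape[1] for r in small_table.records
            if build_cgr(r).n_edges}
    assert dims == {CGR_EDGE_DIM}
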