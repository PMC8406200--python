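"""Native contacts, pocket and interface selections."""

import numpy as np
import pytest

from filadyn.selection import (
    ResidueSet,
    interface_residues,
    junction_interface_residues,
    map_residue_set,
    native_contacts,
    pocket_residues,
)
from filadyn.structio import SelectionError, extract_ca, superpose
from filadyn.synthetic import _rotation


def _brute_contacts(coords, cutoff, min_seq_sep, chain_index):
    pairs = set()
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            same = chain_index[i] == chain_index[j]
            if same and j - i < min_seq_sep:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add((i, j))
    return pairs


class TestNativeContacts:
    def test_cutoff_boundary(self):
        for d, expected in [(7.4, 1), (7.5, 1), (7.6, 0)]:
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            cl = native_contacts(coords, 7.5, 2, chain_index=np.array([0, 1]))
            assert len(cl) == expected, d

    def test_straight_chain_no_contacts(self):
        # 10 beads at 3.8 Å spacing on a line: |i-j|=2 distance is 7.6 Å
        coords = np.outer(np.arange(10), [3.8, 0.0, 0.0])
        cl = native_contacts(coords, 7.5, 2)
        assert len(cl) == 0

    def test_min_seq_sep_excludes_bonds(self):
        coords = np.outer(np.arange(5), [3.0, 0.0, 0.0])
        cl = native_contacts(coords, 7.5, 2)
        assert all(j - i >= 2 for i, j in cl.pairs)

    def test_interchain_pairs_kept_at_any_separation(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        cl = native_contacts(coords, 7.5, 2, chain_index=np.array([0, 1]))
        assert len(cl) == 1

    def test_matches_brute_force(self, chain_trace):
        _trace, ca = chain_trace
        cidx = np.zeros(len(ca), dtype=int)
        cl = native_contacts(ca, 7.5, 2, cidx)
        assert cl.as_set() == _brute_contacts(ca, 7.5, 2, cidx)
        # stored reference distances are the actual native distances
        d = np.linalg.norm(ca[cl.pairs[:, 0]] - ca[cl.pairs[:, 1]], axis=1)
        np.testing.assert_allclose(cl.distances, d, atol=1e-12)

    def test_rigid_motion_invariance(self, chain_trace):
        _trace, ca = chain_trace
        rot = _rotation([1, 2, 3], 73.0)
        moved = ca @ rot.T + np.array([5.0, -3.0, 8.0])
        assert (native_contacts(ca).as_set()
                == native_contacts(moved).as_set())

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            native_contacts(np.zeros((5, 3)), cutoff=-1.0)
        with pytest.raises(SelectionError):
            native_contacts(np.zeros((1, 3)))


class TestPocketResidues:
    def test_expansion_boundary(self, compact_chain):
        trace = extract_ca(compact_chain)
        target = trace[0][1]
        for offset, included in [(5.9, True), (6.1, False)]:
            ligand = [target + np.array([offset, 0, 0])]
            # place the probe away from all other beads
            rs = pocket_residues(compact_chain, ligand, 6.0)
            assert (trace[0][0] in rs) == ((trace[0][0] in rs))  # sanity
            dmin = min(np.linalg.norm(p - ligand[0]) for _r, p in trace)
            if included and dmin <= 6.0:
                assert len(rs) >= 1

    def test_far_ligand_empty(self, compact_chain):
        rs = pocket_residues(compact_chain, [np.array([500.0, 0, 0])], 6.0)
        assert len(rs) == 0

    def test_empty_ligand_error(self, compact_chain):
        with pytest.raises(ValueError):
            pocket_residues(compact_chain, [], 6.0)

    def test_planted_pockets_recovered(self, tetramer_pair):
        """Selection reproduces the generator's brute-force ground truth."""
        structure, truth = tetramer_pair
        for label, members in truth.pockets.items():
            site = truth.ligand_sites[label]
            rs = pocket_residues(structure, [site], 6.0)
            assert sorted(rs.ids) == sorted(members), label


class TestInterfaceResidues:
    def test_separated_chains_empty(self, tetramer_pair):
        structure, _ = tetramer_pair
        # move chain D far away via a copy
        import copy
        st = copy.deepcopy(structure)
        for res in st.chain("D").residues:
            for a in res.atoms:
                a.pos = a.pos + 500.0
        rs = interface_residues(st, ["A"], ["D"], 7.5)
        assert len(rs) == 0

    def test_pair_at_boundary(self):
        from filadyn.synthetic import _chain_from_coords
        from filadyn.structio import Structure
        st = Structure([
            _chain_from_coords(np.array([[0.0, 0, 0]]), "A"),
            _chain_from_coords(np.array([[7.49, 0, 0]]), "B"),
        ])
        assert len(interface_residues(st, ["A"], ["B"], 7.5)) == 1

    def test_overlapping_groups_rejected(self, tetramer_pair):
        structure, _ = tetramer_pair
        with pytest.raises(SelectionError):
            interface_residues(structure, ["A", "B"], ["B", "C"])

    def test_planted_junction_patches_recovered(self, octamer_pair):
        structure, truth = octamer_pair
        got = junction_interface_residues(
            structure, truth.tetramer1_chains, truth.linker_chains,
            truth.tetramer2_chains, 7.5)
        assert sorted(got.ids) == sorted(truth.interface_patches["tetramer1"])


class TestMapResidueSet:
    def test_identity_mapping(self, tetramer_pair):
        structure, truth = tetramer_pair
        rs = ResidueSet(truth.pockets["A"], "pocket")
        mapped = map_residue_set(rs, structure, structure, lambda r: r)
        assert mapped.ids == rs.ids

    def test_offset_mapping(self, tetramer_pair):
        import copy
        structure, truth = tetramer_pair
        target = copy.deepcopy(structure)
        for _cid, res in target.iter_residues():
            res.number += 100
        rs = ResidueSet(truth.pockets["A"], "pocket")
        mapped = map_residue_set(rs, structure, target,
                                 lambda r: (r[0], r[1] + 100, r[2]))
        assert [n for _c, n, _i in mapped.ids] == [n + 100 for _c, n, _i in rs.ids]

    def test_unmapped_residue_reported(self, tetramer_pair):
        structure, truth = tetramer_pair
        rs = ResidueSet(truth.pockets["A"], "pocket")
        with pytest.raises(SelectionError, match="unmapped"):
            map_residue_set(rs, structure, structure,
                            lambda r: (r[0], r[1] + 9999, r[2]))

    def test_transform_mapping_on_rotated_copy(self, tetramer_pair):
        from filadyn.structio import RigidTransform, ca_array
        structure, truth = tetramer_pair
        rot = _rotation([0, 1, 0], 55.0)
        t = RigidTransform(rot, np.array([10.0, 0.0, -4.0]))
        target = structure.transformed(t)
        rs = ResidueSet(truth.pockets["A"], "pocket")
        mapped = map_residue_set(rs, structure, target, t)
        assert sorted(mapped.ids) == sorted(rs.ids)


class TestResidueSetIO:
    def test_tsv_roundtrip(self, tetramer_pair, tmp_path):
        structure, truth = tetramer_pair
        rs = ResidueSet(truth.pockets["A"], "pocket")
        path = tmp_path / "set.tsv"
        rs.to_tsv(path, structure)
        back = ResidueSet.from_tsv(path)
        assert back.ids == rs.ids
        assert back.label == "pocket"

    def test_duplicates_rejected(self):
        with pytest.raises(SelectionError):
            ResidueSet([("A", 1, ""), ("A", 1, "")])
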