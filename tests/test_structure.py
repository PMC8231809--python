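"""Geometry: parsing, Shrake-Rupley SASA, burial, interfaces, secondary structure."""

import math

import numpy as np
import pytest

from tp53conform.simulate import ToyStructureSpec, make_toy_structure
from tp53conform.structure import (
    SSRange,
    assign_secondary_structure,
    atom_sasa,
    burial_from_structure,
    classify_burial,
    compute_sasa,
    find_interface_residues,
    load_structure,
    per_chain_residue_sasa,
    sphere_points,
)


class TestLoadStructure:
    def test_minimal_pdb(self, mini_pdb):
        st = load_structure(mini_pdb)
        assert len(st.atoms) == 3
        assert st.protein_chains() == ["A"]
        assert st.chain_class["A"] == "protein"
        # author numbering inside the DBD range maps onto canonical positions
        assert st.canonical_map[("A", 100)] == 100

    def test_altloc_keeps_highest_occupancy(self, altloc_pdb):
        st = load_structure(altloc_pdb)
        ca = [a for a in st.atoms if a.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0].position[0] == pytest.approx(1.0)  # the occ-0.60 conformer

    def test_unknown_element_raises_naming_atom(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text(
            "ATOM      1 FE   ALA A 100       0.000   0.000   0.000  1.00  0.00"
            "          FE\nEND\n"
        )
        with pytest.raises(KeyError, match="FE"):
            load_structure(bad)

    def test_unparseable_or_empty(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(ValueError):
            load_structure(empty)

    def test_canonical_positions_outside_ranges_are_none(self, tmp_path):
        p = tmp_path / "out.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A 300       0.000   0.000   0.000  1.00  0.00"
            "           C\nEND\n"
        )
        st = load_structure(p)
        assert st.canonical_map[("A", 300)] is None
        assert st.canonical_positions() == set()


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = make_toy_structure(ToyStructureSpec("isolated"))
        [res] = compute_sasa(st, probe_radius=1.4, n_sphere_points=960)
        analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert res.sasa == pytest.approx(analytic, rel=1e-9)  # all points accessible

    def test_distant_pair_has_no_occlusion(self):
        st = make_toy_structure(ToyStructureSpec("pair", spacing=20.0))
        analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
        for res in compute_sasa(st):
            assert res.sasa == pytest.approx(analytic, rel=1e-9)

    def test_cluster_matches_monte_carlo_rejection_oracle(self, cluster_structure):
        """Point-sampled per-atom SASA vs an independent MC rejection oracle."""
        sub_atoms = cluster_structure.atoms[:12]
        from tp53conform.structure import structure_from_atoms

        st = structure_from_atoms(sub_atoms)
        areas = atom_sasa(st, probe_radius=1.4, n_sphere_points=3840)

        rng = np.random.default_rng(0)
        coords = st.coordinates()
        radii = st.radii() + 1.4
        n_mc = 300_000
        for i in range(len(coords)):
            # uniform random directions on the expanded sphere
            v = rng.normal(size=(n_mc, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = coords[i] + radii[i] * v
            outside = np.ones(n_mc, dtype=bool)
            for j in range(len(coords)):
                if j == i:
                    continue
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                outside &= d2 >= radii[j] ** 2
            mc_area = 4.0 * math.pi * radii[i] ** 2 * outside.mean()
            if mc_area > 1.0:
                assert areas[i] == pytest.approx(mc_area, rel=0.02)
            else:  # nearly buried atoms: absolute tolerance
                assert abs(areas[i] - mc_area) < 0.5

    def test_point_count_refinement_is_stable(self, contact_structure):
        coarse = {(r.chain_id, r.residue_number): r.sasa
                  for r in compute_sasa(contact_structure, n_sphere_points=960)}
        fine = {(r.chain_id, r.residue_number): r.sasa
                for r in compute_sasa(contact_structure, n_sphere_points=3840)}
        for key, c in coarse.items():
            assert abs(c - fine[key]) <= 0.01 * fine[key]

    def test_atom_sasa_bounded_by_full_sphere(self, cluster_structure):
        areas = atom_sasa(cluster_structure)
        caps = 4.0 * math.pi * (cluster_structure.radii() + 1.4) ** 2
        assert (areas >= 0).all() and (areas <= caps + 1e-9).all()

    def test_empty_structure_rejected(self):
        from tp53conform.structure import StructureModel

        with pytest.raises(ValueError):
            atom_sasa(StructureModel([], {}, {}))

    def test_sphere_points_are_unit_and_spread(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01


class TestBurial:
    def test_any_chain_rule(self, cluster_structure):
        sasa = {"A": {100: 10.9}, "B": {100: 25.0}, "C": {100: 30.0}, "D": {100: 28.0}}
        st = cluster_structure  # only canonical_map matters; position 100 is mapped
        from tp53conform.structure import AtomRecord, structure_from_atoms

        atoms = [
            AtomRecord(c, 100, "ALA", "CA", "C", (i * 30.0, 0, 0), 1.7)
            for i, c in enumerate("ABCD")
        ]
        st = structure_from_atoms(atoms)
        [call] = classify_burial(st, sasa, cutoff=11.0)
        assert call.status == "Buried"
        assert call.per_chain_sasa == sasa_flat(sasa, 100)

    def test_strictly_below_cutoff(self):
        from tp53conform.structure import AtomRecord, structure_from_atoms

        atoms = [AtomRecord("A", 100, "ALA", "CA", "C", (0, 0, 0), 1.7)]
        st = structure_from_atoms(atoms)
        [call] = classify_burial(st, {"A": {100: 11.0}}, cutoff=11.0)
        assert call.status == "Surface"  # 11.0 is not < 11.0

    def test_absent_position_is_unknown(self, cluster_structure):
        calls = burial_from_structure(cluster_structure, query_positions=[379])
        status = {c.canonical_position: c.status for c in calls}
        assert status[379] == "unknown"

    def test_buried_set_monotone_in_cutoff(self, cluster_structure):
        """The cutoff ladder: Buried sets are nested as the cutoff loosens."""
        sasa = per_chain_residue_sasa(cluster_structure)
        previous: set[int] = set()
        for cutoff in (2.5, 5.0, 7.5, 10.0, 11.0):
            buried = {
                c.canonical_position
                for c in classify_burial(cluster_structure, sasa, cutoff)
                if c.status == "Buried"
            }
            assert previous <= buried
            previous = buried

    def test_compact_cluster_has_a_buried_residue(self, cluster_structure):
        calls = burial_from_structure(cluster_structure, cutoff=11.0)
        assert any(c.status == "Buried" for c in calls)


def sasa_flat(sasa, pos):
    return {chain: res[pos] for chain, res in sasa.items()}


class TestInterface:
    def test_distant_chains_have_no_interface(self):
        st = make_toy_structure(ToyStructureSpec("pair", spacing=50.0))
        # split the two residues into separate chains
        from tp53conform.structure import AtomRecord, structure_from_atoms

        atoms = [
            AtomRecord("A", 100, "ALA", "C1", "C", (0, 0, 0), 1.7),
            AtomRecord("B", 100, "ALA", "C1", "C", (50, 0, 0), 1.7),
        ]
        st = structure_from_atoms(atoms)
        assert find_interface_residues(st, ["A"], ["B"]) == []

    def test_touching_chains_match_sasa_difference_oracle(self, contact_structure):
        calls = find_interface_residues(contact_structure, ["A"], ["B"], cutoff=1.0)
        assert calls, "contact fixture must produce interface residues"
        # independent recomputation of isolated-minus-complex per residue
        iso = {}
        for chain in ("A", "B"):
            for rs in compute_sasa(contact_structure.subset([chain])):
                iso[(rs.chain_id, rs.residue_number)] = rs.sasa
        comp = {
            (rs.chain_id, rs.residue_number): rs.sasa
            for rs in compute_sasa(contact_structure)
        }
        for call in calls:
            key = (call.chain_id, call.residue_number)
            assert call.buried_area == pytest.approx(iso[key] - comp[key], abs=1e-9)
            assert call.buried_area > 1.0

    def test_symmetry_under_role_swap(self, contact_structure):
        ab = find_interface_residues(contact_structure, ["A"], ["B"])
        ba = find_interface_residues(contact_structure, ["B"], ["A"])
        key = lambda c: (c.chain_id, c.residue_number)
        assert {key(c): c.buried_area for c in ab} == {key(c): c.buried_area for c in ba}

    def test_overlapping_subsets_rejected(self, contact_structure):
        with pytest.raises(ValueError, match="overlap"):
            find_interface_residues(contact_structure, ["A"], ["A", "B"])

    def test_partner_class_for_dna(self):
        from tp53conform.structure import AtomRecord, structure_from_atoms

        atoms = [
            AtomRecord("A", 100, "ALA", "C1", "C", (0, 0, 0), 1.7),
            AtomRecord("E", 1, "DA", "P", "P", (3.0, 0, 0), 1.8),
        ]
        st = structure_from_atoms(atoms)
        calls = find_interface_residues(st, ["A"], ["E"], cutoff=0.5)
        partner = {c.chain_id: c.partner_class for c in calls}
        assert partner["A"] == "DNA"
        assert partner["E"] == "protein_monomer"


class TestSecondaryStructure:
    def test_no_annotations_all_loop(self, cluster_structure):
        assign = assign_secondary_structure(cluster_structure, annotations=[])
        assert set(assign.values()) == {"loop"}

    def test_helix_range_covers_exactly(self, cluster_structure):
        residues = sorted(r for _, r in cluster_structure.residues())
        lo, hi = residues[0], residues[2]
        assign = assign_secondary_structure(
            cluster_structure, [SSRange("helix", "A", lo, hi)]
        )
        helix = {r for (c, r), k in assign.items() if k == "helix"}
        assert helix == set(range(lo, hi + 1))

    def test_helix_wins_overlap(self, cluster_structure):
        residues = sorted(r for _, r in cluster_structure.residues())
        lo, hi = residues[0], residues[1]
        assign = assign_secondary_structure(
            cluster_structure,
            [SSRange("sheet", "A", lo, hi), SSRange("helix", "A", lo, hi)],
        )
        assert all(assign[("A", r)] == "helix" for r in range(lo, hi + 1))

    def test_out_of_structure_range_clipped_with_warning(self, cluster_structure):
        with pytest.warns(UserWarning, match="clipped"):
            assign = assign_secondary_structure(
                cluster_structure, [SSRange("helix", "A", 100, 999)]
            )
        assert "helix" in set(assign.values())

    def test_every_protein_residue_classified_once(self, contact_structure):
        assign = assign_secondary_structure(contact_structure, [])
        assert set(assign) == set(contact_structure.residues())
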