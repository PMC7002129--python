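import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import point_plane_rms, rotation_about_axis, random_rotation

from psipig.chlorin import (
    ChlorinError,
    RingPlane,
    c2_crowding,
    detect_axial_ligands,
    find_stacking_multimers,
    fit_plane,
    formyl_oxygen_probe,
    interplane_angle,
    locate_c2_substituent,
    map_ring_atoms,
)
from psipig.structure_io import Atom, Residue, StructureModel
from psipig.synthetic import (
    AxialSpec,
    DonorSpec,
    PlacementSpec,
    build_toy_structure,
    ideal_chlorin_template,
)


def drop_atoms(residue, names):
    return Residue(
        residue.key, residue.name, [a for a in residue.atoms if a.atom_name not in names]
    )


def rigid_copy(residue, rot, trans):
    atoms = [
        dataclasses.replace(a, position=tuple(rot @ a.xyz + np.asarray(trans)))
        for a in residue.atoms
    ]
    return Residue(residue.key, residue.name, atoms)


class TestRingMapping:
    def test_template_maps_completely(self, template):
        ring = map_ring_atoms(template)
        assert len(ring.atoms) == 25  # 24 macrocycle + MG
        assert ring.unmapped == ()

    def test_missing_nitrogen_warns_but_maps(self, template):
        ring_res = drop_atoms(template, {"NB"})  # CCD name of N21
        with pytest.warns(UserWarning, match="N21"):
            ring = map_ring_atoms(ring_res)
        assert "N21" in ring.unmapped

    def test_missing_mg_is_fatal(self, template):
        with pytest.raises(ChlorinError, match="MG"):
            map_ring_atoms(drop_atoms(template, {"MG"}))

    def test_too_many_missing_atoms_fatal(self, template):
        with pytest.raises(ChlorinError, match="unmapped"):
            map_ring_atoms(drop_atoms(template, {"C1B", "C2B", "C3B", "C4B", "CHC"}))

    def test_bond_length_validation_catches_wrong_table(self, template):
        # stretch one ring atom far out of bonding range
        atoms = [
            dataclasses.replace(a, position=(99.0, 0.0, 0.0))
            if a.atom_name == "C2B"
            else a
            for a in template.atoms
        ]
        bad = Residue(template.key, template.name, atoms)
        with pytest.raises(ChlorinError, match="outside"):
            map_ring_atoms(bad)


class TestPlaneFit:
    def test_template_is_exactly_planar(self, template):
        plane = fit_plane(map_ring_atoms(template))
        assert plane.rms <= 1e-9
        assert abs(np.linalg.norm(plane.normal) - 1.0) <= 1e-9

    @given(st.integers(0, 2**31 - 1))
    def test_rms_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        template = ideal_chlorin_template()
        # make it non-planar so the rms is informative
        atoms = list(template.atoms)
        atoms[5] = dataclasses.replace(atoms[5], position=tuple(atoms[5].xyz + [0, 0, 0.4]))
        res = Residue(template.key, template.name, atoms)
        rms0 = fit_plane(map_ring_atoms(res)).rms
        rot = random_rotation(rng)
        trans = rng.uniform(-50, 50, 3)
        rms1 = fit_plane(map_ring_atoms(rigid_copy(res, rot, trans))).rms
        assert rms1 == pytest.approx(rms0, abs=1e-9)

    def test_displaced_atom_rms_matches_direct_point_plane_oracle(self, template):
        ring = map_ring_atoms(template)
        coords = ring.macrocycle_coords()
        normal0 = np.asarray(fit_plane(ring).normal)
        coords[3] = coords[3] + 0.5 * normal0
        plane = fit_plane(coords)
        assert plane.rms == pytest.approx(
            point_plane_rms(coords, plane.normal, plane.centroid), abs=1e-12
        )

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ChlorinError, match="3 atoms"):
            fit_plane(np.array([[0.0, 0, 0], [1, 0, 0]]))


class TestInterplaneAngle:
    def test_self_angle_zero(self, template):
        plane = fit_plane(map_ring_atoms(template))
        assert interplane_angle(plane, plane) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_normals_fold_into_range(self):
        a = RingPlane((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), 0.0)
        # normal at 150 degrees from +z folds to 30
        n = (0.0, np.sin(np.radians(150)), np.cos(np.radians(150)))
        b = RingPlane(tuple(np.asarray(n) / np.linalg.norm(n)), (0.0, 0.0, 0.0), 0.0)
        assert interplane_angle(a, b) == pytest.approx(30.0, abs=1e-9)
        assert interplane_angle(b, a) == interplane_angle(a, b)

    def test_rotated_ring_recovers_rotation_angle(self, template):
        ring = map_ring_atoms(template)
        rot = rotation_about_axis([1.0, 0.0, 0.0], 25.0)  # in-plane axis
        rotated = map_ring_atoms(rigid_copy(template, rot, [0, 0, 0]))
        ang = interplane_angle(fit_plane(ring), fit_plane(rotated))
        assert ang == pytest.approx(25.0, abs=1e-6)
        assert 0.0 <= ang <= 90.0


class TestC2Substituent:
    def test_template_substituent_found_at_bond_length(self, template):
        sub = locate_c2_substituent(map_ring_atoms(template))
        assert sub.atom_name == "CMB"
        c2 = map_ring_atoms(template).atoms["C2"].xyz
        assert np.linalg.norm(sub.xyz - c2) == pytest.approx(1.50, abs=1e-9)

    def test_missing_substituent_reported(self, template):
        bare = drop_atoms(template, {"CMB"})
        with pytest.raises(ChlorinError, match="no substituent"):
            locate_c2_substituent(map_ring_atoms(bare))

    def test_two_substituents_ambiguous(self, template):
        ring = map_ring_atoms(template)
        c2 = ring.atoms["C2"].xyz
        extra = Atom("P", "CLA", 1, "CXX", "C", tuple(c2 + [0.0, 0.0, 1.5]))
        doubled = Residue(template.key, template.name, list(template.atoms) + [extra])
        with pytest.raises(ChlorinError, match="ambiguous"):
            locate_c2_substituent(map_ring_atoms(doubled))


class TestStacking:
    def test_planted_pair_found_with_exact_distance(self):
        model, truth = build_toy_structure(
            [PlacementSpec(), PlacementSpec(translation=(0, 0, 6.0))]
        )
        pairs, components = find_stacking_multimers(model)
        assert len(pairs) == 1
        assert pairs[0].mg_distance == pytest.approx(6.0, abs=1e-9)
        assert pairs[0].interplane_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert [len(c) for c in components] == [2]

    def test_far_pigments_not_paired(self):
        model, _ = build_toy_structure(
            [PlacementSpec(), PlacementSpec(translation=(0, 0, 12.0))]
        )
        pairs, components = find_stacking_multimers(model)
        assert pairs == []
        assert sorted(len(c) for c in components) == [1, 1]

    def test_chain_of_three_is_one_trimer_component(self):
        model, _ = build_toy_structure(
            [
                PlacementSpec(),
                PlacementSpec(translation=(0, 0, 6.0)),
                PlacementSpec(translation=(0, 0, 12.0)),
            ]
        )
        pairs, components = find_stacking_multimers(model)
        assert len(pairs) == 2  # 1-2 and 2-3; 1-3 is 12 A apart
        assert [len(c) for c in components] == [3]

    def test_output_independent_of_enumeration_order(self):
        specs = [
            PlacementSpec(),
            PlacementSpec(translation=(0, 0, 6.0)),
            PlacementSpec(translation=(40.0, 0, 0)),
        ]
        model, _ = build_toy_structure(specs)
        reordered = StructureModel(list(model)[::-1])
        p1, c1 = find_stacking_multimers(model)
        p2, c2 = find_stacking_multimers(reordered)
        key = lambda p: (p.site_a, p.site_b)
        assert sorted(map(key, p1)) == sorted(map(key, p2))
        assert sorted(map(sorted, c1)) == sorted(map(sorted, c2))


class TestAxialLigands:
    def test_planted_his_detected_with_exact_distance(self, toy_pair):
        model, truth = toy_pair
        ligs = detect_axial_ligands(model[("P", 1, "")], model)
        his = [l for l in ligs if l.ligand_class == "HIS_SIDECHAIN"]
        assert len(his) == 1
        assert his[0].distance == pytest.approx(2.15, abs=1e-9)

    def test_empty_when_nothing_in_window(self):
        model, _ = build_toy_structure([PlacementSpec()])
        assert detect_axial_ligands(model[("P", 1, "")], model) == []

    def test_window_is_respected(self):
        model, _ = build_toy_structure(
            [PlacementSpec(axial=AxialSpec(distance=3.5))]
        )
        assert detect_axial_ligands(model[("P", 1, "")], model) == []
        ligs = detect_axial_ligands(model[("P", 1, "")], model, window=(1.9, 4.0))
        assert len(ligs) == 1


class TestCrowding:
    def test_isolated_pigment_reports_no_contacts(self):
        model, _ = build_toy_structure([PlacementSpec()])
        ring = map_ring_atoms(model[("P", 1, "")])
        report = c2_crowding(ring, model)
        assert report.n_contacts == 0
        assert report.min_distance is None

    def test_planted_contact_at_exact_distance(self):
        model, _ = build_toy_structure([PlacementSpec()])
        ring = map_ring_atoms(model[("P", 1, "")])
        probe = formyl_oxygen_probe(ring)
        clash = Residue(
            ("X", 1, ""),
            "ALA",
            [Atom("X", "ALA", 1, "CB", "C", tuple(probe + np.array([2.0, 0, 0])))],
        )
        crowded = StructureModel(list(model) + [clash])
        report = c2_crowding(ring, crowded)
        assert report.n_contacts == 1
        assert report.min_distance == pytest.approx(2.0, abs=1e-9)

    def test_probe_point_matches_independent_vector_arithmetic(self, template):
        ring = map_ring_atoms(template)
        probe = formyl_oxygen_probe(ring, extension=1.2)
        c2 = ring.atoms["C2"].xyz
        sub = locate_c2_substituent(ring).xyz
        u = (sub - c2) / np.linalg.norm(sub - c2)
        assert np.allclose(probe, sub + 1.2 * u, atol=1e-9)


@given(st.integers(0, 2**31 - 1))
def test_pairwise_distances_match_bruteforce_oracle(seed):
    """Mg-Mg distances reported by stacking agree with direct arithmetic."""
    rng = np.random.default_rng(seed)
    n = 3
    offsets = [rng.uniform(-1, 1, 3) + np.array([16.0 * i, 0, 0]) for i in range(n)]
    model, _ = build_toy_structure(
        [PlacementSpec(translation=tuple(o)) for o in offsets]
    )
    pairs, _ = find_stacking_multimers(model, mg_cutoff=1e6)
    mgs = {res.key: res.atom("MG").xyz for res in model.chlorophylls()}
    for p in pairs:
        expected = float(np.linalg.norm(mgs[p.site_a] - mgs[p.site_b]))
        assert p.mg_distance == pytest.approx(expected, abs=1e-9)
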