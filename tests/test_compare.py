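import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from oracles import optimal_site_matching, random_rotation, rotation_about_axis

from psipig.compare import (
    ChainPairing,
    SuperpositionError,
    compare_axial_ligands,
    kabsch_superpose,
    match_pigment_sites,
    transfer_site_labels,
)
from psipig.structure_io import Atom, Residue, StructureModel
from psipig.synthetic import (
    AxialSpec,
    PlacementSpec,
    build_toy_structure,
)


def transformed(model, rot, trans):
    residues = []
    for res in model:
        atoms = [
            dataclasses.replace(a, position=tuple(rot @ a.xyz + np.asarray(trans)))
            for a in res.atoms
        ]
        residues.append(Residue(res.key, res.name, atoms))
    return StructureModel(residues)


class TestKabsch:
    def test_identical_sets_identity_transform(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-10, 10, (20, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd <= 1e-9
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rotated_set_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-10, 10, (15, 3))
        rot = rotation_about_axis([0, 0, 1.0], 90.0)
        sup = kabsch_superpose(pts @ rot.T, pts)
        assert sup.rmsd <= 1e-9
        assert np.allclose(sup.rotation @ rot, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_rmsd_matches_direct_residual_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(-20, 20, (100, 3))
        rot = random_rotation(rng)
        query = (ref + rng.normal(0, 0.1, ref.shape)) @ rot.T + np.array([5.0, -3.0, 2.0])
        sup = kabsch_superpose(query, ref)
        resid = sup.apply(query) - ref
        assert sup.rmsd == pytest.approx(
            float(np.sqrt((resid**2).sum() / len(ref))), abs=1e-12
        )

    def test_cross_check_against_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(-10, 10, (30, 3))
        rot = random_rotation(rng)
        query = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        sup = kabsch_superpose(query, ref)
        r_scipy, _ = Rotation.align_vectors(
            ref - ref.mean(0), query - query.mean(0)
        )
        assert np.allclose(sup.rotation, r_scipy.as_matrix(), atol=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(SuperpositionError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SuperpositionError, match="collinear"):
            kabsch_superpose(line, line)

    @given(st.integers(0, 2**31 - 1))
    def test_rmsd_invariant_under_rigid_pretransformation(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-10, 10, (12, 3))
        query = ref + rng.normal(0, 0.2, ref.shape)
        base = kabsch_superpose(query, ref).rmsd
        rot = random_rotation(rng)
        moved = query @ rot.T + rng.uniform(-30, 30, 3)
        assert kabsch_superpose(moved, ref).rmsd == pytest.approx(base, abs=1e-9)
        assert np.linalg.det(kabsch_superpose(moved, ref).rotation) == pytest.approx(
            1.0, abs=1e-9
        )


def toy_model(n=3, spacing=16.0):
    model, _ = build_toy_structure(
        [PlacementSpec(translation=(spacing * i, 0, 0)) for i in range(n)]
    )
    return model


class TestSiteMatching:
    def test_self_match_all_conserved_zero_displacement(self):
        model = toy_model(3)
        corr = match_pigment_sites(model, model)
        assert all(c.status == "conserved" for c in corr)
        assert all(c.mg_displacement == pytest.approx(0.0, abs=1e-12) for c in corr)

    def test_deleted_pigment_is_lost(self):
        ref = toy_model(3)
        query = StructureModel([r for r in ref if r.key != ("P", 2, "")])
        corr = match_pigment_sites(query, ref)
        lost = [c for c in corr if c.status == "lost"]
        assert len(lost) == 1
        assert lost[0].reference_site == ("P", 2, "")

    def test_added_pigment_is_gained(self):
        ref = toy_model(2)
        extra, _ = build_toy_structure([PlacementSpec(translation=(60.0, 0, 0))])
        query = StructureModel(
            list(ref)
            + [Residue(("P", 9, ""), "CLA", extra[("P", 1, "")].atoms)]
        )
        corr = match_pigment_sites(query, ref)
        gained = [c for c in corr if c.status == "gained"]
        assert len(gained) == 1
        assert gained[0].query_site == ("P", 9, "")

    @given(st.integers(0, 2**31 - 1))
    def test_greedy_matches_exhaustive_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        ref_pts = np.array([[20.0 * i, 0, 0] for i in range(n)])
        # query: each site jittered well under half the cutoff
        q_pts = ref_pts + rng.uniform(-0.8, 0.8, ref_pts.shape)
        pairs = []
        for qi in range(n):
            for ri in range(n):
                d = float(np.linalg.norm(q_pts[qi] - ref_pts[ri]))
                if d <= 2.5:
                    pairs.append((d, qi, ri))
        pairs.sort()
        used_q, used_r, greedy = set(), set(), set()
        for d, qi, ri in pairs:
            if qi not in used_q and ri not in used_r:
                used_q.add(qi)
                used_r.add(ri)
                greedy.add((qi, ri))
        assert greedy == optimal_site_matching(q_pts, ref_pts, 2.5)


class TestLabelsAndLigands:
    def test_reference_numbering_transferred(self):
        ref_res = build_toy_structure([PlacementSpec()])[0][("P", 1, "")]
        atoms = [
            dataclasses.replace(a, chain_id="A", residue_number=1120)
            for a in ref_res.atoms
        ]
        ref = StructureModel([Residue(("A", 1120, ""), "CLA", atoms)])
        q_atoms = [dataclasses.replace(a, chain_id="Q", residue_number=5) for a in ref_res.atoms]
        query = StructureModel([Residue(("Q", 5, ""), "CLA", q_atoms)])
        corr = match_pigment_sites(query, ref)
        labels = transfer_site_labels(query, ref, corr)
        assert labels[("Q", 5, "")] == "A20"

    def test_label_pads_to_two_digits(self):
        ref_res = build_toy_structure([PlacementSpec()])[0][("P", 1, "")]
        atoms = [
            dataclasses.replace(a, chain_id="A", residue_number=1402)
            for a in ref_res.atoms
        ]
        ref = StructureModel([Residue(("A", 1402, ""), "CLA", atoms)])
        corr = match_pigment_sites(ref, ref)
        labels = transfer_site_labels(ref, ref, corr)
        assert labels[("A", 1402, "")] == "A02"

    def test_gained_pigment_gets_new_suffix(self):
        ref = toy_model(1)
        extra, _ = build_toy_structure([PlacementSpec(translation=(50.0, 0, 0))])
        query = StructureModel(
            list(ref) + [Residue(("P", 9, ""), "CLA", extra[("P", 1, "")].atoms)]
        )
        corr = match_pigment_sites(query, ref)
        labels = transfer_site_labels(query, ref, corr)
        assert labels[("P", 9, "")] == "Pnew1"

    def test_identical_models_no_axial_changes(self):
        model, _ = build_toy_structure(
            [PlacementSpec(axial=AxialSpec(distance=2.15))]
        )
        corr = match_pigment_sites(model, model)
        rows = compare_axial_ligands(corr, model, model)
        assert len(rows) == 1
        assert not rows[0]["changed"]
        assert rows[0]["query_ligand"] == "HIS_SIDECHAIN"

    def test_removed_his_reported_as_change(self):
        ref, _ = build_toy_structure([PlacementSpec(axial=AxialSpec(distance=2.15))])
        query = StructureModel([r for r in ref if r.chain_id != "L"])
        corr = match_pigment_sites(query, ref)
        rows = compare_axial_ligands(corr, query, ref)
        assert rows[0]["changed"]
        assert rows[0]["reference_ligand"] == "HIS_SIDECHAIN"
        assert rows[0]["query_ligand"] == "none"

    def test_lipid_headgroup_ligand_class_representable(self):
        model, _ = build_toy_structure(
            [
                PlacementSpec(
                    axial=AxialSpec(distance=2.4, residue_name="LHG", atom_name="O13")
                )
            ]
        )
        from psipig.chlorin import detect_axial_ligands

        ligs = detect_axial_ligands(model[("P", 1, "")], model)
        assert ligs[0].ligand_class == "LIPID_HEADGROUP"


def test_chain_pairing_requires_monotone_pairs():
    with pytest.raises(SuperpositionError, match="strictly increase"):
        ChainPairing(
            "A",
            "B",
            ((("A", 2, ""), ("B", 1, "")), (("A", 1, ""), ("B", 2, ""))),
        )
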