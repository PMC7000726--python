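"""Torsions, ω planarity, Ramachandran regions and salt bridges."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exstab.errors import UndefinedTorsionError
from exstab.geometry import (CHAIN_BREAK_DISTANCE, backbone_torsions,
                             classify_omega, count_nonplanar, dihedral,
                             find_salt_bridges, flank_composition,
                             ramachandran_classify)
from exstab.io import Atom, Chain, Residue, Structure
from exstab.synthetic import (BackboneSpec, build_backbone, helix_spec,
                              plant_salt_bridge)


class TestDihedral:
    def test_planar_trans(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == \
            pytest.approx(180.0)

    def test_planar_cis(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pts = rng.normal(size=(4, 3))
            angle = dihedral(*pts)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-angle, abs=1e-9) or (
                abs(angle) == pytest.approx(180.0))

    def test_sign_convention_matches_reference(self):
        # Bio.PDB implements the IUPAC convention independently
        from Bio.PDB.vectors import Vector, calc_dihedral

        rng = np.random.default_rng(10)
        for _ in range(10):
            pts = rng.normal(size=(4, 3))
            ref = math.degrees(calc_dihedral(*[Vector(*p) for p in pts]))
            assert dihedral(*pts) == pytest.approx(ref, abs=1e-9)

    def test_collinear_is_undefined(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_coincident_points_undefined(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 1, 0), (2, 1, 0))


class TestClassifyOmega:
    @pytest.mark.parametrize("omega,expected", [
        (180.0, "trans_planar"),
        (-180.0, "trans_planar"),
        (165.0, "trans_nonplanar"),
        (-165.0, "trans_nonplanar"),
        (0.0, "cis_planar"),
        (25.0, "cis_nonplanar"),
        (-25.0, "cis_nonplanar"),
        # boundary probes for the trans threshold at 170
        (169.99, "trans_nonplanar"),
        (170.01, "trans_planar"),
        (-169.99, "trans_nonplanar"),
        (-170.01, "trans_planar"),
        # boundary probes for the cis threshold at 20
        (19.99, "cis_planar"),
        (20.01, "cis_nonplanar"),
        (-19.99, "cis_planar"),
        (-20.01, "cis_nonplanar"),
    ])
    def test_thresholds(self, omega, expected):
        assert classify_omega(omega) == expected

    @given(st.floats(min_value=-179.999, max_value=180.0))
    def test_total_partition(self, omega):
        assert classify_omega(omega) in (
            "trans_planar", "trans_nonplanar", "cis_planar", "cis_nonplanar")


class TestBackboneTorsions:
    def test_round_trip_recovers_planted_angles(self):
        spec = BackboneSpec(
            "GAVLK",
            [(-57.0, -47.0, 180.0),
             (-57.0, -47.0, 180.0),
             (-119.0, 131.0, 165.0),
             (61.0, 43.0, -178.0),
             (-57.0, -47.0, -170.5)],
        )
        chain = build_backbone(spec).chains[0]
        recs = backbone_torsions(chain)
        for i in range(1, 5):
            assert recs[i].phi == pytest.approx(spec.torsions[i][0], abs=1e-6)
            assert recs[i].omega == pytest.approx(spec.torsions[i][2], abs=1e-6)
        for i in range(0, 4):
            assert recs[i].psi == pytest.approx(spec.torsions[i][1], abs=1e-6)

    def test_termini_undefined(self):
        chain = build_backbone(helix_spec("GAVLK")).chains[0]
        recs = backbone_torsions(chain)
        assert recs[0].phi is None and recs[0].omega is None
        assert recs[-1].psi is None
        assert recs[0].omega_class == "undefined"

    def test_planted_nonplanar_omega_reported(self):
        spec = helix_spec("GAVLKA")
        torsions = list(spec.torsions)
        torsions[3] = (-57.0, -47.0, 165.0)
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        recs = backbone_torsions(chain)
        assert recs[3].omega == pytest.approx(165.0, abs=1e-6)
        assert recs[3].omega_class == "trans_nonplanar"

    def test_chain_break_undefines_angles(self):
        st_full = build_backbone(helix_spec("GAVLKA"))
        chain = st_full.chains[0]
        # translate the second half far away: C(2)-N(3) >> 2.5 Å
        for res in chain.residues[3:]:
            for atom in res.atoms:
                atom.position = atom.position + np.array([50.0, 0.0, 0.0])
        recs = backbone_torsions(chain)
        assert recs[3].phi is None and recs[3].omega is None
        assert recs[2].psi is None
        assert recs[4].phi is not None  # geometry intact after the break

    def test_missing_backbone_atom_not_fatal(self):
        chain = build_backbone(helix_spec("GAVLKA")).chains[0]
        res = chain.residues[2]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        recs = backbone_torsions(chain)
        assert recs[2].phi is None and recs[2].omega is None


class TestCountNonplanar:
    def test_planted_counts(self):
        spec = helix_spec("A" * 10)
        torsions = list(spec.torsions)
        for idx in (3, 5, 7):
            torsions[idx] = (-57.0, -47.0, 160.0)
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        assert count_nonplanar(chain) == 3

    def test_all_planar(self):
        chain = build_backbone(helix_spec("A" * 10)).chains[0]
        assert count_nonplanar(chain) == 0

    @pytest.mark.parametrize("omega,expected", [
        (169.5, 1), (170.5, 0), (20.5, 1), (19.5, 0)])
    def test_threshold_boundaries_via_builder(self, omega, expected):
        spec = helix_spec("AAAA")
        torsions = list(spec.torsions)
        torsions[2] = (-57.0, -47.0, omega)
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        assert count_nonplanar(chain) == expected

    def test_matches_brute_force_over_omega_records(self):
        rng = np.random.default_rng(21)
        spec = helix_spec("A" * 20)
        torsions = [(-57.0, -47.0, float(rng.uniform(-180, 180)))
                    for _ in range(20)]
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        recs = backbone_torsions(chain)
        by_scan = sum(
            1 for r in recs if r.omega is not None
            and ((abs(r.omega) > 90 and abs(r.omega) < 170)
                 or (abs(r.omega) <= 90 and abs(r.omega) > 20)))
        assert count_nonplanar(chain) == by_scan


class TestFlankComposition:
    def test_single_nonplanar_bond_flanks(self):
        spec = helix_spec("GAVLK")
        torsions = list(spec.torsions)
        torsions[1] = (-57.0, -47.0, 160.0)  # bond between GLY(0) and ALA(1)
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        counts = flank_composition(chain)
        assert counts["omega_a"] == {"GLY": 1}
        assert counts["omega_b"] == {"ALA": 1}

    def test_no_nonplanar_bonds(self):
        chain = build_backbone(helix_spec("GAVLK")).chains[0]
        counts = flank_composition(chain)
        assert counts == {"omega_a": {}, "omega_b": {}}

    def test_totals_conserved(self):
        rng = np.random.default_rng(2)
        spec = helix_spec("ACDEFGHIKLMNPQRSTVWY")
        torsions = [(-57.0, -47.0, float(rng.choice([180.0, 160.0])))
                    for _ in range(20)]
        chain = build_backbone(BackboneSpec(spec.sequence, torsions)).chains[0]
        n = count_nonplanar(chain)
        counts = flank_composition(chain)
        assert sum(counts["omega_a"].values()) == n
        assert sum(counts["omega_b"].values()) == n


class TestRamachandran:
    @pytest.mark.parametrize("phi,psi,label", [
        (-60.0, -45.0, "alpha_R"),
        (-120.0, 130.0, "beta"),
        (60.0, 45.0, "alpha_L"),
        (0.0, 0.0, "other"),
    ])
    def test_default_regions(self, phi, psi, label):
        assert ramachandran_classify(phi, psi) == label

    def test_helix_spec_classifies_alpha(self):
        chain = build_backbone(helix_spec("A" * 8)).chains[0]
        recs = backbone_torsions(chain)
        labels = {ramachandran_classify(r.phi, r.psi)
                  for r in recs if r.phi is not None and r.psi is not None}
        assert labels == {"alpha_R"}


class TestSaltBridges:
    def test_planted_bridge_detected(self):
        st = build_backbone(helix_spec("A" * 20))
        plant_salt_bridge(st, 2, 10, 3.0)
        bridges = find_salt_bridges(st, cutoff=3.2)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.0, abs=1e-9)
        assert (bridges[0].oxygen, bridges[0].nitrogen) == ("OD1", "NZ")

    def test_beyond_cutoff_not_detected(self):
        st = build_backbone(helix_spec("A" * 20))
        plant_salt_bridge(st, 2, 10, 3.5)
        assert find_salt_bridges(st, cutoff=3.2) == []

    def test_residue_pair_deduplication(self):
        # one NZ within the cutoff of both carboxylate oxygens -> 1 bridge
        asp = Residue("ASP", 1, atoms=[
            Atom("OD1", "O", [0.0, 0.0, 0.0]),
            Atom("OD2", "O", [1.0, 0.0, 0.0]),
        ])
        lys = Residue("LYS", 2, atoms=[Atom("NZ", "N", [0.5, 2.8, 0.0])])
        st = Structure("toy", [Chain("A", [asp, lys])])
        bridges = find_salt_bridges(st, cutoff=3.2)
        assert len(bridges) == 1
        # closest oxygen recorded
        d1 = np.linalg.norm([0.5, 2.8, 0.0])
        d2 = np.linalg.norm([-0.5, 2.8, 0.0])
        assert bridges[0].distance == pytest.approx(min(d1, d2))

    def test_histidine_only_when_enabled(self):
        glu = Residue("GLU", 1, atoms=[Atom("OE1", "O", [0.0, 0.0, 0.0])])
        his = Residue("HIS", 2, atoms=[Atom("NE2", "N", [0.0, 3.0, 0.0])])
        st = Structure("toy", [Chain("A", [glu, his])])
        assert find_salt_bridges(st) == []
        assert len(find_salt_bridges(st, include_his=True)) == 1

    def test_count_invariant_under_rigid_transform(self):
        from scipy.spatial.transform import Rotation

        st = build_backbone(helix_spec("A" * 30))
        plant_salt_bridge(st, 2, 12, 3.0)
        plant_salt_bridge(st, 5, 20, 2.9)
        n_before = len(find_salt_bridges(st))
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        for res in st.chains[0].residues:
            for atom in res.atoms:
                atom.position = rot @ atom.position + np.array([5.0, -3.0, 8.0])
        assert len(find_salt_bridges(st)) == n_before == 2
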