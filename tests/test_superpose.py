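"""Kabsch superposition: rigid invariance, oracles, outlier rejection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from exstab.errors import DegenerateGeometryError, InsufficientPairsError
from exstab.io import chain_sequence
from exstab.align import needleman_wunsch
from exstab.superpose import (PairedCoordinates, kabsch, pair_ca_atoms,
                              refine_superposition)
from exstab.synthetic import build_backbone, helix_spec


def random_rigid(rng):
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-10, 10, size=3)
    return rot, trans


def brute_force_rmsd(a, b):
    """Independent oracle: numerical minimisation over rotation vectors
    started from a coarse orientation scan."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(((a0 @ r.T - b0) ** 2).sum() / len(a)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 5)
    for x in grid:
        for y in grid:
            for z in grid:
                res = minimize(cost, np.array([x, y, z]), method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 2000})
                best = min(best, res.fun)
    return best


@pytest.fixture
def cloud():
    rng = np.random.default_rng(42)
    return rng.normal(scale=5.0, size=(30, 3))


class TestKabsch:
    def test_identical_sets_give_zero(self, cloud):
        res = kabsch(PairedCoordinates(cloud, cloud.copy()))
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_transform_gives_zero(self, cloud):
        rng = np.random.default_rng(1)
        rot, trans = random_rigid(rng)
        moved = cloud @ rot.T + trans
        res = kabsch(PairedCoordinates(cloud, moved))
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3),
                           atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rotation_always_proper(self, cloud):
        # mirrored target tempts the fit into a reflection
        mirrored = cloud * np.array([1.0, 1.0, -1.0])
        res = kabsch(PairedCoordinates(cloud, mirrored))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0

    def test_four_point_toy_matches_minimization_oracle(self):
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        b = a.copy()
        b[0, 0] += 1.0  # displace one coordinate by 1 Å
        res = kabsch(PairedCoordinates(a, b))
        assert res.rmsd == pytest.approx(brute_force_rmsd(a, b), abs=1e-6)

    def test_random_cloud_matches_align_vectors(self, cloud):
        rng = np.random.default_rng(7)
        noisy = cloud + rng.normal(scale=0.5, size=cloud.shape)
        res = kabsch(PairedCoordinates(cloud, noisy))
        rot, rssd = Rotation.align_vectors(
            noisy - noisy.mean(axis=0), cloud - cloud.mean(axis=0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(cloud)),
                                         abs=1e-8)

    def test_symmetry(self, cloud):
        rng = np.random.default_rng(3)
        other = cloud + rng.normal(scale=1.0, size=cloud.shape)
        assert kabsch(PairedCoordinates(cloud, other)).rmsd == pytest.approx(
            kabsch(PairedCoordinates(other, cloud)).rmsd)

    def test_rmsd_invariant_under_common_rigid_transform(self, cloud):
        rng = np.random.default_rng(9)
        other = cloud + rng.normal(scale=1.0, size=cloud.shape)
        base = kabsch(PairedCoordinates(cloud, other)).rmsd
        rot, trans = random_rigid(rng)
        moved = kabsch(PairedCoordinates(cloud @ rot.T + trans,
                                         other @ rot.T + trans)).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_collinear_points_are_degenerate(self):
        line = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch(PairedCoordinates(line, line + 1.0))

    def test_too_few_pairs_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(InsufficientPairsError):
            PairedCoordinates(pts, pts)


class TestRefineSuperposition:
    def test_no_outliers_identical_to_plain_kabsch(self, cloud):
        rng = np.random.default_rng(4)
        other = cloud + rng.normal(scale=0.1, size=cloud.shape)
        pairs = PairedCoordinates(cloud, other)
        assert refine_superposition(pairs).rmsd == pytest.approx(
            kabsch(pairs).rmsd)

    def test_planted_outlier_rejected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(scale=5.0, size=(51, 3))
        b = a + rng.normal(scale=0.05, size=a.shape)
        baseline = kabsch(PairedCoordinates(a, b)).rmsd
        b_out = b.copy()
        b_out[25] += np.array([10.0, 0.0, 0.0])
        res = refine_superposition(PairedCoordinates(a, b_out))
        assert res.n_rejected == 1
        assert res.n_used == 50
        assert res.rmsd == pytest.approx(baseline, abs=0.02)

    def test_refined_never_worse_than_unrefined(self):
        rng = np.random.default_rng(12)
        a = rng.normal(scale=5.0, size=(40, 3))
        b = a + rng.normal(scale=1.5, size=a.shape)
        pairs = PairedCoordinates(a, b)
        assert refine_superposition(pairs).rmsd <= kabsch(pairs).rmsd + 1e-12

    def test_counts_conserved(self):
        rng = np.random.default_rng(13)
        a = rng.normal(scale=5.0, size=(30, 3))
        b = a + rng.normal(scale=1.5, size=a.shape)
        res = refine_superposition(PairedCoordinates(a, b))
        assert res.n_used + res.n_rejected == 30


class TestPairCaAtoms:
    def test_identical_chains_pair_every_residue(self):
        st = build_backbone(helix_spec("MKVLATGHIE"))
        chain = st.chains[0]
        aln = needleman_wunsch(chain_sequence(st, "A"), chain_sequence(st, "A"))
        pairs = pair_ca_atoms(aln, chain, chain)
        assert len(pairs) == 10

    def test_gap_columns_skipped(self):
        st_a = build_backbone(helix_spec("MKVLATGHIE"))
        st_b = build_backbone(helix_spec("MKVATGHIE"))  # L deleted
        aln = needleman_wunsch(chain_sequence(st_a, "A"),
                               chain_sequence(st_b, "A"))
        pairs = pair_ca_atoms(aln, st_a.chains[0], st_b.chains[0])
        assert len(pairs) == 9

    def test_residue_without_ca_skipped(self):
        st_a = build_backbone(helix_spec("MKVLATGHIE"))
        st_b = build_backbone(helix_spec("MKVLATGHIE"))
        st_b.chains[0].residues[4].atoms = [
            a for a in st_b.chains[0].residues[4].atoms if a.name != "CA"]
        aln = needleman_wunsch(chain_sequence(st_a, "A"),
                               chain_sequence(st_b, "A"))
        pairs = pair_ca_atoms(aln, st_a.chains[0], st_b.chains[0])
        assert len(pairs) == 9
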