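"""Synthetic sequence and structure generators.

Everything downstream of I/O can be exercised without downloads:

* :func:`sample_sequences` draws i.i.d. residues from group-biased
  compositions, emulating the compositional signal that separates
  extremostable proteins (enriched in Gly/Ala/Val/Ile, depleted in
  Gln/His/Met/Cys) from their mesophilic orthologs;
* :func:`build_backbone` places N/CA/C atoms by the natural-extension
  reference frame (NeRF) construction from ideal internal coordinates,
  so planted φ/ψ/ω torsions are recovered exactly by measurement;
* :func:`plant_salt_bridge` adds pseudo side-chain O/N atoms at a
  controlled separation;
* :func:`make_benchmark_pair` produces a rigidly transformed, noisy
  copy of a backbone whose post-fit RMSD is calibrated to a target.

The sequence model is deliberately minimal — independent multinomial
residues with no positional or phylogenetic correlation — because the
comparisons it feeds operate on composition only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import BackboneSpecError, PlacementError
from .io import AA1_TO_3, Atom, Chain, ProteinRecord, Residue, Structure

__all__ = [
    "GroupProfile",
    "BackboneSpec",
    "EXTREMOPHILE_PROFILE",
    "MESOPHILE_PROFILE",
    "sample_sequences",
    "build_backbone",
    "helix_spec",
    "plant_salt_bridge",
    "make_benchmark_pair",
    "make_ortholog_pair",
]

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# average globular-protein residue frequencies (approximate field values)
_BASE_FREQ = {
    "A": 0.083, "C": 0.014, "D": 0.054, "E": 0.062, "F": 0.039,
    "G": 0.072, "H": 0.022, "I": 0.053, "K": 0.058, "L": 0.091,
    "M": 0.022, "N": 0.043, "P": 0.047, "Q": 0.040, "R": 0.051,
    "S": 0.068, "T": 0.059, "V": 0.066, "W": 0.014, "Y": 0.032,
}


@dataclass(frozen=True)
class GroupProfile:
    """Residue-composition bias of a protein group."""

    name: str
    bias: dict[str, float]
    mean_length: float = 250.0
    length_sd: float = 30.0

    def __post_init__(self) -> None:
        total = sum(self.bias.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bias probabilities sum to {total}, not 1")
        if any(v < 0 for v in self.bias.values()):
            raise ValueError("negative probability")


def _shifted_profile(name: str, up: str, down: str, shift: float) -> GroupProfile:
    freq = dict(_BASE_FREQ)
    for aa in up:
        freq[aa] += shift
    for aa in down:
        freq[aa] = max(freq[aa] - shift * len(up) / len(down), 1e-4)
    total = sum(freq.values())
    return GroupProfile(name=name, bias={k: v / total for k, v in freq.items()})


#: Extremostable-group bias: G/A/V/I enriched, Q/H/M/C depleted.
EXTREMOPHILE_PROFILE = _shifted_profile("extremophile", "GAVI", "QHMC", 0.012)

#: Mesophilic counterpart: the unmodified background composition.
MESOPHILE_PROFILE = GroupProfile(
    name="mesophile",
    bias={k: v / sum(_BASE_FREQ.values()) for k, v in _BASE_FREQ.items()},
)


def sample_sequences(
    profile: GroupProfile, n: int, seed: int
) -> list[ProteinRecord]:
    """Draw ``n`` i.i.d.-residue sequences from a group profile."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(sorted(profile.bias))
    probs = np.array([profile.bias[a] for a in letters])
    probs = probs / probs.sum()
    records = []
    for i in range(n):
        length = max(10, int(round(rng.normal(profile.mean_length,
                                              profile.length_sd))))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(
            ProteinRecord(id=f"{profile.name}_{i:04d}", sequence=seq,
                          description=f"synthetic {profile.name} protein {i}")
        )
    return records


@dataclass(frozen=True)
class BackboneSpec:
    """Per-residue (φ, ψ, ω) targets and the residue-type sequence.

    The first φ, first ω and last ψ are unused by construction (those
    torsions do not exist at chain termini); any value may be supplied.
    """

    sequence: str
    torsions: Sequence[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.torsions):
            raise BackboneSpecError(
                f"{len(self.torsions)} torsion rows for "
                f"{len(self.sequence)} residues"
            )
        if len(self.sequence) < 2:
            raise BackboneSpecError("need at least 2 residues")


def helix_spec(sequence: str, phi: float = -57.0, psi: float = -47.0,
               omega: float = 180.0) -> BackboneSpec:
    """Uniform-torsion spec (an ideal α-helix by default)."""
    return BackboneSpec(sequence, [(phi, psi, omega)] * len(sequence))


def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A–B–C, |C–D|, angle B–C–D and torsion A–B–C–D."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-12:
        raise PlacementError("collinear reference frame")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(spec: BackboneSpec, chain_id: str = "A",
                   structure_id: str = "synthetic") -> Structure:
    """Place N/CA/C atoms sequentially from internal coordinates.

    Measured torsions on the result reproduce the spec's targets to
    well under 1e-6 degrees.
    """
    n_res = len(spec.sequence)
    coords: list[np.ndarray] = []

    # seed the first three atoms: N1 at origin, CA1 on +x, C1 in xy-plane
    n1 = np.zeros(3)
    ca1 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANGLE_N_CA_C)
    c1 = ca1 + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    coords.extend([n1, ca1, c1])

    for i in range(1, n_res):
        psi_prev = spec.torsions[i - 1][1]
        omega_i = spec.torsions[i][2]
        phi_i = spec.torsions[i][0]
        n_prev, ca_prev, c_prev = coords[3 * (i - 1): 3 * i]
        n_i = _nerf_place(n_prev, ca_prev, c_prev,
                          BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _nerf_place(ca_prev, c_prev, n_i,
                           BOND_N_CA, ANGLE_C_N_CA, omega_i)
        c_i = _nerf_place(c_prev, n_i, ca_i,
                          BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.extend([n_i, ca_i, c_i])

    residues = []
    for i, letter in enumerate(spec.sequence):
        name3 = AA1_TO_3.get(letter.upper(), "UNK")
        n_pos, ca_pos, c_pos = coords[3 * i: 3 * i + 3]
        residues.append(
            Residue(
                name=name3,
                seq_number=i + 1,
                atoms=[
                    Atom("N", "N", n_pos),
                    Atom("CA", "C", ca_pos),
                    Atom("C", "C", c_pos),
                ],
            )
        )
    return Structure(id=structure_id, chains=[Chain(chain_id, residues)])


def plant_salt_bridge(
    structure: Structure,
    acidic_at: int,
    basic_at: int,
    distance: float,
    chain_id: Optional[str] = None,
) -> Structure:
    """Add a pseudo Asp OD1 / Lys NZ contact at a given separation (Å).

    The named residues are relabelled ASP and LYS and each receives one
    contact atom, placed along the line between their Cα atoms so the
    O–N distance equals ``distance``. Indices are 0-based positions in
    the chain.
    """
    if distance <= 0:
        raise PlacementError("distance must be positive")
    chain = structure.chain(chain_id) if chain_id else structure.chains[0]
    try:
        res_acid = chain.residues[acidic_at]
        res_base = chain.residues[basic_at]
    except IndexError as exc:
        raise PlacementError(f"residue index out of range: {exc}") from exc
    ca_a = res_acid.atom("CA")
    ca_b = res_base.atom("CA")
    if ca_a is None or ca_b is None:
        raise PlacementError("both residues need a CA atom")
    axis = ca_b.position - ca_a.position
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise PlacementError("residues coincide; cannot orient side chains")
    axis = axis / norm
    midpoint = 0.5 * (ca_a.position + ca_b.position)
    pos_o = midpoint - 0.5 * distance * axis
    pos_n = midpoint + 0.5 * distance * axis
    res_acid.name = "ASP"
    res_base.name = "LYS"
    res_acid.atoms = [a for a in res_acid.atoms if a.name != "OD1"]
    res_base.atoms = [a for a in res_base.atoms if a.name != "NZ"]
    res_acid.atoms.append(Atom("OD1", "O", pos_o))
    res_base.atoms.append(Atom("NZ", "N", pos_n))
    return structure


def make_ortholog_pair(
    seed: int,
    length: int = 120,
    n_mutations: int = 20,
    rmsd_target: float = 0.5,
) -> tuple[Structure, Structure]:
    """A synthetic ortholog pair with controlled divergence.

    Both structures share one backbone conformation; the second carries
    ``n_mutations`` residue substitutions (setting the expected
    alignment identity to about ``100·(1 − n_mutations/length)``) and
    isotropic coordinate noise calibrated to ``rmsd_target`` Å, so
    sequence and structural divergence can be planted independently.
    """
    if not 0 <= n_mutations <= length:
        raise ValueError("n_mutations must be within [0, length]")
    rng = np.random.default_rng(seed)
    spec = _random_coil_spec(rng, length)
    ref = build_backbone(spec, structure_id="ortho_ref")
    seq = list(spec.sequence)
    for pos in rng.choice(length, size=n_mutations, replace=False):
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = str(rng.choice(choices))
    moved = build_backbone(
        BackboneSpec("".join(seq), spec.torsions), structure_id="ortho_var")
    sigma = rmsd_target / math.sqrt(3.0)
    if sigma > 0:
        for res in moved.chains[0].residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0, sigma, size=3)
    return ref, moved


def _random_coil_spec(rng: np.random.Generator, n_residues: int) -> BackboneSpec:
    letters = rng.choice(list(AMINO_ACIDS), size=n_residues)
    torsions = []
    for _ in range(n_residues):
        if rng.random() < 0.5:  # beta-ish
            phi = rng.uniform(-150, -90)
            psi = rng.uniform(110, 160)
        else:  # alpha-ish
            phi = rng.uniform(-70, -50)
            psi = rng.uniform(-55, -35)
        torsions.append((phi, psi, 180.0))
    return BackboneSpec("".join(letters), torsions)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_benchmark_pair(
    seed: int, rmsd_target: float, n_residues: int = 200
) -> tuple[Structure, Structure]:
    """A backbone and a rigidly moved, noise-perturbed copy.

    Isotropic Gaussian noise with per-axis σ = target/√3 gives an
    expected post-fit RMSD close to ``rmsd_target`` for chains long
    enough that the 6 fitted degrees of freedom are negligible.
    """
    if rmsd_target < 0:
        raise ValueError("rmsd_target must be >= 0")
    rng = np.random.default_rng(seed)
    spec = _random_coil_spec(rng, n_residues)
    ref = build_backbone(spec, structure_id="bench_ref")
    moved = build_backbone(spec, structure_id="bench_moved")
    rot = _random_rotation(rng)
    trans = rng.uniform(-20, 20, size=3)
    sigma = rmsd_target / math.sqrt(3.0)
    for res in moved.chains[0].residues:
        for atom in res.atoms:
            noisy = atom.position + rng.normal(0.0, sigma, size=3) \
                if sigma > 0 else atom.position
            atom.position = rot @ noisy + trans
    return ref, moved
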