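"""Backbone geometry: φ/ψ/ω torsions, peptide-bond planarity,
Ramachandran regions, flanking-residue statistics and salt bridges.

Torsion conventions (IUPAC sign, degrees in (−180, 180]):

    φ(i) = C(i−1)–N(i)–CA(i)–C(i)
    ψ(i) = N(i)–CA(i)–C(i)–N(i+1)
    ω(i) = CA(i−1)–C(i−1)–N(i)–CA(i)   (the peptide bond *preceding* i)

Angles are undefined at chain termini, across chain breaks (peptide
C–N distance above 2.5 Å) and wherever a backbone atom is missing.

The ω planarity classes follow unsigned thresholds on |ω|: a trans
bond (|ω| > 90°) is non-planar when |ω| < 170°, i.e. when it deviates
more than 10° from planarity; a cis bond is non-planar when |ω| > 20°.

A salt bridge is recorded once per (acidic, basic) residue pair with at
least one side-chain oxygen–nitrogen contact within the cutoff
(default 3.2 Å; Asp OD1/OD2 and Glu OE1/OE2 versus Lys NZ and
Arg NE/NH1/NH2, His ND1/NE2 optional); the closest atom pair is kept.
No angular criterion is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedTorsionError
from .io import Chain, Residue, Structure

__all__ = [
    "TorsionRecord",
    "FlankContext",
    "SaltBridge",
    "RamachandranRegion",
    "DEFAULT_REGIONS",
    "dihedral",
    "backbone_torsions",
    "classify_omega",
    "count_nonplanar",
    "flank_composition",
    "ramachandran_classify",
    "find_salt_bridges",
    "CHAIN_BREAK_DISTANCE",
]

#: Peptide C–N distance beyond which the chain is considered broken (Å).
CHAIN_BREAK_DISTANCE = 2.5

OMEGA_CLASSES = (
    "trans_planar", "trans_nonplanar", "cis_planar", "cis_nonplanar",
)

#: Side-chain contact atoms for salt-bridge detection.
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = {"HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class TorsionRecord:
    residue_index: int
    residue_name: str
    seq_number: int
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]
    omega_class: str  # one of OMEGA_CLASSES or "undefined"


@dataclass(frozen=True)
class FlankContext:
    """Residues flanking a peptide bond: before (ω_a) and after (ω_b)."""

    bond: tuple[int, int]
    omega_a: Optional[str]
    omega_b: Optional[str]


@dataclass(frozen=True)
class SaltBridge:
    acidic: str
    basic: str
    oxygen: str
    nitrogen: str
    distance: float


@dataclass(frozen=True)
class RamachandranRegion:
    label: str
    phi_min: float
    phi_max: float
    psi_min: float
    psi_max: float

    def contains(self, phi: float, psi: float) -> bool:
        return (self.phi_min <= phi <= self.phi_max
                and self.psi_min <= psi <= self.psi_max)


#: Rectangular core regions; anything else classifies as "other".
DEFAULT_REGIONS = (
    RamachandranRegion("beta", -180.0, -45.0, 90.0, 180.0),
    RamachandranRegion("alpha_R", -145.0, -35.0, -70.0, -10.0),
    RamachandranRegion("alpha_L", 35.0, 100.0, -20.0, 90.0),
)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 about the p2–p3 axis, degrees.

    Returns a value in (−180, 180] with the IUPAC sign convention
    (positive = clockwise rotation of p4 relative to p1 looking down
    p2→p3). Mirroring the points flips the sign.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise UndefinedTorsionError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise UndefinedTorsionError("collinear points: torsion undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m @ n2)
    angle = -math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def classify_omega(omega: float) -> str:
    """Planarity class of a peptide bond from its ω angle.

    Trans (|ω| > 90°) bonds are non-planar below 170°; cis bonds are
    non-planar above 20°. Together the four classes partition
    (−180, 180].
    """
    mag = abs(omega)
    if mag > 90.0:
        return "trans_nonplanar" if mag < 170.0 else "trans_planar"
    return "cis_nonplanar" if mag > 20.0 else "cis_planar"


def _backbone(res: Residue):
    return res.atom("N"), res.atom("CA"), res.atom("C")


def _try_dihedral(*points) -> Optional[float]:
    if any(p is None for p in points):
        return None
    try:
        return dihedral(*points)
    except UndefinedTorsionError:
        return None


def _bonded(prev: Residue, curr: Residue) -> bool:
    c = prev.atom("C")
    n = curr.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.position - n.position)) <= CHAIN_BREAK_DISTANCE


def backbone_torsions(chain: Chain) -> list[TorsionRecord]:
    """φ/ψ/ω per residue; undefined at termini, breaks or missing atoms."""
    records: list[TorsionRecord] = []
    residues = chain.residues
    for i, res in enumerate(residues):
        n_i, ca_i, c_i = _backbone(res)
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        prev_ok = prev_res is not None and _bonded(prev_res, res)
        next_ok = next_res is not None and _bonded(res, next_res)

        phi = psi = omega = None
        if prev_ok:
            c_prev = prev_res.atom("C")
            ca_prev = prev_res.atom("CA")
            pos = lambda a: a.position if a is not None else None
            phi = _try_dihedral(pos(c_prev), pos(n_i), pos(ca_i), pos(c_i))
            omega = _try_dihedral(pos(ca_prev), pos(c_prev), pos(n_i), pos(ca_i))
        if next_ok:
            n_next = next_res.atom("N")
            pos = lambda a: a.position if a is not None else None
            psi = _try_dihedral(pos(n_i), pos(ca_i), pos(c_i), pos(n_next))
        records.append(
            TorsionRecord(
                residue_index=i,
                residue_name=res.name,
                seq_number=res.seq_number,
                phi=phi,
                psi=psi,
                omega=omega,
                omega_class=classify_omega(omega) if omega is not None
                else "undefined",
            )
        )
    return records


def count_nonplanar(chain: Chain) -> int:
    """Number of defined ω angles classified as non-planar."""
    return sum(
        1 for rec in backbone_torsions(chain)
        if rec.omega_class in ("trans_nonplanar", "cis_nonplanar")
    )


def flank_composition(chain: Chain) -> dict[str, dict[str, int]]:
    """Residue-type counts flanking each non-planar peptide bond.

    The bond carrying ω(i) joins residue i−1 (the ω_a flank) to residue
    i (the ω_b flank). Counts per flank therefore each total the number
    of non-planar bonds whose flank residue exists.
    """
    counts = {"omega_a": {}, "omega_b": {}}
    residues = chain.residues
    for rec in backbone_torsions(chain):
        if rec.omega_class not in ("trans_nonplanar", "cis_nonplanar"):
            continue
        i = rec.residue_index
        before = residues[i - 1].name if i > 0 else None
        after = residues[i].name
        if before is not None:
            counts["omega_a"][before] = counts["omega_a"].get(before, 0) + 1
        counts["omega_b"][after] = counts["omega_b"].get(after, 0) + 1
    return counts


def ramachandran_classify(
    phi: float,
    psi: float,
    regions: Sequence[RamachandranRegion] = DEFAULT_REGIONS,
) -> str:
    """Label of the first region rectangle containing (φ, ψ), else "other"."""
    for region in regions:
        if region.contains(phi, psi):
            return region.label
    return "other"


def _charged_atoms(res: Residue, table: dict[str, tuple[str, ...]]):
    names = table.get(res.name)
    if not names:
        return []
    return [a for name in names if (a := res.atom(name)) is not None]


def find_salt_bridges(
    structure: Structure,
    cutoff: float = 3.2,
    include_his: bool = False,
) -> list[SaltBridge]:
    """Distance-based salt-bridge detection over all chains.

    One bridge per (acidic residue, basic residue) pair with any
    side-chain O–N contact within ``cutoff`` Å; the closest contact is
    recorded. His nitrogens count as basic only when ``include_his``.
    """
    basic_table = dict(BASIC_ATOMS)
    if include_his:
        basic_table.update(HIS_ATOMS)

    acidic_sites = []
    basic_sites = []
    for chain in structure.chains:
        for res in chain.residues:
            ref = f"{chain.id}/{res.name}{res.seq_number}{res.insertion_code}"
            for atom in _charged_atoms(res, ACIDIC_ATOMS):
                acidic_sites.append((ref, atom))
            for atom in _charged_atoms(res, basic_table):
                basic_sites.append((ref, atom))

    best: dict[tuple[str, str], SaltBridge] = {}
    for ref_a, atom_o in acidic_sites:
        for ref_b, atom_n in basic_sites:
            d = float(np.linalg.norm(atom_o.position - atom_n.position))
            if d > cutoff:
                continue
            key = (ref_a, ref_b)
            if key not in best or d < best[key].distance:
                best[key] = SaltBridge(
                    acidic=ref_a, basic=ref_b,
                    oxygen=atom_o.name, nitrogen=atom_n.name,
                    distance=d,
                )
    return sorted(best.values(), key=lambda sb: (sb.acidic, sb.basic))
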