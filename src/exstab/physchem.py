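"""Sequence-level physicochemical descriptors.

Net charge as a function of pH follows the Henderson–Hasselbalch model:
every ionisable group contributes a fractional charge

    basic:   +1 / (1 + 10^(pH - pKa))
    acidic:  -1 / (1 + 10^(pKa - pH))

summed over side chains (D, E, C, Y acidic; H, K, R basic) and the two
termini. The isoelectric point is the unique root of this strictly
decreasing function, found by bisection on [0, 14].

The default pKa table uses EMBOSS-style values. Residue class sets for
the hydrophobic / polar / nonpolar percentages are explicit and
swappable because the conventions differ between tools; the defaults
are declared, not inferred from any particular web service.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import FrozenSet, Mapping, Union

from .io import ProteinRecord

__all__ = [
    "PKaTable",
    "DEFAULT_PKA",
    "PhyschemProfile",
    "HYDROPHOBIC_RESIDUES",
    "POLAR_RESIDUES",
    "net_charge",
    "isoelectric_point",
    "residue_class_fractions",
    "physchem_profile",
]

#: Default hydrophobic residue class.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWCGP")

#: Default polar residue class; nonpolar is the complement of the 20.
POLAR_RESIDUES = frozenset("DEHKNQRST")


def _check_pka(value: float, what: str) -> float:
    if not 0.0 < value < 14.0:
        raise ValueError(f"{what} pKa {value} outside (0, 14)")
    return value


@dataclass(frozen=True)
class PKaTable:
    """Ionisable-group pKa values with acid/base signs."""

    side_chain: Mapping[str, float] = field(
        default_factory=lambda: {
            "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
            "H": 6.5, "K": 10.8, "R": 12.5,
        }
    )
    n_term: float = 8.6
    c_term: float = 3.6
    acidic: FrozenSet[str] = frozenset("DECY")
    basic: FrozenSet[str] = frozenset("HKR")

    def __post_init__(self) -> None:
        _check_pka(self.n_term, "N-terminus")
        _check_pka(self.c_term, "C-terminus")
        for aa, v in self.side_chain.items():
            _check_pka(v, aa)
        if set(self.side_chain) != self.acidic | self.basic:
            raise ValueError("side-chain table must cover acidic ∪ basic")


DEFAULT_PKA = PKaTable()


@dataclass(frozen=True)
class PhyschemProfile:
    """Per-protein descriptor bundle."""

    pI: float
    net_charge_pH7: float
    hydrophobic_pct: float
    polar_pct: float
    nonpolar_pct: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pI < 14.0:
            raise ValueError(f"pI {self.pI} outside (0, 14)")
        if abs(self.polar_pct + self.nonpolar_pct - 100.0) > 1e-9:
            raise ValueError("polar + nonpolar percentages must sum to 100")


def _sequence(record: Union[ProteinRecord, str]) -> str:
    return record.sequence if isinstance(record, ProteinRecord) else record


def net_charge(
    record: Union[ProteinRecord, str],
    pH: float,
    pka: PKaTable = DEFAULT_PKA,
) -> float:
    """Henderson–Hasselbalch net charge at a given pH, termini included."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    counts = Counter(_sequence(record))
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in pka.basic:
        if counts[aa]:
            charge += counts[aa] / (1.0 + 10.0 ** (pH - pka.side_chain[aa]))
    for aa in pka.acidic:
        if counts[aa]:
            charge -= counts[aa] / (1.0 + 10.0 ** (pka.side_chain[aa] - pH))
    return charge


def isoelectric_point(
    record: Union[ProteinRecord, str],
    pka: PKaTable = DEFAULT_PKA,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH and the termini guarantee
    one basic and one acidic group, so the root exists and is unique.
    ``tol`` bounds the residual charge |Q(pI)|, not the pH error.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    # converge the bracket fully; the charge residual then sits far
    # below tol even on shallow titration curves
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        q = net_charge(record, mid, pka)
        if abs(q) < tol and hi - lo < 1e-6:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def residue_class_fractions(
    record: Union[ProteinRecord, str],
    hydrophobic: FrozenSet[str] = HYDROPHOBIC_RESIDUES,
    polar: FrozenSet[str] = POLAR_RESIDUES,
) -> dict[str, float]:
    """Percentages of hydrophobic / polar / nonpolar residues.

    ``polar`` and its complement partition the 20 standard residues;
    the hydrophobic class is independent of that partition. X residues
    are excluded from the denominator.
    """
    seq = [c for c in _sequence(record) if c != "X"]
    if not seq:
        raise ValueError("no standard residues in sequence")
    n = len(seq)
    n_hydro = sum(1 for c in seq if c in hydrophobic)
    n_polar = sum(1 for c in seq if c in polar)
    polar_pct = 100.0 * n_polar / n
    return {
        "hydrophobic_pct": 100.0 * n_hydro / n,
        "polar_pct": polar_pct,
        "nonpolar_pct": 100.0 - polar_pct,
    }


def physchem_profile(
    record: Union[ProteinRecord, str],
    pka: PKaTable = DEFAULT_PKA,
    hydrophobic: FrozenSet[str] = HYDROPHOBIC_RESIDUES,
    polar: FrozenSet[str] = POLAR_RESIDUES,
    report_ph: float = 7.0,
) -> PhyschemProfile:
    """Full descriptor bundle at the reporting pH (neutral by default)."""
    fractions = residue_class_fractions(record, hydrophobic, polar)
    return PhyschemProfile(
        pI=isoelectric_point(record, pka),
        net_charge_pH7=net_charge(record, report_ph, pka),
        **fractions,
    )
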