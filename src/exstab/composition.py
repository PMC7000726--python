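"""Amino-acid composition profiles and binned occurrence distributions.

Composition is reported as residue percentages per protein; occurrence
distributions count, for each residue type, how many proteins of a group
fall into each 2-percentage-point abundance bin ([0,2), [2,4), ... with
the final bin closed at 20%), the binning used to compare residue
preference between extremophile groups and their mesophilic orthologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedCompositionError
from .io import ProteinRecord

__all__ = [
    "AMINO_ACIDS",
    "BIN_EDGES",
    "CompositionProfile",
    "OccurrenceDistribution",
    "composition_percent",
    "bin_occurrences",
    "compare_composition",
]

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Half-open 2%-wide bins; the final bin [18, 20] is closed.
BIN_EDGES = tuple(range(0, 22, 2))
N_BINS = len(BIN_EDGES) - 1

BIN_LABELS = tuple(
    f"[{lo},{hi})" if i < N_BINS - 1 else f"[{lo},{hi}]"
    for i, (lo, hi) in enumerate(zip(BIN_EDGES[:-1], BIN_EDGES[1:]))
)


@dataclass(frozen=True)
class CompositionProfile:
    """Residue percentages for one protein.

    ``length`` is the effective length: X residues are excluded from
    both numerator and denominator.
    """

    percents: dict[str, float]
    length: int

    def __post_init__(self) -> None:
        total = sum(self.percents.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, not 100")
        if any(v < 0 for v in self.percents.values()):
            raise ValueError("negative percentage")


@dataclass(frozen=True)
class OccurrenceDistribution:
    """Per-residue protein counts across the abundance bins."""

    counts: pd.DataFrame  # index: residues, columns: BIN_LABELS
    n_proteins: int


def composition_percent(record: ProteinRecord) -> CompositionProfile:
    """Percentage of each standard residue in a sequence (X ignored)."""
    effective = [c for c in record.sequence if c != "X"]
    n = len(effective)
    if n == 0:
        raise UndefinedCompositionError(
            f"record {record.id!r}: no standard residues"
        )
    percents = {aa: 0.0 for aa in AMINO_ACIDS}
    for c in effective:
        percents[c] += 1.0
    raw = {aa: 100.0 * v / n for aa, v in percents.items()}
    # renormalise exactly to kill float drift in the invariant check
    total = sum(raw.values())
    percents = {aa: v * 100.0 / total for aa, v in raw.items()}
    return CompositionProfile(percents=percents, length=n)


def _bin_index(value: float) -> int:
    """Bin index for an abundance percentage; boundary → upper bin."""
    if value > BIN_EDGES[-1]:
        logger.warning("abundance %.3f%% exceeds the 20%% axis; clamped", value)
        return N_BINS - 1
    if value >= BIN_EDGES[-2]:  # [18, 20] closed at 20
        return N_BINS - 1
    return int(value // 2)


def bin_occurrences(profiles: Sequence[CompositionProfile]) -> OccurrenceDistribution:
    """Count proteins per residue per abundance bin.

    Each profile lands in exactly one bin per residue, so every
    residue's bin counts sum to the group size.
    """
    if len(profiles) == 0:
        raise InsufficientDataError("no profiles to bin")
    counts = np.zeros((len(AMINO_ACIDS), N_BINS), dtype=int)
    for profile in profiles:
        for i, aa in enumerate(AMINO_ACIDS):
            counts[i, _bin_index(profile.percents[aa])] += 1
    df = pd.DataFrame(counts, index=list(AMINO_ACIDS), columns=list(BIN_LABELS))
    return OccurrenceDistribution(counts=df, n_proteins=len(profiles))


def compare_composition(
    group_a: Iterable[CompositionProfile],
    group_b: Iterable[CompositionProfile],
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-residue two-sample t-test of composition between groups.

    Returns a DataFrame indexed by residue with columns
    ``mean_a, mean_b, t, df, p``.
    """
    from .stats import t_test  # local import avoids a cycle

    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >=2 proteins per group, got {len(a)} and {len(b)}"
        )
    rows = []
    for aa in AMINO_ACIDS:
        x = np.array([p.percents[aa] for p in a])
        y = np.array([p.percents[aa] for p in b])
        res = t_test(x, y, variant=variant, parameter=aa)
        rows.append(
            {"residue": aa, "mean_a": res.mean_a, "mean_b": res.mean_b,
             "t": res.t, "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows).set_index("residue")
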