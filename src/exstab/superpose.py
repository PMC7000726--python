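"""Rigid-body Cα superposition (Kabsch) with iterative outlier rejection.

The Kabsch algorithm gives the closed-form least-squares rotation
between two paired point sets via SVD of the cross-covariance matrix,
with the reflection case corrected by flipping the smallest singular
direction so the result is always a proper rotation (det = +1).

``refine_superposition`` repeats {fit, drop pairs whose post-fit
distance exceeds a cutoff} for a bounded number of cycles, mirroring
the default behaviour of the interactive tools whose RMSD values the
pipeline reproduces (5 cycles, 2.0 Å cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import AlignmentResult
from .errors import DegenerateGeometryError, InsufficientPairsError
from .io import Chain

__all__ = [
    "PairedCoordinates",
    "SuperpositionResult",
    "pair_ca_atoms",
    "kabsch",
    "refine_superposition",
]


@dataclass
class PairedCoordinates:
    """Equal-length paired 3D coordinates (Å) with residue provenance."""

    points_a: np.ndarray  # (n, 3)
    points_b: np.ndarray  # (n, 3)
    refs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points_a = np.asarray(self.points_a, dtype=float)
        self.points_b = np.asarray(self.points_b, dtype=float)
        if self.points_a.shape != self.points_b.shape:
            raise ValueError("point sets differ in shape")
        if self.points_a.ndim != 2 or self.points_a.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.points_a) < 3:
            raise InsufficientPairsError(
                f"need >=3 pairs, got {len(self.points_a)}"
            )

    def __len__(self) -> int:
        return len(self.points_a)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map x -> rotation @ x + translation of set A onto B."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    n_used: int
    n_rejected: int
    cycles_run: int = 0

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def pair_ca_atoms(
    alignment: AlignmentResult, chain_a: Chain, chain_b: Chain
) -> PairedCoordinates:
    """Cα coordinate pairs from the aligned (non-gap) columns.

    Columns where either residue lacks a Cα atom are skipped; fewer
    than three surviving pairs is an error.
    """
    pts_a, pts_b, refs = [], [], []
    ia = ib = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        res_a = chain_a.residues[ia] if ca != "-" else None
        res_b = chain_b.residues[ib] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if res_a is None or res_b is None:
            continue
        atom_a = res_a.atom("CA")
        atom_b = res_b.atom("CA")
        if atom_a is None or atom_b is None:
            continue
        pts_a.append(atom_a.position)
        pts_b.append(atom_b.position)
        refs.append(
            (f"{res_a.name}{res_a.seq_number}", f"{res_b.name}{res_b.seq_number}")
        )
    if len(pts_a) < 3:
        raise InsufficientPairsError(
            f"only {len(pts_a)} Cα pairs from alignment"
        )
    return PairedCoordinates(np.array(pts_a), np.array(pts_b), refs)


def kabsch(pairs: PairedCoordinates) -> SuperpositionResult:
    """Closed-form least-squares superposition of A onto B."""
    a = pairs.points_a
    b = pairs.points_b
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    a0 = a - centroid_a
    b0 = b - centroid_b
    cov = a0.T @ b0
    u, sing, vt = np.linalg.svd(cov)
    if sing[0] <= 0 or sing[1] < 1e-10 * sing[0]:
        raise DegenerateGeometryError(
            "point sets are (near-)collinear; rotation not determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        raise DegenerateGeometryError("singular cross-covariance")
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = centroid_b - rotation @ centroid_a
    diff = a0 @ rotation.T - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_used=len(a),
        n_rejected=0,
        cycles_run=0,
    )


def refine_superposition(
    pairs: PairedCoordinates,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Kabsch fit with iterative rejection of poorly fitting pairs.

    Each cycle refits on the retained pairs and drops pairs whose
    post-fit distance exceeds ``reject_cutoff`` Å; iteration stops when
    no pair is rejected or after ``cycles`` cycles. All pairs rejected
    (fewer than 3 left) is an error.
    """
    n_total = len(pairs)
    keep = np.ones(n_total, dtype=bool)
    fit: Optional[SuperpositionResult] = None
    cycles_run = 0
    for _ in range(max(cycles, 0) + 1):
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            raise InsufficientPairsError(
                "outlier rejection left fewer than 3 pairs"
            )
        subset = PairedCoordinates(
            pairs.points_a[idx], pairs.points_b[idx],
            [pairs.refs[i] for i in idx] if pairs.refs else [],
        )
        fit = kabsch(subset)
        if cycles_run >= cycles:
            break
        dist = np.linalg.norm(
            fit.transform(pairs.points_a[idx]) - pairs.points_b[idx], axis=1
        )
        bad = dist > reject_cutoff
        if not bad.any():
            break
        keep[idx[bad]] = False
        cycles_run += 1
    assert fit is not None
    return SuperpositionResult(
        rotation=fit.rotation,
        translation=fit.translation,
        rmsd=fit.rmsd,
        n_used=int(keep.sum()),
        n_rejected=int(n_total - keep.sum()),
        cycles_run=cycles_run,
    )
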