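"""Needleman–Wunsch global alignment with affine gaps.

Three-state Gotoh dynamic programming (match, gap-in-b, gap-in-a) with
an affine gap cost of ``gap_open + (L - 1) * gap_extend`` for a run of
length L, so setting ``gap_extend == gap_open`` degenerates to linear
gap scoring. End gaps are unpenalised by default, matching the global
aligner convention whose identity percentages this module reproduces
(BLOSUM62, open 10.0, extend 0.5).

Reported statistics use the full alignment length (gap columns
included) as denominator:

* identity  — columns with identical residues;
* similarity — columns whose substitution score is positive;
* gaps      — columns containing a gap.

Tie-breaking during traceback is deterministic: diagonal, then up
(gap in the second sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io import ProteinRecord

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "blosum62",
    "load_matrix",
    "needleman_wunsch",
    "identity_matrix_for_pairs",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue substitution scores; X scores 0 vs everything."""

    name: str
    scores: dict[Tuple[str, str], float]

    def score(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        try:
            return self.scores[(a, b)]
        except KeyError:
            return self.scores[(b, a)]

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            mirror = self.scores.get((b, a))
            if mirror is not None and mirror != s:
                raise ValueError(f"asymmetric scores for {a}/{b}")


def _from_biopython(arr, name: str) -> SubstitutionMatrix:
    alphabet = [c for c in arr.alphabet if c.isalpha()]
    scores = {
        (a, b): float(arr[a, b]) for a in alphabet for b in alphabet
    }
    return SubstitutionMatrix(name=name, scores=scores)


@lru_cache(maxsize=None)
def blosum62() -> SubstitutionMatrix:
    """The BLOSUM62 matrix (default scoring)."""
    return _from_biopython(substitution_matrices.load("BLOSUM62"), "BLOSUM62")


def load_matrix(source: Union[str, Path]) -> SubstitutionMatrix:
    """Load a matrix by name (e.g. ``BLOSUM62``) or NCBI-format file path."""
    path = Path(source)
    if path.exists():
        return _from_biopython(substitution_matrices.read(str(path)), path.stem)
    return _from_biopython(substitution_matrices.load(str(source)), str(source))


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps_pct: float
    length: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if not self.identity_pct <= self.similarity_pct + 1e-9:
            raise ValueError("identity exceeds similarity")


def _alignment_stats(
    aligned_a: str, aligned_b: str, matrix: SubstitutionMatrix, score: float
) -> AlignmentResult:
    length = len(aligned_a)
    ident = simil = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            ident += 1
        if matrix.score(ca, cb) > 0:
            simil += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=100.0 * ident / length,
        similarity_pct=100.0 * simil / length,
        gaps_pct=100.0 * gaps / length,
        length=length,
    )


# traceback pointer codes: state we came FROM
_M, _X, _Y = 0, 1, 2


def needleman_wunsch(
    a: Union[ProteinRecord, str],
    b: Union[ProteinRecord, str],
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences."""
    s = a.sequence if isinstance(a, ProteinRecord) else a
    t = b.sequence if isinstance(b, ProteinRecord) else b
    if not s or not t:
        raise ValueError("both sequences must be non-empty")
    if matrix is None:
        matrix = blosum62()
    n, m = len(s), len(t)

    # M[i][j]: best score ending in s[i-1]~t[j-1] column
    # X[i][j]: best score ending with s[i-1] over a gap (gap in t, "up")
    # Y[i][j]: best score ending with a gap over t[j-1] ("left")
    # plain lists: scalar access dominates, numpy indexing would be slower
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr_m = [[_M] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[_M] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[_M] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if end_gaps_free else -(gap_open + (i - 1) * gap_extend)
        ptr_x[i][0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if end_gaps_free else -(gap_open + (j - 1) * gap_extend)
        ptr_y[0][j] = _Y if j > 1 else _M

    score_of = matrix.score
    for i in range(1, n + 1):
        si = s[i - 1]
        m_prev, x_prev, y_prev = M[i - 1], X[i - 1], Y[i - 1]
        m_row, x_row, y_row = M[i], X[i], Y[i]
        pm_row, px_row, py_row = ptr_m[i], ptr_x[i], ptr_y[i]
        for j in range(1, m + 1):
            sub = score_of(si, t[j - 1])
            # M: diagonal move from any state
            best, origin = m_prev[j - 1], _M
            if x_prev[j - 1] > best:
                best, origin = x_prev[j - 1], _X
            if y_prev[j - 1] > best:
                best, origin = y_prev[j - 1], _Y
            m_row[j] = best + sub
            pm_row[j] = origin
            # X: consume s[i-1] against a gap; free in the last column
            go, ge = (0.0, 0.0) if (end_gaps_free and j == m) else (
                gap_open, gap_extend)
            best, origin = m_prev[j] - go, _M
            if x_prev[j] - ge > best:
                best, origin = x_prev[j] - ge, _X
            if y_prev[j] - go > best:
                best, origin = y_prev[j] - go, _Y
            x_row[j] = best
            px_row[j] = origin
            # Y: consume t[j-1] against a gap; free in the last row
            go, ge = (0.0, 0.0) if (end_gaps_free and i == n) else (
                gap_open, gap_extend)
            best, origin = m_row[j - 1] - go, _M
            if x_row[j - 1] - go > best:
                best, origin = x_row[j - 1] - go, _X
            if y_row[j - 1] - ge > best:
                best, origin = y_row[j - 1] - ge, _Y
            y_row[j] = best
            py_row[j] = origin

    # termination: best state at (n, m); ties prefer M, then X, then Y
    finals = (M[n][m], X[n][m], Y[n][m])
    state = 0
    for k in (1, 2):
        if finals[k] > finals[state]:
            state = k
    score = float(finals[state])

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            prev = ptr_m[i][j]
            out_a.append(s[i - 1])
            out_b.append(t[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            prev = ptr_x[i][j]
            out_a.append(s[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = ptr_y[i][j]
            out_a.append("-")
            out_b.append(t[j - 1])
            j -= 1
        state = prev
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return _alignment_stats(aligned_a, aligned_b, matrix, score)


def identity_matrix_for_pairs(
    pairs: Iterable[Tuple[ProteinRecord, ProteinRecord]],
    matrix: Optional[SubstitutionMatrix] = None,
    **kwargs,
) -> pd.DataFrame:
    """Alignment statistics table, one row per ortholog pair."""
    rows = []
    for rec_a, rec_b in pairs:
        res = needleman_wunsch(rec_a, rec_b, matrix=matrix, **kwargs)
        rows.append(
            {"id_a": rec_a.id, "id_b": rec_b.id,
             "identity_pct": res.identity_pct,
             "similarity_pct": res.similarity_pct,
             "gaps_pct": res.gaps_pct,
             "score": res.score,
             "length": res.length}
        )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "identity_pct", "similarity_pct",
                 "gaps_pct", "score", "length"],
    )
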