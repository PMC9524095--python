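"""Affine-gap pairwise alignment and reference-numbered motif mapping.

The superoxide ("HHHH") motif check works by globally aligning a candidate
to the NOX2 reference and reading off the query residues aligned to the
four reference histidine positions. End gaps are free by default
(semi-global alignment) so that long N-terminal extensions - EF-hands,
peroxidase domains, the DspNOX sensory region - do not distort the mapping
of the C-terminal oxidase core.

Gap convention: a gap of length k costs ``gap_open + (k-1) * gap_extend``
(both negative). Traceback is deterministic with tie order
diagonal > up > left (match preferred over a gap in the query, over a gap
in the reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .config import MotifSpec
from .seqio import SequenceRecord

__all__ = [
    "Alignment",
    "MotifCheck",
    "global_align",
    "map_reference_positions",
    "check_hhhh",
    "load_matrix",
    "encode",
]

_NEG = -1.0e30


@lru_cache(maxsize=8)
def load_matrix(name: str) -> Tuple[np.ndarray, Dict[str, int]]:
    """Load a named substitution matrix as (numpy array, letter->index map)."""
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix: {name!r}") from None
    alphabet = str(mat.alphabet)
    idx = {ch: i for i, ch in enumerate(alphabet)}
    return np.asarray(mat, dtype=np.float64), idx


def encode(residues: str, idx: Dict[str, int]) -> np.ndarray:
    """Encode residues as matrix indices; letters outside the alphabet -> X."""
    x = idx.get("X", 0)
    return np.array([idx.get(ch, x) for ch in residues], dtype=np.int64)


@njit(cache=True)
def _affine_dp(smat, go, ge, free_ends):  # pragma: no cover - jitted
    La, Lb = smat.shape
    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)  # gap in b (vertical / "up")
    Y = np.full((La + 1, Lb + 1), _NEG)  # gap in a (horizontal / "left")
    pM = np.zeros((La + 1, Lb + 1), np.uint8)
    pX = np.zeros((La + 1, Lb + 1), np.uint8)
    pY = np.zeros((La + 1, Lb + 1), np.uint8)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = 0.0 if free_ends else go + (i - 1) * ge
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, Lb + 1):
        Y[0, j] = 0.0 if free_ends else go + (j - 1) * ge
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            # tie preference everywhere: M (diagonal) > X (up) > Y (left)
            best = M[i - 1, j - 1]
            arg = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = 2
            M[i, j] = best + smat[i - 1, j - 1]
            pM[i, j] = arg

            best = M[i - 1, j] + go
            arg = 0
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                arg = 1
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                arg = 2
            X[i, j] = best
            pX[i, j] = arg

            best = M[i, j - 1] + go
            arg = 0
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                arg = 1
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                arg = 2
            Y[i, j] = best
            pY[i, j] = arg

    # end cell: corner always; with free ends also last row / last column
    ei, ej, estate = La, Lb, 0
    best_score = M[La, Lb]
    if X[La, Lb] > best_score:
        best_score = X[La, Lb]
        estate = 1
    if Y[La, Lb] > best_score:
        best_score = Y[La, Lb]
        estate = 2
    if free_ends:
        for i in range(La - 1, 0, -1):  # last column
            for st in range(3):
                v = M[i, Lb] if st == 0 else (X[i, Lb] if st == 1 else Y[i, Lb])
                if v > best_score:
                    best_score = v
                    ei, ej, estate = i, Lb, st
        for j in range(Lb - 1, 0, -1):  # last row
            for st in range(3):
                v = M[La, j] if st == 0 else (X[La, j] if st == 1 else Y[La, j])
                if v > best_score:
                    best_score = v
                    ei, ej, estate = La, j, st
    cols_a = np.empty(La + Lb, np.int64)
    cols_b = np.empty(La + Lb, np.int64)
    n = 0
    if free_ends:  # terminal free gaps, recorded in reverse order
        if ei == La:
            for j in range(Lb, ej, -1):
                cols_a[n] = -1
                cols_b[n] = j - 1
                n += 1
        else:
            for i in range(La, ei, -1):
                cols_a[n] = i - 1
                cols_b[n] = -1
                n += 1
    i, j, st = ei, ej, estate
    while i > 0 or j > 0:
        if st == 0:
            if i == 0 and j == 0:
                break
            prev = pM[i, j]
            cols_a[n] = i - 1
            cols_b[n] = j - 1
            n += 1
            i -= 1
            j -= 1
            st = prev
        elif st == 1:
            prev = pX[i, j]
            cols_a[n] = i - 1
            cols_b[n] = -1
            n += 1
            i -= 1
            st = prev
        else:
            prev = pY[i, j]
            cols_a[n] = -1
            cols_b[n] = j - 1
            n += 1
            j -= 1
            st = prev
    return best_score, cols_a[:n][::-1].copy(), cols_b[:n][::-1].copy()


@dataclass
class Alignment:
    """A pairwise alignment of a (reference) against b (query)."""

    a_gapped: str
    b_gapped: str
    score: float
    a_cols: np.ndarray  # per column: 0-based index into a, or -1 for gap
    b_cols: np.ndarray

    def identity(self) -> float:
        pairs = [(x, y) for x, y in zip(self.a_gapped, self.b_gapped) if "-" not in (x, y)]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    free_end_gaps: bool = False,
) -> Alignment:
    """Optimal affine-gap global (or, with free ends, semi-global) alignment."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    sub, idx = load_matrix(matrix)
    ca, cb = encode(a, idx), encode(b, idx)
    smat = np.ascontiguousarray(sub[ca[:, None], cb[None, :]])
    score, a_cols, b_cols = _affine_dp(smat, float(gap_open), float(gap_extend), free_end_gaps)
    a_g = "".join(a[i] if i >= 0 else "-" for i in a_cols)
    b_g = "".join(b[j] if j >= 0 else "-" for j in b_cols)
    return Alignment(a_g, b_g, float(score), a_cols, b_cols)


def map_reference_positions(
    aln: Alignment, positions: Sequence[int]
) -> List[Tuple[int, Optional[int]]]:
    """Map 1-based reference coordinates through an alignment.

    The reference is sequence ``a`` of the alignment. Returns, for each
    reference coordinate, the 1-based query coordinate aligned to the same
    column, or None where the query has a gap.
    """
    ref_len = int((aln.a_cols >= 0).sum())
    col_of = {int(i): c for c, i in enumerate(aln.a_cols) if i >= 0}
    out: List[Tuple[int, Optional[int]]] = []
    for pos in positions:
        if not (1 <= pos <= ref_len):
            raise ValueError(f"reference position {pos} outside 1..{ref_len}")
        col = col_of[pos - 1]
        q = int(aln.b_cols[col])
        out.append((pos, q + 1 if q >= 0 else None))
    return out


@dataclass
class MotifCheck:
    """Outcome of the four-histidine motif check for one candidate."""

    seq_id: str
    # (reference pos, query pos or None, query residue or '-', pass flag)
    records: List[Tuple[int, Optional[int], str, bool]]
    full_motif: bool


def check_hhhh(
    query: SequenceRecord,
    spec: MotifSpec,
    reference: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> MotifCheck:
    """Verify the superoxide motif on a query in reference numbering.

    ``full_motif`` is true iff all reference positions map to non-gap query
    residues equal to the required residue (exact match; conservative
    substitutions fail).
    """
    if reference.id != spec.reference_id:
        raise ValueError(
            f"reference id {reference.id!r} does not match motif spec "
            f"{spec.reference_id!r}"
        )
    aln = global_align(
        reference.residues,
        query.residues,
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
        free_end_gaps=True,
    )
    mapped = map_reference_positions(aln, spec.positions)
    records = []
    for pos, qpos in mapped:
        res = query.residues[qpos - 1] if qpos is not None else "-"
        records.append((pos, qpos, res, res == spec.required_residue))
    return MotifCheck(
        seq_id=query.id,
        records=records,
        full_motif=all(r[3] for r in records),
    )
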