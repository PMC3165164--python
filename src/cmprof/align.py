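"""Global Needleman-Wunsch alignment with affine gap costs and a baseline
shift, over an arbitrary position-pair score matrix.

The optimum of

    sum over matched pairs of (S(i, j) - base)  -  sum over gaps of
    (g_open + (len - 1) * g_ext)

is found with the standard three-state dynamic program (match, gap in
protein 2 consuming i, gap in protein 1 consuming j).  End gaps are
penalized (true global alignment) unless ``semi_global`` is set.  Traceback
ties are broken deterministically: match > gap in protein 1 > gap in
protein 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .scoring import ScoreMatrix, ScoringParams, score_matrix

__all__ = ["AlignmentResult", "nw_affine", "align_proteins", "alignment_accuracy"]

NEG = float("-inf")
_M, _IX, _IY = 0, 1, 2  # IX consumes i (gap in protein 2); IY consumes j


@dataclass
class AlignmentResult:
    """Aligned position pairs (0-based, strictly increasing in both
    coordinates), the optimal total score, and the full gapped column list
    (``columns``: (i, j) with -1 for a gap) for display."""

    pairs: list[tuple[int, int]]
    total_score: float
    columns: list[tuple[int, int]] = field(default_factory=list)
    n1: int = 0
    n2: int = 0

    def pairs_1based(self) -> list[tuple[int, int]]:
        return [(i + 1, j + 1) for i, j in self.pairs]

    def gapped_strings(self, seq1: str, seq2: str) -> tuple[str, str]:
        """Render the alignment over two residue strings of lengths n1, n2."""
        s1 = "".join(seq1[i] if i >= 0 else "-" for i, _ in self.columns)
        s2 = "".join(seq2[j] if j >= 0 else "-" for _, j in self.columns)
        return s1, s2

    def recompute_score(self, S: np.ndarray, params: ScoringParams) -> float:
        """Re-derive the total score from the pair/gap structure."""
        total = 0.0
        shift = params.base_sign * params.base
        run = None  # current gap direction
        for i, j in self.columns:
            if i >= 0 and j >= 0:
                total += S[i, j] + shift
                run = None
            else:
                direction = "i" if i >= 0 else "j"
                if run == direction:
                    total -= params.g_ext
                else:
                    total -= params.g_open
                run = direction
        return total


def nw_affine(S: ScoreMatrix | np.ndarray, params: ScoringParams,
              semi_global: bool = False) -> AlignmentResult:
    """Optimal global alignment over a score matrix with affine gap costs.

    Empty matrices yield an empty alignment of score 0; otherwise a global
    alignment is always returned, however negative the scores.
    """
    Sm = S.S if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    if not np.all(np.isfinite(Sm)):
        raise ConfigError("score matrix must be finite")
    n1, n2 = Sm.shape
    if n1 == 0 or n2 == 0:
        cols = [(-1, j) for j in range(n2)] + [(i, -1) for i in range(n1)]
        score = 0.0
        if not semi_global and (n1 or n2):
            k = n1 + n2
            score = -(params.g_open + (k - 1) * params.g_ext)
        return AlignmentResult(pairs=[], total_score=score, columns=cols, n1=n1, n2=n2)

    shift = params.base_sign * params.base
    go, ge = params.g_open, params.g_ext
    sub = Sm + shift

    M = np.full((n1 + 1, n2 + 1), NEG)
    IX = np.full((n1 + 1, n2 + 1), NEG)
    IY = np.full((n1 + 1, n2 + 1), NEG)
    ptr = np.zeros((3, n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    end_open, end_ext = (0.0, 0.0) if semi_global else (go, ge)
    for i in range(1, n1 + 1):
        IX[i, 0] = -(end_open + (i - 1) * end_ext)
        ptr[_IX, i, 0] = _M if i == 1 else _IX
    for j in range(1, n2 + 1):
        IY[0, j] = -(end_open + (j - 1) * end_ext)
        ptr[_IY, 0, j] = _M if j == 1 else _IY

    for i in range(1, n1 + 1):
        Mi1, IXi1, IYi1 = M[i - 1], IX[i - 1], IY[i - 1]
        Mi, IXi, IYi = M[i], IX[i], IY[i]
        edge_i = (i == n1)
        for j in range(1, n2 + 1):
            # match state: tie priority M > IY > IX on equal predecessors
            best, arg = Mi1[j - 1], _M
            if IYi1[j - 1] > best:
                best, arg = IYi1[j - 1], _IY
            if IXi1[j - 1] > best:
                best, arg = IXi1[j - 1], _IX
            Mi[j] = best + sub[i - 1, j - 1]
            ptr[_M, i, j] = arg
            # IX: gap in protein 2, consumes i (vertical)
            o, e = (end_open, end_ext) if (semi_global and j == n2) else (go, ge)
            cand_m = Mi1[j] - o
            cand_y = IYi1[j] - o
            cand_x = IXi1[j] - e
            best, arg = cand_m, _M
            if cand_y > best:
                best, arg = cand_y, _IY
            if cand_x > best:
                best, arg = cand_x, _IX
            IXi[j] = best
            ptr[_IX, i, j] = arg
            # IY: gap in protein 1, consumes j (horizontal)
            o, e = (end_open, end_ext) if (semi_global and edge_i) else (go, ge)
            cand_m = Mi[j - 1] - o
            cand_x = IXi[j - 1] - o
            cand_y = IYi[j - 1] - e
            best, arg = cand_m, _M
            if cand_y > best:
                best, arg = cand_y, _IY
            if cand_x > best:
                best, arg = cand_x, _IX
            IYi[j] = best
            ptr[_IY, i, j] = arg

    finals = (M[n1, n2], IY[n1, n2], IX[n1, n2])
    order = (_M, _IY, _IX)
    state = order[int(np.argmax(finals))]
    total = float(max(finals))

    cols: list[tuple[int, int]] = []
    i, j = n1, n2
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == _M:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _IX:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
        state = prev
    cols.reverse()
    pairs = [(ci, cj) for ci, cj in cols if ci >= 0 and cj >= 0]
    return AlignmentResult(pairs=pairs, total_score=total, columns=cols, n1=n1, n2=n2)


def align_proteins(params: ScoringParams,
                   terms: tuple[str, ...] = ("mut",),
                   semi_global: bool = False,
                   **inputs) -> tuple[AlignmentResult, ScoreMatrix]:
    """Score-matrix construction followed by global alignment.

    ``inputs`` are the keyword arguments of :func:`cmprof.scoring.score_matrix`
    (profile1/profile2, cm1/cm2, ss1/ss2) for the requested terms.
    """
    smat = score_matrix(params, terms=terms, **inputs)
    result = nw_affine(smat, params, semi_global=semi_global)
    return result, smat


def alignment_accuracy(result: AlignmentResult,
                       truth: list[tuple[int, int]]) -> float:
    """Fraction of reference position pairs recovered by the alignment."""
    if not truth:
        return float("nan")
    got = set(result.pairs)
    return sum(1 for p in truth if tuple(p) in got) / len(truth)
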