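"""Post-hoc analyses of alignments: preservation of coevolution and
top-ranked residue pairs.

If an alignment pairs the inter-related residues of one protein with the
comparable residues of the other, the two proteins' mutual-information
matrices — restricted to the aligned positions — should correlate.  The
correlation is measured on the vectorized upper triangles (the matrices are
symmetric) with Pearson's r.  The second analysis ranks aligned position
pairs by a chosen scoring term (sequence-profile or CM-profile score), the
tabular counterpart of highlighting top pairs on a superposed structure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .align import AlignmentResult
from .coevolution import CoevolutionConfig, corrected_joint, count_pairs, mi_matrix
from .errors import ConfigError, InputError
from .msa_io import Msa

__all__ = ["aligned_mi_correlation", "correlate_mi_matrices", "top_pairs"]


def correlate_mi_matrices(mi1: np.ndarray, mi2: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two symmetric matrices' upper triangles."""
    if mi1.shape != mi2.shape or mi1.ndim != 2 or mi1.shape[0] != mi1.shape[1]:
        raise InputError("matrices must be square and of equal shape")
    k = mi1.shape[0]
    if k < 3:
        raise InputError("need at least 3 aligned positions for a correlation")
    iu = np.triu_indices(k, 1)
    r, p = stats.pearsonr(mi1[iu], mi2[iu])
    return float(r), float(p)


def aligned_mi_correlation(msa1: Msa, msa2: Msa, alignment: AlignmentResult,
                           coev_cfg: CoevolutionConfig | None = None
                           ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Correlation between the two proteins' mutual-information matrices
    over aligned positions (unaligned residues excluded).

    Returns (r, p-value, mi1_sub, mi2_sub) where the matrices are restricted
    to aligned positions in alignment order.
    """
    pairs = alignment.pairs
    if len(pairs) < 3:
        raise InputError("need at least 3 aligned positions for a correlation")
    cfg = coev_cfg or CoevolutionConfig()
    mi1 = mi_matrix(corrected_joint(count_pairs(msa1), cfg))
    mi2 = mi_matrix(corrected_joint(count_pairs(msa2), cfg))
    pos1 = [i for i, _ in pairs]
    pos2 = [j for _, j in pairs]
    sub1 = mi1[np.ix_(pos1, pos1)]
    sub2 = mi2[np.ix_(pos2, pos2)]
    r, p = correlate_mi_matrices(sub1, sub2)
    return r, p, sub1, sub2


def top_pairs(alignment: AlignmentResult, components: dict[str, np.ndarray],
              term: str, k: int = 10) -> list[tuple[int, int, float]]:
    """The k aligned position pairs with the highest score for one term.

    Descending by score; ties broken by (i, j) ascending.  Returns 0-based
    (i, j, score) triples; if k exceeds the number of aligned pairs, all are
    returned.
    """
    if term not in components:
        raise ConfigError(f"component matrix for term {term!r} not available")
    comp = components[term]
    scored = [(i, j, float(comp[i, j])) for i, j in alignment.pairs]
    scored.sort(key=lambda t: (-t[2], t[0], t[1]))
    return scored[:k]
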