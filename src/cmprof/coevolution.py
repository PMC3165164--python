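"""Correlated mutation statistics from a multiple sequence alignment.

For every pair of seed positions (i, j) the MSA yields a 20x20 table of
observation counts N(a_i, b_j) over the sequences that are non-gap at both
positions.  Because few observations make raw joint frequencies noisy, a
low-number correction adds a pseudocount ``lambda_`` to every cell:

    f(a_i, b_j) = (N(a_i, b_j) + lambda) / (n_eff(i, j) + 400 * lambda)

Marginals f(a_i) and f(b_j) are derived from the corrected joint, so that
statistically independent columns give a log-odds of exactly zero even with
pseudocounts.  The correlated-mutation score is the log-odds

    m(a_i, b_j) = ln[ f(a_i, b_j) / (f(a_i) * f(b_j)) ]

positive for positively correlated occupancy, negative for anti-correlated,
zero for independent evolution.  For a fixed position i and amino-acid pair
(a, b) the scores over all positions j form the length-n correlated-mutation
vector that downstream LPC analysis turns into cepstral features.  The same
corrected joint yields mutual information (in nats) for post-hoc analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, N_AA, N_PAIRS, GAP_CODE
from .errors import InputError
from .msa_io import Msa

__all__ = [
    "PairCounts",
    "CoevolutionConfig",
    "JointFrequencies",
    "CorrelatedMutationVector",
    "count_pairs",
    "corrected_joint",
    "cm_vector",
    "cm_signal_stack",
    "mutual_information",
    "mi_matrix",
]


@dataclass
class CoevolutionConfig:
    """Low-number-correction settings: per-cell pseudocount ``lambda_`` (> 0
    in normal use; 0 allowed for exact-frequency analyses) and the natural
    log convention."""

    lambda_: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise InputError("lambda_ must be >= 0")


@dataclass
class PairCounts:
    """Observation counts N[i, j, a, b] (shape (n, n, 20, 20)) and the number
    of sequences n_eff[i, j] non-gap at both positions."""

    N: np.ndarray
    n_eff: np.ndarray

    @property
    def n(self) -> int:
        return self.N.shape[0]


@dataclass
class JointFrequencies:
    """Low-number-corrected joint frequencies f[i, j, a, b] with marginals
    fa[i, j, a] = sum_b f and fb[i, j, b] = sum_a f."""

    f: np.ndarray
    fa: np.ndarray = field(init=False)
    fb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fa = self.f.sum(axis=3)
        self.fb = self.f.sum(axis=2)

    @property
    def n(self) -> int:
        return self.f.shape[0]


@dataclass
class CorrelatedMutationVector:
    """Log-odds scores m(a_i, b_j) for fixed position i and pair (a, b),
    over all positions j = 1..n (the LPC input signal)."""

    i: int
    a: str
    b: str
    m: np.ndarray


def count_pairs(msa: Msa) -> PairCounts:
    """Tally N(a_i, b_j) for every position pair of a (thinned) MSA.

    Sequences gapped at i or j contribute nothing to the (i, j) table.
    """
    mat = msa.matrix()
    onehot = (mat[:, :, None] == np.arange(N_AA, dtype=mat.dtype)).astype(np.float32)
    # (n_seq, n, 20) x (n_seq, n, 20) -> (n, 20, n, 20)
    N = np.tensordot(onehot, onehot, axes=([0], [0]))
    N = np.ascontiguousarray(N.transpose(0, 2, 1, 3))
    n_eff = N.sum(axis=(2, 3), dtype=np.float64)
    return PairCounts(N=N, n_eff=n_eff)


def corrected_joint(counts: PairCounts, cfg: CoevolutionConfig | None = None) -> JointFrequencies:
    """Apply the low-number correction; every (i, j) table sums to 1."""
    cfg = cfg or CoevolutionConfig()
    denom = counts.n_eff + N_PAIRS * cfg.lambda_
    if np.any(denom <= 0):
        raise InputError("n_eff + 400*lambda must be positive for every position pair")
    f = (counts.N.astype(np.float64) + cfg.lambda_) / denom[:, :, None, None]
    return JointFrequencies(f=f)


def cm_vector(freqs: JointFrequencies, i: int, a: str | int, b: str | int) -> CorrelatedMutationVector:
    """The correlated-mutation vector m(a_i, b) = [m(a_i, b_1) .. m(a_i, b_n)].

    The self term j = i is included so the vector has length exactly n.
    """
    ia = AA_INDEX[a] if isinstance(a, str) else int(a)
    ib = AA_INDEX[b] if isinstance(b, str) else int(b)
    with np.errstate(divide="ignore"):
        m = (np.log(freqs.f[i, :, ia, ib])
             - np.log(freqs.fa[i, :, ia])
             - np.log(freqs.fb[i, :, ib]))
    # lambda_ > 0 guarantees finite entries; at lambda_ = 0 unobserved cells
    # are -inf, which analytic checks on observed cells never touch.
    from .alphabet import ALPHABET
    return CorrelatedMutationVector(i=i, a=ALPHABET[ia], b=ALPHABET[ib], m=m)


def cm_signal_stack(freqs: JointFrequencies) -> np.ndarray:
    """All n x 400 correlated-mutation vectors as an (n, 400, n) array.

    Entry [i, 20*idx(a)+idx(b), j] equals m(a_i, b_j).
    """
    n = freqs.n
    with np.errstate(divide="ignore"):
        logf = np.log(freqs.f)
        logfa = np.log(freqs.fa)
        logfb = np.log(freqs.fb)
    m = logf - logfa[:, :, :, None] - logfb[:, :, None, :]
    if not np.all(np.isfinite(m)):
        raise InputError("zero frequencies in correlated-mutation signals; use lambda_ > 0")
    # (i, j, a, b) -> (i, a, b, j) -> (i, 400, n)
    return np.ascontiguousarray(m.transpose(0, 2, 3, 1)).reshape(n, N_PAIRS, n)


def mutual_information(freqs: JointFrequencies, i: int, j: int) -> float:
    """MI(i, j) in nats from the corrected joint at (i, j)."""
    f = freqs.f[i, j]
    outer = np.outer(freqs.fa[i, j], freqs.fb[i, j])
    mask = f > 0
    return float(np.sum(f[mask] * np.log(f[mask] / outer[mask])))


def mi_matrix(freqs: JointFrequencies) -> np.ndarray:
    """Symmetric (n, n) matrix of mutual information values in nats."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(freqs.f) - np.log(freqs.fa[:, :, :, None]) - np.log(freqs.fb[:, :, None, :])
        terms = np.where(freqs.f > 0, freqs.f * ratio, 0.0)
    return terms.sum(axis=(2, 3))
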