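"""Linear predictive coding of correlated-mutation vectors and assembly of
CM profiles.

The LPC model approximates a signal sample s(t) as a linear combination of
its p predecessors, s(t) ~ sum_{k=1..p} a_k s(t-k).  Minimizing the summed
squared prediction error leads to the symmetric Toeplitz normal equations

    sum_{k=1..p} a_k r(|i-k|) = r(i),   i = 1..p,

with r the autocorrelation of s, solved in O(p^2) by the Levinson-Durbin
recursion.  The LPC cepstral coefficients of the all-pole synthesis filter
1/A(z), A(z) = 1 - sum a_k z^-k, follow from the standard recursion

    c_m = a_m + sum_{k=1..m-1} (k/m) c_k a_{m-k}        (m <= p)
    c_m =       sum_{k=m-p..m-1} (k/m) c_k a_{m-k}      (m > p)

and decay with order, so the first L of them (excluding c_0) give a
fixed-length spectral summary of a variable-length signal.

A CM profile applies this to all n x 400 correlated-mutation vectors of a
protein: per position i and ordered amino-acid pair (a, b), the length-n
log-odds vector is reduced to L cepstral coefficients; the resulting
(n, 400, L) array is z-normalized per coefficient order over the whole
protein so all orders carry equal weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET, N_PAIRS
from .coevolution import CoevolutionConfig, cm_signal_stack, corrected_joint, count_pairs
from .errors import InputError
from .msa_io import Msa

__all__ = [
    "LpcConfig",
    "LpcFit",
    "CmProfile",
    "autocorrelation",
    "levinson_durbin",
    "lpc_to_cepstrum",
    "build_cm_profile",
]

_ZERO_TOL = 1e-12


@dataclass
class LpcConfig:
    """LPC model order ``p`` and number of cepstral coefficients ``L`` kept
    (c_0 excluded).  Defaults p=6, L=9."""

    p: int = 6
    L: int = 9

    def __post_init__(self) -> None:
        if self.p < 1 or self.L < 1:
            raise InputError("p and L must be >= 1")


@dataclass
class LpcFit:
    """LPC coefficients ``a`` (length p), autocorrelation ``r`` (0..p), final
    prediction error ``E`` >= 0, and a degeneracy flag for constant-zero or
    underflowing signals."""

    a: np.ndarray
    r: np.ndarray
    E: float
    degenerate: bool = False


def autocorrelation(s: np.ndarray, p: int) -> np.ndarray:
    """r(k) = sum_t s(t) s(t+k) for k = 0..p; requires len(s) > p."""
    s = np.asarray(s, dtype=float)
    n = s.shape[-1]
    if n <= p:
        raise InputError(f"signal length {n} must exceed model order {p}")
    return np.array([float(np.dot(s[: n - k], s[k:])) for k in range(p + 1)])


def levinson_durbin(r: np.ndarray) -> LpcFit:
    """Solve the symmetric Toeplitz normal equations by Levinson-Durbin.

    Degenerate cases: r(0) = 0 (constant-zero signal) returns a = 0, E = 0
    flagged; a vanishing intermediate prediction error truncates the order,
    padding the remaining coefficients with zeros.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0] - 1
    a = np.zeros(p)
    if r[0] <= _ZERO_TOL:
        return LpcFit(a=a, r=r, E=0.0, degenerate=True)
    E = r[0]
    degenerate = False
    for m in range(1, p + 1):
        if E <= _ZERO_TOL * r[0]:
            degenerate = True
            break
        k = (r[m] - np.dot(a[: m - 1], r[1:m][::-1])) / E
        a_new = a.copy()
        a_new[m - 1] = k
        a_new[: m - 1] = a[: m - 1] - k * a[: m - 1][::-1]
        a = a_new
        E = (1.0 - k * k) * E
        if E < 0.0:
            E = 0.0
    return LpcFit(a=a, r=r, E=float(E), degenerate=degenerate)


def lpc_to_cepstrum(fit: LpcFit | np.ndarray, L: int) -> np.ndarray:
    """First L cepstral coefficients (c_1..c_L) of the all-pole filter."""
    a = fit.a if isinstance(fit, LpcFit) else np.asarray(fit, dtype=float)
    p = a.shape[0]
    c = np.zeros(L)
    for m in range(1, L + 1):
        acc = a[m - 1] if m <= p else 0.0
        for k in range(max(1, m - p), m):
            acc += (k / m) * c[k - 1] * a[m - k - 1]
        c[m - 1] = acc
    return c


# Vectorized internals over a batch of signals (rows).

def _batch_autocorrelation(S: np.ndarray, p: int) -> np.ndarray:
    n = S.shape[1]
    if n <= p:
        raise InputError(f"signal length {n} must exceed model order {p}")
    return np.stack([np.einsum("bt,bt->b", S[:, : n - k], S[:, k:]) for k in range(p + 1)], axis=1)


def _batch_levinson(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin over rows of R (shape (B, p+1)); degenerate rows get
    zero coefficients.  Returns (a, E)."""
    B, p1 = R.shape
    p = p1 - 1
    a = np.zeros((B, p))
    r0 = R[:, 0]
    live = r0 > _ZERO_TOL
    E = np.where(live, r0, 1.0)  # placeholder to avoid divide-by-zero
    active = live.copy()
    for m in range(1, p + 1):
        active &= E > _ZERO_TOL * np.maximum(r0, _ZERO_TOL)
        acc = R[:, m] - np.einsum("bk,bk->b", a[:, : m - 1], R[:, 1:m][:, ::-1])
        k = np.where(active, acc / np.where(active, E, 1.0), 0.0)
        head = a[:, : m - 1] - k[:, None] * a[:, : m - 1][:, ::-1]
        a[:, : m - 1] = np.where(active[:, None], head, a[:, : m - 1])
        a[:, m - 1] = np.where(active, k, a[:, m - 1])
        E = np.where(active, np.maximum((1.0 - k * k) * E, 0.0), E)
    E = np.where(live, E, 0.0)
    return a, E


def _batch_cepstrum(A: np.ndarray, L: int) -> np.ndarray:
    B, p = A.shape
    C = np.zeros((B, L))
    for m in range(1, L + 1):
        acc = A[:, m - 1].copy() if m <= p else np.zeros(B)
        for k in range(max(1, m - p), m):
            acc += (k / m) * C[:, k - 1] * A[:, m - k - 1]
        C[:, m - 1] = acc
    return C


@dataclass
class CmProfile:
    """Normalized CM profile: coeffs[i, pair, l] for seed position i, ordered
    amino-acid pair index (20*idx(a)+idx(b)) and cepstral order l+1."""

    coeffs: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.coeffs.shape[0]

    @property
    def L(self) -> int:
        return self.coeffs.shape[2]

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, coeffs=self.coeffs, meta=json.dumps(self.meta))

    @classmethod
    def from_npz(cls, path: str | Path) -> "CmProfile":
        data = np.load(path, allow_pickle=False)
        return cls(coeffs=data["coeffs"], meta=json.loads(str(data["meta"])))

    def to_tsv(self, path: str | Path) -> None:
        """Text serialization: header comments then one row per (i, pair)."""
        with Path(path).open("w") as fh:
            fh.write(f"# meta\t{json.dumps(self.meta, sort_keys=True)}\n")
            fh.write(f"# shape\t{self.coeffs.shape[0]}\t{self.coeffs.shape[1]}\t{self.coeffs.shape[2]}\n")
            for i in range(self.coeffs.shape[0]):
                for pair in range(self.coeffs.shape[1]):
                    vals = "\t".join(repr(float(v)) for v in self.coeffs[i, pair])
                    fh.write(f"{i}\t{pair}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CmProfile":
        meta: dict = {}
        shape = None
        coeffs = None
        with Path(path).open() as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "# meta":
                    meta = json.loads(parts[1])
                elif parts[0] == "# shape":
                    shape = tuple(int(v) for v in parts[1:4])
                    coeffs = np.zeros(shape)
                else:
                    i, pair = int(parts[0]), int(parts[1])
                    coeffs[i, pair] = [float(v) for v in parts[2:]]
        if coeffs is None:
            raise InputError(f"{path}: missing shape header")
        return cls(coeffs=coeffs, meta=meta)


def build_cm_profile(msa: Msa,
                     coev_cfg: CoevolutionConfig | None = None,
                     lpc_cfg: LpcConfig | None = None,
                     normalize: str = "per_order") -> CmProfile:
    """Full pipeline: pair counts -> corrected joint -> log-odds vectors ->
    autocorrelation -> Levinson-Durbin -> cepstra -> z-normalization.

    ``normalize`` is "per_order" (mean/variance pooled over all n x 400
    entries of each coefficient order; default), "per_position" (pooled over
    the 400 pairs of each position) or "none".  Zero-variance orders map to
    zeros.  All-zero signals (uniform corrected joint) short-circuit to zero
    cepstra.
    """
    coev_cfg = coev_cfg or CoevolutionConfig()
    lpc_cfg = lpc_cfg or LpcConfig()
    n = msa.n
    if n <= lpc_cfg.p:
        raise InputError(
            f"seed length {n} must exceed LPC order p={lpc_cfg.p}; use a shorter model order")
    if normalize not in ("per_order", "per_position", "none"):
        raise InputError(f"unknown normalization {normalize!r}")
    freqs = corrected_joint(count_pairs(msa), coev_cfg)
    signals = cm_signal_stack(freqs).reshape(n * N_PAIRS, n)
    R = _batch_autocorrelation(signals, lpc_cfg.p)
    A, _ = _batch_levinson(R)
    C = _batch_cepstrum(A, lpc_cfg.L)
    C[R[:, 0] <= _ZERO_TOL] = 0.0
    coeffs = C.reshape(n, N_PAIRS, lpc_cfg.L)
    if normalize == "per_order":
        mean = coeffs.mean(axis=(0, 1))
        std = coeffs.std(axis=(0, 1))
        coeffs = np.where(std > _ZERO_TOL, (coeffs - mean) / np.where(std > 0, std, 1.0), 0.0)
    elif normalize == "per_position":
        mean = coeffs.mean(axis=1, keepdims=True)
        std = coeffs.std(axis=1, keepdims=True)
        coeffs = np.where(std > _ZERO_TOL, (coeffs - mean) / np.where(std > 0, std, 1.0), 0.0)
    meta = {"n": n, "p": lpc_cfg.p, "L": lpc_cfg.L, "lambda": coev_cfg.lambda_,
            "alphabet": ALPHABET, "pair_index": "20*idx(a)+idx(b)",
            "normalize": normalize}
    return CmProfile(coeffs=coeffs, meta=meta)
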