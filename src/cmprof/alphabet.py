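"""The 20-letter amino-acid alphabet, residue/pair index conventions and
background frequencies.

Everything in the package indexes amino acids by their position in
``ALPHABET`` (alphabetical one-letter codes) and ordered amino-acid pairs
``(a, b)`` by ``20*idx(a) + idx(b)``.  Gaps and any non-standard residue
letter (B, Z, X, U, O, ...) are encoded as ``GAP_CODE`` and excluded from
all frequency counts, keeping the 20-letter alphabet exact.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
N_PAIRS = N_AA * N_AA
GAP_CODE = 20

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# BLOSUM62 amino-acid background frequencies, reordered to ALPHABET.
_BLOSUM62_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
BACKGROUND = np.array([_BLOSUM62_BG[aa] for aa in ALPHABET], dtype=float)
BACKGROUND /= BACKGROUND.sum()

_ENCODE_LUT = np.full(128, GAP_CODE, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_aa)] = _i
    _ENCODE_LUT[ord(_aa.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an aligned sequence string to int8 codes (gap/unknown -> 20)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[np.minimum(raw, 127)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] if c < N_AA else "-" for c in codes)


def pair_index(a: str | int, b: str | int) -> int:
    """Index of ordered pair (a, b) in the fixed 400-pair layout."""
    ia = AA_INDEX[a] if isinstance(a, str) else int(a)
    ib = AA_INDEX[b] if isinstance(b, str) else int(b)
    return N_AA * ia + ib
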