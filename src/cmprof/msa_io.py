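"""Reading, writing and thinning multiple sequence alignments, plus the
external profile and secondary-structure formats.

An :class:`Msa` is an aligned sequence set whose first record is the *seed*
sequence; every column where the seed has a gap is dropped on input, so that
columns index the seed residues directly (0-based internally, 1-based in all
user-facing output).  MSAs are thinned the way large automatically built
alignments usually are before coevolution analysis: sequences covering less
than half of the seed are removed and the remainder is clustered at 65%
identity, keeping one representative per cluster.

Sequence profiles (per-position amino-acid frequencies ``q`` and log-odds
scores ``t``) come either from a PSI-BLAST ASCII PSSM file (the 40-column
checkpoint text format) or, as a fallback, from the MSA itself via
:func:`build_profile`.  Predicted secondary structure is read from PSIPRED
``.ss2`` (VFORMAT) files or plain 3-state strings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .alphabet import ALPHABET, BACKGROUND, GAP_CODE, N_AA, decode, encode
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Msa",
    "SequenceProfile",
    "SecondaryStructure",
    "read_msa",
    "write_msa",
    "thin_msa",
    "build_profile",
    "read_psiblast_pssm",
    "write_psiblast_pssm",
    "read_ss2",
]


@dataclass
class Msa:
    """Aligned sequence set with a designated seed (first) sequence.

    ``rows`` are aligned strings over the 20 amino-acid letters plus ``-``;
    seed-gap columns have already been removed, so ``n`` (the number of
    columns) equals the seed length.
    """

    seed_id: str
    ids: list[str]
    rows: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("Msa requires at least one sequence")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows length mismatch")

    @property
    def n(self) -> int:
        """Seed length = number of columns."""
        return len(self.rows[0])

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def sequences(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.rows))

    def matrix(self) -> np.ndarray:
        """Int8 encoding, shape (n_seq, n); gaps and non-standard letters = 20."""
        if self._matrix is None:
            self._matrix = np.vstack([encode(r) for r in self.rows])
        return self._matrix


@dataclass
class SequenceProfile:
    """Per-position amino-acid frequencies ``q`` and log-odds scores ``t``.

    Both arrays have shape (n, 20) in ALPHABET order; each row of ``q`` is a
    probability vector.
    """

    q: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.q.shape != self.t.shape or self.q.ndim != 2 or self.q.shape[1] != N_AA:
            raise InputError(f"profile shapes must match and be (n, 20), got {self.q.shape} / {self.t.shape}")
        if np.any(self.q < -1e-12):
            raise InputError("negative frequencies in profile")
        sums = self.q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InputError("profile frequency rows must sum to 1")

    @property
    def n(self) -> int:
        return self.q.shape[0]


@dataclass
class SecondaryStructure:
    """Predicted 3-state secondary structure: H (helix), E (strand), C (coil)."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise InputError(f"illegal secondary-structure states {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.states)


def read_msa(path: str | Path, format: str = "fasta") -> Msa:
    """Read an aligned FASTA or Stockholm file; first record is the seed.

    Columns where the seed has a gap are dropped so positions index the seed.
    Illegal residue letters are mapped to gaps with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format not in ("fasta", "stockholm"):
        raise InputError(f"unsupported MSA format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "No records found" in msg or "Empty file" in msg:
            raise InputError(f"{path}: empty alignment file") from exc
        raise FormatError(f"{path}: {msg}") from exc
    ids = [rec.id for rec in aln]
    raw = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    legal = set(ALPHABET) | {"-"}
    cleaned = []
    for rid, row in zip(ids, raw):
        bad = sorted(set(row) - legal)
        if bad:
            logger.warning("%s: sequence %s has non-standard letters %s; treated as gaps",
                           path.name, rid, "".join(bad))
            row = re.sub(f"[^{ALPHABET}-]", "-", row)
        cleaned.append(row)
    keep = [k for k, ch in enumerate(cleaned[0]) if ch != "-"]
    rows = ["".join(row[k] for k in keep) for row in cleaned]
    return Msa(seed_id=ids[0], ids=ids, rows=rows)


def write_msa(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    """Write the MSA; round-trips byte-identically through :func:`read_msa`
    for alignments whose seed has no gap columns."""
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for rid, row in msa.sequences:
                fh.write(f">{rid}\n{row}\n")
    elif format == "stockholm":
        with path.open("w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(rid) for rid in msa.ids) + 2
            for rid, row in msa.sequences:
                fh.write(f"{rid:<{width}}{row}\n")
            fh.write("//\n")
    else:
        raise InputError(f"unsupported MSA format {format!r}")


def _coverage(row_codes: np.ndarray) -> float:
    return float(np.mean(row_codes != GAP_CODE))


def _identity(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise identity on pre-aligned rows.

    Matches over mutually non-gap columns, divided by the number of non-gap
    columns of the member with the smaller coverage.
    """
    both = (x != GAP_CODE) & (y != GAP_CODE)
    denom = min(int(np.sum(x != GAP_CODE)), int(np.sum(y != GAP_CODE)))
    if denom == 0:
        return 0.0
    matches = int(np.sum((x == y) & both))
    return matches / denom


def thin_msa(msa: Msa, min_coverage: float = 0.5, identity_cutoff: float = 0.65) -> Msa:
    """Remove sequences covering < ``min_coverage`` of the seed, then greedy
    leader clustering (Hobohm-1 style, input order) at ``identity_cutoff``.

    The seed is always retained; no two retained sequences share more than
    ``identity_cutoff`` identity.  Idempotent.
    """
    mat = msa.matrix()
    kept_idx: list[int] = [0]
    kept_rows: list[np.ndarray] = [mat[0]]
    for k in range(1, msa.n_seq):
        row = mat[k]
        if _coverage(row) < min_coverage:
            continue
        if any(_identity(row, r) > identity_cutoff for r in kept_rows):
            continue
        kept_idx.append(k)
        kept_rows.append(row)
    return Msa(seed_id=msa.seed_id,
               ids=[msa.ids[k] for k in kept_idx],
               rows=[msa.rows[k] for k in kept_idx])


def build_profile(msa: Msa, background: np.ndarray | None = None,
                  pseudocount_weight: float = 1.0) -> SequenceProfile:
    """Fallback sequence profile from column counts with pseudocount mixing.

    q(a_i) = (c(a_i) + w*bg_a) / (N_i + w); t(a_i) = log2(q(a_i)/bg_a).
    Gaps are excluded from counts; a column with zero observations gets
    q = background and t = 0.  A PSI-BLAST PSSM, when available, should be
    preferred (see :func:`read_psiblast_pssm`).
    """
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (N_AA,) or abs(bg.sum() - 1.0) > 1e-9:
        raise InputError("background must be a 20-vector summing to 1")
    if pseudocount_weight < 0:
        raise InputError("pseudocount_weight must be >= 0")
    mat = msa.matrix()
    counts = np.zeros((msa.n, N_AA), dtype=float)
    for a in range(N_AA):
        counts[:, a] = np.sum(mat == a, axis=0)
    totals = counts.sum(axis=1)
    q = np.empty_like(counts)
    empty = totals == 0
    with np.errstate(invalid="ignore"):
        q = (counts + pseudocount_weight * bg) / (totals + pseudocount_weight)[:, None]
    if pseudocount_weight == 0:
        q[empty] = bg
    # q can only be 0 with zero pseudocount weight; score such letters 0 so
    # downstream cross-products stay finite (they carry zero frequency anyway).
    t = np.where(q > 0, np.log2(np.maximum(q, 1e-300) / bg), 0.0)
    t[empty] = 0.0
    return SequenceProfile(q=q, t=t)


# PSI-BLAST ASCII PSSM (-Q output): header line of 40 amino-acid letters,
# then one row per position: index, residue, 20 integer scores, 20 percentages.
def read_psiblast_pssm(path: str | Path) -> SequenceProfile:
    """Parse the 40-column PSI-BLAST ASCII PSSM text format.

    ``t`` comes from the first 20 (score) columns as printed; ``q`` from the
    20 percentage columns divided by 100 and renormalized.  An all-zero
    percentage row falls back to the uniform distribution with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    header_at = 0
    for ln, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 40 and all(tok in ALPHABET for tok in tokens[:40]):
            header_cols = tokens[:40]
            header_at = ln
            break
    if header_cols is None:
        raise FormatError(f"{path}: no 40-column amino-acid header found")
    score_order = [header_cols[k] for k in range(20)]
    freq_order = [header_cols[20 + k] for k in range(20)]
    t_rows, q_rows = [], []
    expected_idx = 0
    for ln in range(header_at + 1, len(lines)):
        tokens = lines[ln].split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (K, Lambda)
        if len(tokens) < 42:
            raise FormatError(f"{path}:{ln + 1}: expected >= 42 fields, got {len(tokens)}")
        expected_idx += 1
        if int(tokens[0]) != expected_idx:
            raise FormatError(f"{path}:{ln + 1}: position index {tokens[0]} out of order")
        try:
            scores = [float(v) for v in tokens[2:22]]
            freqs = [float(v) for v in tokens[22:42]]
        except ValueError as exc:
            raise FormatError(f"{path}:{ln + 1}: non-numeric PSSM field") from exc
        t_row = np.zeros(N_AA)
        q_row = np.zeros(N_AA)
        for col, aa in enumerate(score_order):
            t_row[ALPHABET.index(aa)] = scores[col]
        for col, aa in enumerate(freq_order):
            q_row[ALPHABET.index(aa)] = freqs[col] / 100.0
        t_rows.append(t_row)
        q_rows.append(q_row)
    if not t_rows:
        raise FormatError(f"{path}: no PSSM rows found")
    q = np.vstack(q_rows)
    t = np.vstack(t_rows)
    zero = q.sum(axis=1) <= 0
    if np.any(zero):
        logger.warning("%s: %d all-zero frequency rows set to uniform", path.name, int(zero.sum()))
        q[zero] = 1.0 / N_AA
    q /= q.sum(axis=1, keepdims=True)
    return SequenceProfile(q=q, t=t)


def write_psiblast_pssm(profile: SequenceProfile, path: str | Path,
                        seq: str | None = None) -> None:
    """Write a profile in the PSI-BLAST ASCII PSSM layout (floats allowed),
    round-tripping q and t through :func:`read_psiblast_pssm`."""
    path = Path(path)
    seq = seq or "".join(ALPHABET[int(np.argmax(row))] for row in profile.q)
    with path.open("w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(list(ALPHABET) * 2) + "\n")
        for i in range(profile.n):
            t_part = " ".join(f"{v:.4f}" for v in profile.t[i])
            q_part = " ".join(f"{100.0 * v:.6f}" for v in profile.q[i])
            fh.write(f"{i + 1:5d} {seq[i]} {t_part}  {q_part}\n")
        fh.write("\n                      K         Lambda\n")


# PSIPRED .ss2 column order is (coil, helix, strand); ties resolved H > E > C.
_SS_PRIORITY = ("H", "E", "C")


def read_ss2(path: str | Path) -> SecondaryStructure:
    """Read a PSIPRED VFORMAT .ss2 file; per-row argmax state, ties H > E > C."""
    path = Path(path)
    states = []
    for ln, line in enumerate(path.read_text().splitlines()):
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        if len(tokens) < 6 or not tokens[0].isdigit():
            raise FormatError(f"{path}:{ln + 1}: malformed .ss2 row")
        p_c, p_h, p_e = (float(tokens[3]), float(tokens[4]), float(tokens[5]))
        probs = {"H": p_h, "E": p_e, "C": p_c}
        best = max(_SS_PRIORITY, key=lambda s: (probs[s], -_SS_PRIORITY.index(s)))
        states.append(best)
    if not states:
        raise InputError(f"{path}: no secondary-structure rows")
    return SecondaryStructure(states="".join(states))
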