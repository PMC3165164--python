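"""Model building by C-alpha coordinate copying and MaxSub model-quality
scoring.

A backbone model for the first protein (the target) is built from an
alignment by copying, at every aligned position, the C-alpha coordinate of
the second protein (the template).  MaxSub then measures how much of the
model superimposes well on the target's experimental structure: every
contiguous window of aligned residues seeds a least-squares (Kabsch)
superposition that is iteratively extended over all residues closer than a
distance threshold d; the best subset found scores

    sum over subset of 1 / (1 + (d_i / d)^2)

normalized by the reference length, giving a value in [0, 1] — 0 for a
completely wrong model, 1 for a perfect one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignmentResult
from .errors import DegenerateError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CaTrace",
    "MaxSubResult",
    "read_pdb_ca",
    "write_pdb_ca",
    "build_model",
    "kabsch",
    "maxsub",
    "average_maxsub",
]


@dataclass
class CaTrace:
    """C-alpha trace: residue identifiers (1-based seed positions) and 3D
    coordinates in Angstrom."""

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.ids.shape[0], 3):
            raise InputError("coords must be (len(ids), 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.ids)

    def lookup(self) -> dict[int, int]:
        return {int(r): k for k, r in enumerate(self.ids)}


@dataclass
class MaxSubResult:
    """MaxSub score in [0, 1], the best superimposable residue-pair subset,
    and the RMSD over that subset."""

    score: float
    subset: list[tuple[int, int]] = field(default_factory=list)
    rmsd_subset: float = float("nan")


def read_pdb_ca(path: str | Path, chain: str | None = None) -> CaTrace:
    """First-model, first-altloc C-alpha atoms of one chain of a PDB file."""
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    model = st[0]
    chains = [c.name for c in model]
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise InputError(f"{path}: no chain {chain!r}; available {chains}")
    ids, coords = [], []
    for res in model[chain]:
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                ids.append(res.seqid.num)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                break
    if not ids:
        raise InputError(f"{path}: chain {chain!r} has no C-alpha atoms")
    return CaTrace(ids=np.array(ids), coords=np.array(coords))


def write_pdb_ca(trace: CaTrace, path: str | Path, chain: str = "A") -> None:
    """Write a C-alpha-only PDB file (ALA residues)."""
    with Path(path).open("w") as fh:
        for k, (rid, xyz) in enumerate(zip(trace.ids, trace.coords), start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  ALA {chain}{int(rid):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")


def build_model(alignment: AlignmentResult, template: CaTrace,
                target_length: int | None = None) -> CaTrace:
    """Copy template C-alpha coordinates onto the target per the alignment.

    The model contains only aligned target residues; pairs whose template
    position lacks coordinates are skipped with a warning.
    """
    lut = template.lookup()
    ids, coords = [], []
    for i, j in alignment.pairs:
        tid = j + 1  # template residue id (1-based)
        if target_length is not None and i >= target_length:
            raise InputError(f"aligned target position {i + 1} exceeds target length {target_length}")
        k = lut.get(tid)
        if k is None:
            logger.warning("template residue %d missing coordinates; pair skipped", tid)
            continue
        ids.append(i + 1)
        coords.append(template.coords[k])
    if not ids:
        return CaTrace(ids=np.zeros(0, dtype=int), coords=np.zeros((0, 3)))
    return CaTrace(ids=np.array(ids), coords=np.array(coords))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q.

    Returns (R, t, rmsd) with R a proper rotation (det +1) such that
    ``P @ R.T + t`` minimizes the RMSD to Q.  Requires >= 3 non-collinear
    points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise InputError("P and Q must be matching (m, 3) arrays")
    m = P.shape[0]
    if m < 3:
        raise DegenerateError(f"need >= 3 points, got {m}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateError("collinear point set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def _maxsub_value(d: np.ndarray, threshold: float) -> float:
    return float(np.sum(1.0 / (1.0 + (d / threshold) ** 2)))


def maxsub(model: CaTrace, reference: CaTrace,
           pairs: list[tuple[int, int]] | None = None,
           d_threshold: float = 3.5, seed_len: int = 4,
           normalize_by: int | None = None, max_iter: int = 20) -> MaxSubResult:
    """Seed-and-extend search for the largest well-superimposable subset.

    Every contiguous window of ``seed_len`` corresponding residues seeds a
    Kabsch superposition, iteratively re-fit on the residues within
    ``d_threshold`` until a fixed point (at most ``max_iter`` rounds).  The
    subset maximizing sum 1/(1+(d_i/d)^2) wins; the score divides that sum
    by ``normalize_by`` (default: reference length).
    """
    if pairs is None:
        ref_lut = reference.lookup()
        pairs = [(int(r), int(r)) for r in model.ids if int(r) in ref_lut]
    norm = normalize_by if normalize_by is not None else len(reference)
    if norm <= 0:
        raise InputError("normalize_by must be positive")
    k = len(pairs)
    if k < seed_len:
        return MaxSubResult(score=0.0)
    mod_lut = model.lookup()
    ref_lut = reference.lookup()
    Pm = np.array([model.coords[mod_lut[a]] for a, _ in pairs])
    Pr = np.array([reference.coords[ref_lut[b]] for _, b in pairs])

    best_value = 0.0
    best_mask: np.ndarray | None = None
    best_rmsd = float("nan")
    for w in range(k - seed_len + 1):
        window = slice(w, w + seed_len)
        try:
            R, t, _ = kabsch(Pm[window], Pr[window])
        except DegenerateError:
            continue
        mask = np.zeros(k, dtype=bool)
        mask[window] = True
        for _ in range(max_iter):
            d = np.linalg.norm(Pm @ R.T + t - Pr, axis=1)
            new_mask = d < d_threshold
            if new_mask.sum() < 3 or np.array_equal(new_mask, mask):
                mask = new_mask if new_mask.sum() >= 3 else mask
                break
            mask = new_mask
            try:
                R, t, _ = kabsch(Pm[mask], Pr[mask])
            except DegenerateError:
                break
        d = np.linalg.norm(Pm @ R.T + t - Pr, axis=1)
        inside = d < d_threshold
        if not inside.any():
            continue
        value = _maxsub_value(d[inside], d_threshold)
        if value > best_value:
            best_value = value
            best_mask = inside
            diff = d[inside]
            best_rmsd = float(np.sqrt(np.mean(diff * diff)))
    if best_mask is None:
        return MaxSubResult(score=0.0)
    subset = [pairs[idx] for idx in np.flatnonzero(best_mask)]
    return MaxSubResult(score=min(best_value / norm, 1.0), subset=subset, rmsd_subset=best_rmsd)


def average_maxsub(results: list[MaxSubResult]) -> float:
    """Arithmetic mean MaxSub score over a set of alignment/structure pairs."""
    if not results:
        raise InputError("average_maxsub needs at least one result")
    return float(np.mean([r.score for r in results]))
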