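"""Deterministic synthetic-data generators.

These give every part of the pipeline realistic, fully-specified inputs
without any database downloads: star-phylogeny MSAs with planted covarying
column pairs, pairs of sister sequence families with a known residue
correspondence, and idealized C-alpha traces.  All generators are pure
functions of their seed.

The MSA model draws each sequence independently around an ancestral
sequence (a star phylogeny — no tree structure).  Each column uses a small
random subset of the 20 amino acids so that toy alignments stay informative
at modest depths.  A planted pair (i, j) substitutes compensatorily: with
probability equal to its coupling strength the two positions are drawn
jointly from one of two paired state combinations, otherwise independently
like any other column.
"""

from __future__ import annotations

import numpy as np

from .alphabet import ALPHABET, N_AA
from .assess import CaTrace
from .errors import InputError
from .msa_io import Msa

__all__ = ["simulate_msa", "simulate_sister_families", "simulate_ca_trace"]


def _check_planted(planted_pairs, n: int) -> None:
    used: set[int] = set()
    for i, j, c in planted_pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise InputError(f"planted pair ({i}, {j}) out of range or degenerate")
        if i in used or j in used:
            raise InputError("planted pairs must be disjoint")
        if not (0.0 <= c <= 1.0):
            raise InputError("coupling strength must be in [0, 1]")
        used.update((i, j))


def _draw_rows(rng, n_seq, n, col_states, ancestral, planted, mutation_rate):
    """Sample the sequence matrix given per-column state sets and planted
    pairings; the first row is the unmutated ancestor (the seed)."""
    mat = np.empty((n_seq, n), dtype=np.int8)
    mat[0] = ancestral
    k = col_states.shape[1]
    for s in range(1, n_seq):
        row = ancestral.copy()
        mutate = rng.random(n) < mutation_rate
        choice = rng.integers(0, k, size=n)
        row[mutate] = col_states[np.arange(n), choice][mutate]
        for i, j, c in planted:
            if rng.random() < c:
                # compensatory substitution: both positions jump together
                state = rng.integers(0, 2)
                row[i] = col_states[i, state]
                row[j] = col_states[j, state]
        mat[s] = row
    return mat


def simulate_msa(n: int, n_seq: int,
                 planted_pairs: list[tuple[int, int, float]] | None = None,
                 mutation_rate: float = 0.35,
                 states_per_column: int = 4,
                 seed: int = 0) -> tuple[Msa, list[tuple[int, int]]]:
    """Synthetic MSA with planted covarying column pairs.

    Returns the Msa (seed sequence first) and the ground-truth list of
    planted (i, j) positions (0-based).  Reproducible given ``seed``.
    """
    if not (0.0 < mutation_rate < 1.0):
        raise InputError("mutation_rate must be in (0, 1)")
    if not (2 <= states_per_column <= N_AA):
        raise InputError("states_per_column must be in [2, 20]")
    planted = list(planted_pairs or [])
    _check_planted(planted, n)
    rng = np.random.default_rng(seed)
    col_states = np.vstack([
        rng.choice(N_AA, size=states_per_column, replace=False) for _ in range(n)
    ]).astype(np.int8)
    ancestral = col_states[:, 0].copy()
    mat = _draw_rows(rng, n_seq, n, col_states, ancestral, planted, mutation_rate)
    rows = ["".join(ALPHABET[c] for c in row) for row in mat]
    ids = ["seed"] + [f"seq{k}" for k in range(1, n_seq)]
    return Msa(seed_id="seed", ids=ids, rows=rows), [(i, j) for i, j, _ in planted]


def simulate_sister_families(n: int = 80, n_seq: int = 300,
                             n_planted: int = 8,
                             divergence: float = 0.3,
                             indel_rate: float = 0.05,
                             mutation_rate: float = 0.35,
                             coupling: float = 0.9,
                             states_per_column: int = 4,
                             seed: int = 0
                             ) -> tuple[Msa, Msa, list[tuple[int, int]]]:
    """Two descendant families of a shared ancestor with shared planted
    covariation and a known column-to-column correspondence.

    Each family mutates the shared ancestor (family B's ancestor differs
    from A's at a ``divergence`` fraction of columns) and then deletes
    non-planted columns independently at ``indel_rate``, so the ground-truth
    correspondence maps the columns surviving in both families (0-based
    positions after deletion).
    """
    if not (0.0 < divergence < 1.0):
        raise InputError("divergence must be in (0, 1)")
    if not (0.0 <= indel_rate < 1.0):
        raise InputError("indel_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    col_states = np.vstack([
        rng.choice(N_AA, size=states_per_column, replace=False) for _ in range(n)
    ]).astype(np.int8)
    positions = rng.permutation(n)[: 2 * n_planted]
    planted = [(int(positions[2 * k]), int(positions[2 * k + 1]), coupling)
               for k in range(n_planted)]
    _check_planted(planted, n)
    planted_cols = {p for i, j, _ in planted for p in (i, j)}

    anc_a = col_states[:, 0].copy()
    anc_b = anc_a.copy()
    diverge = rng.random(n) < divergence
    alt = col_states[np.arange(n), rng.integers(1, states_per_column, size=n)]
    anc_b[diverge] = alt[diverge]

    keep = []
    for anc in (anc_a, anc_b):
        drop = (rng.random(n) < indel_rate) & ~np.isin(np.arange(n), list(planted_cols))
        keep.append(~drop)

    msas = []
    for fam, (anc, kept) in enumerate(zip((anc_a, anc_b), keep)):
        mat = _draw_rows(rng, n_seq, n, col_states, anc, planted, mutation_rate)
        mat = mat[:, kept]
        rows = ["".join(ALPHABET[c] for c in row) for row in mat]
        ids = ["seed"] + [f"fam{fam}_seq{k}" for k in range(1, n_seq)]
        msas.append(Msa(seed_id="seed", ids=ids, rows=rows))

    pos_a = np.cumsum(keep[0]) - 1  # original column -> family-A position
    pos_b = np.cumsum(keep[1]) - 1
    correspondence = [(int(pos_a[c]), int(pos_b[c]))
                      for c in range(n) if keep[0][c] and keep[1][c]]
    return msas[0], msas[1], correspondence


def simulate_ca_trace(length: int, geometry: str = "helix", seed: int = 0) -> CaTrace:
    """Idealized C-alpha trace with ~3.8 A consecutive spacing.

    ``geometry``: "helix" (ideal alpha-helix: rise 1.5 A, 100 deg/residue,
    radius chosen for 3.8 A Ca-Ca), "extended" (flat zigzag) or
    "random-walk" (fixed-step random directions).
    """
    if length < 4:
        raise InputError("length must be >= 4")
    rng = np.random.default_rng(seed)
    idx = np.arange(length)
    if geometry == "helix":
        rise, theta = 1.5, np.deg2rad(100.0)
        radius = np.sqrt((3.8**2 - rise**2) / (2.0 * (1.0 - np.cos(theta))))
        coords = np.column_stack([
            radius * np.cos(theta * idx),
            radius * np.sin(theta * idx),
            rise * idx,
        ])
    elif geometry == "extended":
        half_width = 0.95
        dx = np.sqrt(3.8**2 - (2 * half_width) ** 2)
        coords = np.column_stack([
            dx * idx,
            half_width * np.where(idx % 2 == 0, 1.0, -1.0),
            np.zeros(length),
        ])
    elif geometry == "random-walk":
        steps = rng.standard_normal((length - 1, 3))
        steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise InputError(f"unknown geometry {geometry!r}")
    return CaTrace(ids=idx + 1, coords=coords)
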