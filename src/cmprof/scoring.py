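"""Position-pair similarity terms and the combined alignment score matrix.

The alignment score between position i of one protein and position j of
another is the weighted sum

    S(i, j) = w_mut * S_mut(i, j) + w_cor * S_cor(i, j) + w_sec * S_sec(i, j)

with
  * S_mut — the symmetric sequence-profile cross score
    0.5 * sum_a [ q(a_i) t(a_j) + q(a_j) t(a_i) ] over the 20 amino acids,
  * S_cor — the CM-profile score alpha * mean_{(a,b)} [ d0 - d(c(a_i,b),
    c(a_j,b)) ], positive when the mean Euclidean distance between the two
    positions' 400 cepstral vectors is below the threshold d0,
  * S_sec — 1 if the predicted secondary-structure states match, else 0.

Named parameter presets bundle the weights, d0, the baseline shift and the
affine gap penalties selected for each scoring-term combination (profile
only, profile+SS, CM only, CM+profile, CM+profile+SS).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigError, InputError
from .lpc import CmProfile
from .msa_io import SecondaryStructure, SequenceProfile

__all__ = [
    "ScoringParams",
    "ScoreMatrix",
    "PRESET_NAMES",
    "load_preset",
    "s_mut",
    "s_mut_matrix",
    "s_cor",
    "s_cor_matrix",
    "s_sec",
    "s_sec_matrix",
    "score_matrix",
]

PRESET_NAMES = ("ppa", "ppa_ss", "cmpa", "cmpa_ppa", "cmpa_ppa_ss")


@dataclass
class ScoringParams:
    """Weights, CM-score threshold/scale, baseline and affine gap penalties.

    ``base`` is subtracted from every substitution score before alignment;
    a gap of length k costs g_open + (k-1)*g_ext.
    """

    w_mut: float = 1.0
    w_sec: float = 0.0
    w_cor: float = 0.0
    d0: float = 3.2
    alpha: float = 0.025
    base: float = 0.0
    g_open: float = 8.0
    g_ext: float = 0.6
    cor_aggregate: str = "mean"  # "mean" or "sum" over the 400 pairs
    base_sign: int = -1          # -1: subtract base from scores; +1: add

    def __post_init__(self) -> None:
        if not (self.g_open >= self.g_ext >= 0):
            raise ConfigError("require g_open >= g_ext >= 0")
        if self.alpha <= 0 or self.d0 <= 0:
            raise ConfigError("alpha and d0 must be positive")
        if self.cor_aggregate not in ("mean", "sum"):
            raise ConfigError("cor_aggregate must be 'mean' or 'sum'")
        if self.base_sign not in (-1, 1):
            raise ConfigError("base_sign must be -1 or +1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScoringParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_preset(name: str) -> ScoringParams:
    """Load one of the bundled parameter presets by name."""
    key = name.lower()
    if key not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    ref = importlib.resources.files("cmprof").joinpath(f"presets/{key}.yaml")
    return ScoringParams.from_dict(yaml.safe_load(ref.read_text()))


@dataclass
class ScoreMatrix:
    """Combined score matrix S (n1 x n2) with optional per-term components."""

    S: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape


def s_mut_matrix(p1: SequenceProfile, p2: SequenceProfile) -> np.ndarray:
    """Sequence-profile score for all position pairs: 0.5*(Q1 T2' + T1 Q2')."""
    return 0.5 * (p1.q @ p2.t.T + p1.t @ p2.q.T)


def s_mut(p1: SequenceProfile, p2: SequenceProfile, i: int, j: int) -> float:
    return float(0.5 * (np.dot(p1.q[i], p2.t[j]) + np.dot(p2.q[j], p1.t[i])))


def _check_cm_compatible(c1: CmProfile, c2: CmProfile) -> None:
    for key in ("p", "L", "lambda", "alphabet", "pair_index", "normalize"):
        if c1.meta.get(key) != c2.meta.get(key):
            raise ConfigError(
                f"CM profiles built with different conventions: {key} "
                f"{c1.meta.get(key)!r} vs {c2.meta.get(key)!r}")


def s_cor_matrix(c1: CmProfile, c2: CmProfile, params: ScoringParams) -> np.ndarray:
    """CM-profile score for all position pairs.

    Euclidean distances between the L-vectors of corresponding amino-acid
    pairs, thresholded at d0, aggregated over the 400 pairs and scaled by
    alpha.
    """
    _check_cm_compatible(c1, c2)
    a1 = c1.coeffs
    a2 = c2.coeffs
    sq1 = np.einsum("ipl,ipl->ip", a1, a1)
    sq2 = np.einsum("jpl,jpl->jp", a2, a2)
    cross = np.einsum("ipl,jpl->ijp", a1, a2)
    d2 = sq1[:, None, :] + sq2[None, :, :] - 2.0 * cross
    d = np.sqrt(np.maximum(d2, 0.0))
    margin = params.d0 - d
    agg = margin.mean(axis=2) if params.cor_aggregate == "mean" else margin.sum(axis=2)
    return params.alpha * agg


def s_cor(c1: CmProfile, c2: CmProfile, i: int, j: int, params: ScoringParams) -> float:
    _check_cm_compatible(c1, c2)
    d = np.linalg.norm(c1.coeffs[i] - c2.coeffs[j], axis=1)
    margin = params.d0 - d
    agg = margin.mean() if params.cor_aggregate == "mean" else margin.sum()
    return float(params.alpha * agg)


def s_sec_matrix(ss1: SecondaryStructure, ss2: SecondaryStructure) -> np.ndarray:
    a = np.frombuffer(ss1.states.encode(), dtype=np.uint8)
    b = np.frombuffer(ss2.states.encode(), dtype=np.uint8)
    return (a[:, None] == b[None, :]).astype(float)


def s_sec(ss1: SecondaryStructure, ss2: SecondaryStructure, i: int, j: int) -> int:
    """1 if the predicted states at i and j are identical, 0 otherwise."""
    return int(ss1.states[i] == ss2.states[j])


def score_matrix(params: ScoringParams,
                 terms: tuple[str, ...] = ("mut",),
                 profile1: SequenceProfile | None = None,
                 profile2: SequenceProfile | None = None,
                 cm1: CmProfile | None = None,
                 cm2: CmProfile | None = None,
                 ss1: SecondaryStructure | None = None,
                 ss2: SecondaryStructure | None = None,
                 keep_components: bool = True) -> ScoreMatrix:
    """Weighted combination of the requested similarity terms.

    Raises ConfigError naming any requested term whose inputs are missing.
    """
    unknown = set(terms) - {"mut", "cor", "sec"}
    if unknown:
        raise ConfigError(f"unknown scoring terms {sorted(unknown)}")
    if not terms:
        raise InputError("at least one scoring term required")
    components: dict[str, np.ndarray] = {}
    S: np.ndarray | None = None
    weights = {"mut": params.w_mut, "cor": params.w_cor, "sec": params.w_sec}
    for term in terms:
        if term == "mut":
            if profile1 is None or profile2 is None:
                raise ConfigError("term 'mut' requested but sequence profiles missing")
            comp = s_mut_matrix(profile1, profile2)
        elif term == "cor":
            if cm1 is None or cm2 is None:
                raise ConfigError("term 'cor' requested but CM profiles missing")
            comp = s_cor_matrix(cm1, cm2, params)
        else:
            if ss1 is None or ss2 is None:
                raise ConfigError("term 'sec' requested but secondary structures missing")
            comp = s_sec_matrix(ss1, ss2)
        if S is None:
            S = weights[term] * comp
        else:
            if comp.shape != S.shape:
                raise ConfigError(f"term {term!r} matrix shape {comp.shape} != {S.shape}")
            S = S + weights[term] * comp
        if keep_components:
            components[term] = comp
    return ScoreMatrix(S=S, components=components)
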