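"""Simulated-annealing selection of scoring parameters.

The objective — typically the average MaxSub score of models built from the
alignments of a training set — is maximized with a Metropolis walk:
Gaussian proposals clipped to per-parameter boxes, acceptance probability
exp(delta / T) for worsening moves, geometric cooling T_k = T0 * gamma^k
with a fixed number of proposals per temperature.  The best-ever state is
returned together with a full evaluation trace; runs are reproducible given
the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .scoring import ScoringParams

logger = logging.getLogger(__name__)

__all__ = ["AnnealConfig", "AnnealResult", "anneal", "tune_scoring_params"]


@dataclass
class AnnealConfig:
    """Search box and schedule for simulated annealing."""

    x0: np.ndarray
    step: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    T0: float = 1.0
    gamma: float = 0.95
    n_per_temp: int = 20
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.step = np.broadcast_to(np.asarray(self.step, dtype=float), self.x0.shape).copy()
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), self.x0.shape).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), self.x0.shape).copy()
        if self.T0 <= 0:
            raise InputError("T0 must be > 0")
        if not (0.0 < self.gamma < 1.0):
            raise InputError("gamma must be in (0, 1)")
        if self.n_steps < 1 or self.n_per_temp < 1:
            raise InputError("n_steps and n_per_temp must be >= 1")
        if np.any(self.lower > self.upper):
            raise InputError("lower bound exceeds upper bound")
        if np.any(self.x0 < self.lower) or np.any(self.x0 > self.upper):
            raise InputError("x0 outside the search box")


@dataclass
class AnnealResult:
    best_x: np.ndarray
    best_value: float
    trace: list[dict] = field(default_factory=list)


def anneal(objective, cfg: AnnealConfig) -> AnnealResult:
    """Maximize ``objective`` over the search box; returns best-ever state.

    A proposal whose evaluation raises is rejected and logged.  The trace
    records every evaluation (step, temperature, x, value, accepted,
    running best).
    """
    rng = np.random.default_rng(cfg.seed)
    x = cfg.x0.copy()
    value = float(objective(x))
    if not np.isfinite(value):
        raise InputError("objective not finite at x0")
    best_x, best_value = x.copy(), value
    trace: list[dict] = [{"step": 0, "T": cfg.T0, "x": x.copy(), "value": value,
                          "accepted": True, "best": best_value}]
    for step in range(1, cfg.n_steps + 1):
        T = cfg.T0 * cfg.gamma ** ((step - 1) // cfg.n_per_temp)
        prop = np.clip(x + cfg.step * rng.standard_normal(x.shape), cfg.lower, cfg.upper)
        u = rng.random()  # drawn unconditionally to keep the stream aligned
        try:
            v = float(objective(prop))
        except Exception as exc:  # noqa: BLE001 - objective failures reject the step
            logger.warning("objective raised at step %d: %s", step, exc)
            trace.append({"step": step, "T": T, "x": prop, "value": float("nan"),
                          "accepted": False, "best": best_value})
            continue
        delta = v - value
        accept = delta >= 0 or u < np.exp(delta / T)
        if accept:
            x, value = prop, v
            if v > best_value:
                best_x, best_value = prop.copy(), v
        trace.append({"step": step, "T": T, "x": prop, "value": v,
                      "accepted": bool(accept), "best": best_value})
    return AnnealResult(best_x=best_x, best_value=best_value, trace=trace)


# Default tuned fields and boxes for ScoringParams searches.
_DEFAULT_BOXES = {
    "w_mut": (0.0, 3.0, 0.1),
    "w_sec": (0.0, 3.0, 0.1),
    "w_cor": (0.0, 3.0, 0.1),
    "d0": (0.5, 6.0, 0.2),
    "base": (-2.0, 2.0, 0.1),
    "g_open": (0.5, 15.0, 0.5),
    "g_ext": (0.0, 3.0, 0.1),
}


def tune_scoring_params(objective, start: ScoringParams,
                        fields: tuple[str, ...] = ("w_mut", "w_cor", "d0", "base", "g_open", "g_ext"),
                        T0: float = 0.05, gamma: float = 0.9,
                        n_per_temp: int = 20, n_steps: int = 500,
                        seed: int = 0) -> tuple[ScoringParams, float, list[dict]]:
    """Anneal selected ScoringParams fields against ``objective(params)``.

    g_ext is clipped to g_open so the affine-cost invariant always holds.
    """
    for f in fields:
        if f not in _DEFAULT_BOXES:
            raise InputError(f"cannot tune field {f!r}")

    def vec_to_params(x: np.ndarray) -> ScoringParams:
        kwargs = dict(zip(fields, (float(v) for v in x)))
        if "g_ext" in kwargs:
            cap = kwargs.get("g_open", start.g_open)
            kwargs["g_ext"] = min(kwargs["g_ext"], cap)
        return replace(start, **kwargs)

    cfg = AnnealConfig(
        x0=np.array([getattr(start, f) for f in fields]),
        step=np.array([_DEFAULT_BOXES[f][2] for f in fields]),
        lower=np.array([_DEFAULT_BOXES[f][0] for f in fields]),
        upper=np.array([_DEFAULT_BOXES[f][1] for f in fields]),
        T0=T0, gamma=gamma, n_per_temp=n_per_temp, n_steps=n_steps, seed=seed)
    res = anneal(lambda x: objective(vec_to_params(x)), cfg)
    return vec_to_params(res.best_x), res.best_value, res.trace
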