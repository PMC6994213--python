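"""Forward model and goal inversion for curiosity-driven exploration.

The forward model is a locally weighted linear regression (LWR): a Gaussian
kernel over stored formulations weights a per-query ridge-regularized linear
fit, one independent fit per observation dimension. Goal inversion searches
the mixture simplex (via the unit box with candidate renormalization) for
the formulation whose predicted observation, mapped to the unit square, is
closest to a target — the "infer parameters for this self-generated goal"
step of the curiosity loop. An exhaustive simplex-lattice minimizer of the
same cost is provided as an independent test oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._cmaes import cmaes_minimize
from .core_data import (
    BehaviorObservation,
    ConfigError,
    ExplorationDataset,
    ObservationBounds,
    OilFormulation,
    normalize_formulation,
    observation_to_goalspace,
)

__all__ = [
    "ForwardModelConfig",
    "InversionConfig",
    "ModelUnavailableError",
    "lwr_predict",
    "invert_goal",
    "grid_invert_oracle",
    "inversion_cost",
]

_TIE_TOL = 1e-12


class ModelUnavailableError(RuntimeError):
    """Raised when the dataset cannot support a forward-model prediction."""


@dataclass(frozen=True)
class ForwardModelConfig:
    """Locally weighted linear regression hyperparameters.

    ``bandwidth_h`` is the Gaussian kernel width in raw ratio space (default
    0.1, so a small neighborhood of the query carries non-negligible weight);
    below ``min_points`` of effective kernel support the prediction falls
    back to the kernel-weighted mean (a local linear fit in 4 inputs needs
    at least 5 points).
    """

    bandwidth_h: float = 0.1
    ridge_lambda: float = 1e-6
    min_points: int = 5

    def __post_init__(self) -> None:
        if self.bandwidth_h <= 0:
            raise ConfigError(f"bandwidth_h must be > 0, got {self.bandwidth_h}")
        if self.ridge_lambda < 0:
            raise ConfigError(f"ridge_lambda must be >= 0, got {self.ridge_lambda}")
        if self.min_points < 1:
            raise ConfigError(f"min_points must be >= 1, got {self.min_points}")


@dataclass(frozen=True)
class InversionConfig:
    """Evolution-strategy settings for goal inversion."""

    sigma0: float = 0.3
    max_evaluations: int = 240
    population_size: int | None = None
    restarts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ConfigError(f"sigma0 must be > 0, got {self.sigma0}")
        pop = self.population_size or 4 + int(3 * np.log(4))
        if self.max_evaluations < pop:
            raise ConfigError("max_evaluations must be >= population_size")
        if self.restarts < 0:
            raise ConfigError("restarts must be >= 0")


def _kernel_weights(X: np.ndarray, xq: np.ndarray, h: float) -> np.ndarray:
    d2 = np.sum((X - xq) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * h * h))


def _predict_arrays(
    X: np.ndarray, Y: np.ndarray, xq: np.ndarray, cfg: ForwardModelConfig
) -> np.ndarray:
    """Raw LWR prediction on bare arrays (hot path of goal inversion)."""
    w = _kernel_weights(X, xq, cfg.bandwidth_h)
    wsum = float(w.sum())
    if wsum <= 0.0:
        # kernel underflow: fall back to the nearest stored point
        i = int(np.argmin(np.sum((X - xq) ** 2, axis=1)))
        pred = Y[i]
    else:
        n_eff = wsum * wsum / float(np.sum(w * w))
        if X.shape[0] >= cfg.min_points and n_eff >= cfg.min_points:
            A = np.column_stack([np.ones(X.shape[0]), X - xq])
            AW = A * w[:, None]
            lhs = AW.T @ A
            reg = np.eye(5) * cfg.ridge_lambda
            reg[0, 0] = 0.0  # intercept unpenalized
            lhs = lhs + reg
            rhs = AW.T @ Y
            try:
                beta = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
            pred = beta[0]  # fit evaluated at the (centered) query
        else:
            pred = (w @ Y) / wsum
    return np.maximum(pred, 0.0)


def lwr_predict(
    ds: ExplorationDataset, query: OilFormulation, cfg: ForwardModelConfig | None = None
) -> BehaviorObservation:
    """Predict the behavior of a formulation from past experiments.

    Kernel weights w_i = exp(-||x_i - x_q||^2 / (2 h^2)) select a local
    neighborhood. If the effective (Kish) sample size of the weights reaches
    ``min_points``, each observation dimension is fitted by weighted ridge
    regression on query-centered ratios and the fit is evaluated at the
    query; otherwise the w-weighted mean of stored observations is returned.
    Predictions are clipped to be non-negative.
    """
    cfg = cfg or ForwardModelConfig()
    if len(ds) == 0:
        raise ModelUnavailableError("cannot predict from an empty dataset")
    pred = _predict_arrays(ds.formulations(), ds.observations(), query.as_array(), cfg)
    return BehaviorObservation(float(pred[0]), float(pred[1]))


def inversion_cost(
    ds: ExplorationDataset,
    goal: np.ndarray,
    fm_cfg: ForwardModelConfig,
    bounds: ObservationBounds,
    box_point: np.ndarray,
) -> float:
    """Squared goal-space distance between the prediction at a box candidate and a goal.

    The candidate (a point in [0,1]^4) is renormalized onto the simplex
    before prediction; a degenerate all-zero candidate costs +inf.
    """
    x = np.clip(np.asarray(box_point, dtype=float), 0.0, 1.0)
    s = x.sum()
    if s <= 1e-12:
        return float("inf")
    pred = _predict_arrays(ds.formulations(), ds.observations(), x / s, fm_cfg)
    lo, hi = bounds.lows(), bounds.highs()
    z = np.clip((pred - lo) / (hi - lo), 0.0, 1.0)
    diff = z - np.asarray(goal, dtype=float)
    return float(diff @ diff)


def _audit_grid_points() -> list[np.ndarray]:
    """Fixed 4-level-per-axis audit grid (levels 0, 1/3, 2/3, 1), deduplicated on the simplex."""
    levels = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    seen: dict[tuple, np.ndarray] = {}
    for combo in itertools.product(range(4), repeat=4):
        x = levels[list(combo)]
        if x.sum() <= 0:
            continue
        r = x / x.sum()
        key = tuple(np.round(r, 12))
        seen.setdefault(key, r)
    return [seen[k] for k in sorted(seen)]


def _better(cost: float, ratios: tuple, best_cost: float, best_ratios: tuple | None) -> bool:
    if cost < best_cost - _TIE_TOL:
        return True
    return abs(cost - best_cost) <= _TIE_TOL and (best_ratios is None or ratios < best_ratios)


def invert_goal(
    ds: ExplorationDataset,
    goal: np.ndarray,
    fm_cfg: ForwardModelConfig | None = None,
    inv_cfg: InversionConfig | None = None,
    bounds: ObservationBounds | None = None,
    rng: np.random.Generator | None = None,
) -> OilFormulation:
    """Find the formulation whose predicted observation best matches a goal.

    Runs an evolution-strategy (CMA-ES) search over the unit box with
    candidate renormalization onto the simplex, optionally restarting from
    random points, then floors the result with a fixed coarse audit grid so
    the achieved cost never exceeds the grid's best. Ties are broken toward
    the lexicographically smallest ratio vector. Bit-reproducible for a
    fixed seed.
    """
    fm_cfg = fm_cfg or ForwardModelConfig()
    inv_cfg = inv_cfg or InversionConfig()
    bounds = bounds or ObservationBounds()
    if len(ds) < fm_cfg.min_points:
        raise ModelUnavailableError(
            f"need at least {fm_cfg.min_points} records for goal inversion, have {len(ds)}"
        )
    goal = np.asarray(goal, dtype=float)
    if rng is None:
        rng = np.random.default_rng(inv_cfg.seed)

    def cost(x: np.ndarray) -> float:
        return inversion_cost(ds, goal, fm_cfg, bounds, x)

    # audit grid doubles as the search seed (its argmin) and as a floor on
    # the achieved cost
    best_cost = float("inf")
    best_ratios: tuple | None = None
    audit_best: np.ndarray | None = None
    for gx in _audit_grid_points():
        c = cost(gx)
        r = tuple(normalize_formulation(gx).ratios)
        if _better(c, r, best_cost, best_ratios):
            best_cost, best_ratios = c, r
            audit_best = gx
    n_starts = inv_cfg.restarts + 1
    chunk = inv_cfg.max_evaluations // n_starts
    for start in range(n_starts):
        x0 = audit_best if start == 0 else rng.uniform(0.0, 1.0, size=4)
        bx, bf, _ = cmaes_minimize(
            cost, x0, inv_cfg.sigma0, rng, chunk, inv_cfg.population_size
        )
        r = tuple(normalize_formulation(np.clip(bx, 0, 1)).ratios) if bx.sum() > 1e-12 else None
        if r is not None and _better(bf, r, best_cost, best_ratios):
            best_cost, best_ratios = bf, r
    assert best_ratios is not None
    return OilFormulation(best_ratios)


def grid_invert_oracle(
    ds: ExplorationDataset,
    goal: np.ndarray,
    fm_cfg: ForwardModelConfig | None = None,
    bounds: ObservationBounds | None = None,
    resolution: int = 5,
) -> OilFormulation:
    """Exhaustive simplex-lattice minimizer of the inversion cost (test oracle).

    Enumerates every normalized combination of ``resolution`` evenly spaced
    levels per axis and returns the exact argmin, breaking ties toward the
    lexicographically first ratio vector.
    """
    fm_cfg = fm_cfg or ForwardModelConfig()
    bounds = bounds or ObservationBounds()
    if resolution < 2:
        raise ConfigError(f"resolution must be >= 2, got {resolution}")
    if len(ds) == 0:
        raise ModelUnavailableError("cannot invert on an empty dataset")
    levels = np.linspace(0.0, 1.0, resolution)
    goal = np.asarray(goal, dtype=float)
    seen: set[tuple] = set()
    candidates: list[tuple] = []
    for combo in itertools.product(range(resolution), repeat=4):
        x = levels[list(combo)]
        if x.sum() <= 0:
            continue
        r = tuple((x / x.sum()).tolist())
        key = tuple(np.round(r, 12))
        if key not in seen:
            seen.add(key)
            candidates.append(r)
    candidates.sort()
    best_cost = float("inf")
    best_ratios: tuple | None = None
    for r in candidates:
        c = inversion_cost(ds, goal, fm_cfg, bounds, np.asarray(r))
        if _better(c, r, best_cost, best_ratios):
            best_cost, best_ratios = c, r
    assert best_ratios is not None
    return OilFormulation(best_ratios)
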