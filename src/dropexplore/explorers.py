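"""Exploration strategies and the closed-loop experiment runner.

Two strategies share one runner:

* **random** — random parameter search: each experiment draws a formulation
  uniformly from the mixture simplex (flat Dirichlet).
* **ca** — the curiosity algorithm (random goal exploration): each experiment
  samples a temporary target uniformly over the normalized observation
  space, fits the forward model to everything observed so far, and inverts
  it to pick the formulation predicted to land closest to the target.

The CA starts with zero data: its first ``n_bootstrap`` experiments are
random picks that seed the forward model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_data import (
    BehaviorObservation,
    ConfigError,
    ExperimentRecord,
    ExplorationDataset,
    ObservationBounds,
    OilFormulation,
    child_rng,
    config_hash,
    normalize_formulation,
)
from .droplet_env_sim import EnvConfig, simulate_experiment
from .surrogate_models import (
    ForwardModelConfig,
    InversionConfig,
    ModelUnavailableError,
    invert_goal,
)

__all__ = [
    "ExplorerConfig",
    "sample_random_formulation",
    "sample_goal",
    "next_experiment",
    "run_exploration",
]

logger = logging.getLogger(__name__)

_ALGORITHMS = ("ca", "random")


@dataclass(frozen=True)
class ExplorerConfig:
    """Settings of one exploration run.

    ``n_bootstrap`` random experiments are performed before the forward model
    is first used (a local linear model in four inputs needs minimal
    support); the total number of experiments is exactly ``budget``.
    """

    algorithm: str = "ca"
    budget: int = 1000
    n_bootstrap: int = 10
    seed: int = 0
    forward: ForwardModelConfig = field(default_factory=ForwardModelConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    bounds: ObservationBounds = field(default_factory=ObservationBounds)
    experiment_duration_s: float = 90.0

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ConfigError(f"algorithm must be one of {_ALGORITHMS}, got {self.algorithm!r}")
        if self.budget < 0:
            raise ConfigError(f"budget must be >= 0, got {self.budget}")
        if not (0 <= self.n_bootstrap <= max(self.budget, 0)):
            raise ConfigError(
                f"n_bootstrap must be in [0, budget], got {self.n_bootstrap} with budget {self.budget}"
            )


def sample_random_formulation(rng: np.random.Generator) -> OilFormulation:
    """Draw a formulation uniformly from the 3-simplex (flat Dirichlet)."""
    return normalize_formulation(rng.dirichlet(np.ones(4)))


def sample_goal(rng: np.random.Generator, bounds: ObservationBounds | None = None) -> np.ndarray:
    """Draw a temporary target uniformly over the unit square of normalized observations."""
    return rng.uniform(0.0, 1.0, size=2)


def next_experiment(
    ds: ExplorationDataset,
    cfg: ExplorerConfig,
    rng_goal: np.random.Generator,
    rng_param: np.random.Generator,
    rng_opt: np.random.Generator | None = None,
) -> tuple[OilFormulation, np.ndarray | None]:
    """Choose the next formulation to test (and the goal that chose it, if any).

    Random search never emits a goal. The CA emits a goal once the bootstrap
    phase is over; if the forward model is unavailable the iteration falls
    back to a random pick (consuming the budget slot) with a logged warning.
    """
    if cfg.algorithm == "random" or len(ds) < cfg.n_bootstrap:
        return sample_random_formulation(rng_param), None
    goal = sample_goal(rng_goal, cfg.bounds)
    try:
        f = invert_goal(ds, goal, cfg.forward, cfg.inversion, cfg.bounds, rng=rng_opt)
    except ModelUnavailableError as exc:
        logger.warning("goal inversion unavailable (%s); falling back to a random pick", exc)
        return sample_random_formulation(rng_param), None
    return f, goal


def run_exploration(
    env_cfg: EnvConfig,
    explorer_cfg: ExplorerConfig,
    env: Callable[[OilFormulation], BehaviorObservation] | None = None,
) -> ExplorationDataset:
    """Run the strategy -> environment -> dataset loop for the full budget.

    All randomness (goal sampling, bootstrap picks, environment noise, the
    inversion optimizer) flows from ``explorer_cfg.seed`` through named child
    streams, so a run is bit-reproducible from its seed. ``env`` replaces the
    synthetic droplet environment with an arbitrary formulation->observation
    map (used for testing against known ground truth).
    """
    seed = explorer_cfg.seed
    rng_goal = child_rng(seed, "goal-sampling")
    rng_param = child_rng(seed, "bootstrap")
    rng_env = child_rng(seed, "environment-noise")
    rng_opt = child_rng(seed, "optimizer")
    ds = ExplorationDataset(
        metadata={
            "algorithm": explorer_cfg.algorithm,
            "budget": explorer_cfg.budget,
            "seed": seed,
            "bounds": {
                "speed": list(explorer_cfg.bounds.speed),
                "count": list(explorer_cfg.bounds.count),
            },
            "temperature_C": env_cfg.temperature_C,
            "config_hash": config_hash(
                {"env": config_hash(env_cfg), "explorer": config_hash(explorer_cfg)}
            ),
        }
    )
    for i in range(explorer_cfg.budget):
        f, goal = next_experiment(ds, explorer_cfg, rng_goal, rng_param, rng_opt)
        if env is not None:
            obs = env(f)
        else:
            obs = simulate_experiment(f, env_cfg, rng=rng_env)
        ds.append(
            ExperimentRecord(
                index=i,
                formulation=f,
                observation=obs,
                temperature_C=env_cfg.temperature_C,
                goal=None if goal is None else (float(goal[0]), float(goal[1])),
                seed=seed,
                duration_s=explorer_cfg.experiment_duration_s,
            )
        )
    return ds
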