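"""Synthetic stand-in for the physical droplet experiment.

Maps (oil formulation, temperature, seed) to a behavior observation and,
optionally, to full droplet trajectories. The simulator reproduces the
qualitative phenomenology of self-propelled oil-in-water droplets:

* a nonlinear formulation -> behavior landscape in which high activity is
  confined to a few localized regions of the mixture simplex (rare events);
* a sharp temperature regime shift — activity switches on steeply between
  roughly 22.6 and 27 degC, modeled as a logistic gate;
* six-phase motion programs over long (15-min) experiments: two speed peaks
  whose times decrease linearly with temperature and whose magnitudes grow
  with temperature.

It makes no claim of quantitative fidelity to any real droplet system; it is
a test harness with exact, analytically known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .core_data import (
    BehaviorObservation,
    ConfigError,
    OilFormulation,
    child_rng,
)

__all__ = [
    "EnvConfig",
    "TrajectorySet",
    "EnvelopeParams",
    "InvalidSamplingError",
    "simulate_experiment",
    "simulate_trajectories",
    "ground_truth",
    "GroundTruth",
    "envelope_params",
    "envelope_speed",
    "envelope_acceleration",
    "envelope_breakpoints",
    "PHASE_BOUNDARY_BASES_S",
    "PHASE_BOUNDARY_SLOPES_S_PER_C",
]


class InvalidSamplingError(ValueError):
    """Raised when a trajectory sampling request is inconsistent (dt >= duration)."""


#: Phase-boundary times (s) at the reference temperature 25 degC, for the five
#: transitions P1->P2 .. P5->P6.
PHASE_BOUNDARY_BASES_S = np.array([40.0, 110.0, 180.0, 330.0, 480.0])
#: Linear temperature dependence of each boundary (s per degC); negative:
#: every phase transition happens earlier in hotter experiments.
PHASE_BOUNDARY_SLOPES_S_PER_C = np.array([-2.0, -4.0, -6.0, -8.0, -10.0])

_T_REF_C = 25.0
#: Fraction of the first acceleration maximum that marks the end of initiation.
_RISE_FRACTION = 0.1


@dataclass(frozen=True)
class EnvConfig:
    """Configuration of the synthetic droplet environment.

    Parameters
    ----------
    temperature_C
        Ambient temperature, degC, within [15, 35].
    noise_speed_sd, noise_count_sd
        Gaussian observation noise on mean speed (mm/s) and droplet count.
    n_active_modes
        Number of localized high-activity regions in formulation space.
    mode_width
        Length scale (Euclidean distance on the simplex) of each region.
    regime_shift_midpoint_C, regime_shift_steepness
        Logistic temperature gate: activity ~ sigmoid(steepness * (T - midpoint)).
    arena_radius_mm
        Radius of the dish tracking area (a 32-mm petri dish -> 16 mm).
    n_droplets_initial
        Droplets placed per experiment (four, in a Y pattern).
    seed
        Seed for observation noise and trajectory headings.
    landscape_seed
        Seed fixing the activity landscape (mode centers/amplitudes). Kept
        separate from ``seed`` so the simulated chemistry is the same system
        across exploration runs, as a real chemical system would be.
    """

    temperature_C: float = 27.0
    noise_speed_sd: float = 0.3
    noise_count_sd: float = 0.5
    n_active_modes: int = 3
    mode_width: float = 0.10
    regime_shift_midpoint_C: float = 24.8
    regime_shift_steepness: float = 1.5
    arena_radius_mm: float = 16.0
    n_droplets_initial: int = 4
    seed: int = 0
    landscape_seed: int = 777

    def __post_init__(self) -> None:
        if not (15.0 <= self.temperature_C <= 35.0):
            raise ConfigError(f"temperature_C must be in [15, 35], got {self.temperature_C}")
        if self.noise_speed_sd < 0 or self.noise_count_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_active_modes < 1:
            raise ConfigError("n_active_modes must be >= 1")
        if self.mode_width <= 0:
            raise ConfigError("mode_width must be > 0")
        if self.regime_shift_steepness <= 0:
            raise ConfigError("regime_shift_steepness must be > 0")
        if self.arena_radius_mm <= 0:
            raise ConfigError("arena_radius_mm must be > 0")
        if self.n_droplets_initial < 1:
            raise ConfigError("n_droplets_initial must be >= 1")


@dataclass
class TrajectorySet:
    """Per-droplet positions over time at a uniform sampling interval.

    ``positions`` has shape (n_droplets, n_times, 2) in mm; ``times`` is the
    shared, strictly increasing time axis in seconds.
    """

    times: np.ndarray
    positions: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError(f"positions must be (n_droplets, n_times, 2), got {self.positions.shape}")
        if self.positions.shape[1] != self.times.shape[0]:
            raise ValueError("positions and times disagree on the number of samples")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_droplets(self) -> int:
        return self.positions.shape[0]

    def speeds(self) -> np.ndarray:
        """Instantaneous speeds (n_droplets, n_times - 1) in mm/s from displacements."""
        disp = np.diff(self.positions, axis=1)
        return np.linalg.norm(disp, axis=2) / self.dt

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: droplet_id, t_s, x_mm, y_mm."""
        n_d, n_t, _ = self.positions.shape
        return pd.DataFrame(
            {
                "droplet_id": np.repeat(np.arange(n_d), n_t),
                "t_s": np.tile(self.times, n_d),
                "x_mm": self.positions[:, :, 0].ravel(),
                "y_mm": self.positions[:, :, 1].ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrajectorySet":
        df = pd.read_csv(path)
        ids = np.sort(df["droplet_id"].unique())
        times = np.sort(df[df["droplet_id"] == ids[0]]["t_s"].to_numpy())
        pos = np.empty((len(ids), len(times), 2))
        for k, did in enumerate(ids):
            sub = df[df["droplet_id"] == did].sort_values("t_s")
            pos[k, :, 0] = sub["x_mm"].to_numpy()
            pos[k, :, 1] = sub["y_mm"].to_numpy()
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        return cls(times=times, positions=pos, dt=dt)


# ---------------------------------------------------------------------------
# Formulation -> behavior landscape (short exploration experiments)
# ---------------------------------------------------------------------------


def _landscape(cfg: EnvConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mode centers/amplitudes for the speed map and the (distinct) count map."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.landscape_seed & 0x7FFFFFFF, 11]))
    k = cfg.n_active_modes
    speed_centers = rng.dirichlet(np.ones(4), size=k)
    speed_amps = rng.uniform(6.0, 9.0, size=k)
    count_centers = rng.dirichlet(np.ones(4), size=k)
    count_amps = rng.uniform(-2.0, 6.0, size=k)
    return speed_centers, speed_amps, count_centers, count_amps


def _temperature_gate(cfg: EnvConfig, temperature_C: float | None = None) -> float:
    t = cfg.temperature_C if temperature_C is None else temperature_C
    z = cfg.regime_shift_steepness * (t - cfg.regime_shift_midpoint_C)
    return float(1.0 / (1.0 + np.exp(-z)))


def _mode_sum(x: np.ndarray, centers: np.ndarray, amps: np.ndarray, width: float) -> float:
    d2 = np.sum((centers - x) ** 2, axis=1)
    return float(np.sum(amps * np.exp(-d2 / (2.0 * width**2))))


def _noise_rng(f: OilFormulation, cfg: EnvConfig) -> np.random.Generator:
    """Noise stream that is a pure function of (formulation, seed, temperature)."""
    tag_f = zlib.crc32(np.asarray(f.ratios, dtype=float).tobytes())
    tag_t = int(round(cfg.temperature_C * 1000)) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, tag_f, tag_t])
    )


def simulate_experiment(
    f: OilFormulation, cfg: EnvConfig, rng: np.random.Generator | None = None
) -> BehaviorObservation:
    """Run one simulated 90-s droplet experiment.

    Mean speed is a sum of localized squared-exponential activity modes on
    the simplex, gated by a logistic function of temperature, plus Gaussian
    noise; mean droplet count is the initial droplet number modulated by a
    distinct mode map. Both are floored at zero.

    Deterministic for fixed (f, cfg): the default noise stream is derived
    from (formulation, cfg.seed, temperature). Pass ``rng`` to draw noise
    from an external stream instead (used by the exploration runner so each
    experiment in a run gets independent noise).
    """
    sc, sa, cc, ca = _landscape(cfg)
    gate = _temperature_gate(cfg)
    x = f.as_array()
    speed = _mode_sum(x, sc, sa, cfg.mode_width) * gate
    count = cfg.n_droplets_initial + _mode_sum(x, cc, ca, cfg.mode_width) * gate
    if cfg.noise_speed_sd > 0 or cfg.noise_count_sd > 0:
        if rng is None:
            rng = _noise_rng(f, cfg)
        speed += rng.normal(0.0, cfg.noise_speed_sd)
        count += rng.normal(0.0, cfg.noise_count_sd)
    return BehaviorObservation(max(speed, 0.0), max(count, 0.0))


# ---------------------------------------------------------------------------
# Six-phase speed envelope (long phase-diagram experiments)
#
# The envelope is constructed boundary-first: the five transition times are
# linear in temperature, and the acceleration profile is a continuous
# piecewise-linear curve (triangle lobes) whose characteristic points — the
# rise threshold, first maximum, zero crossings, minimum — fall exactly on
# those times. Integrating gives a piecewise-quadratic two-peak speed
# profile with peaks exactly at the 3rd and 5th boundaries.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvelopeParams:
    """Analytic description of one temperature's six-phase speed envelope.

    ``boundaries`` are the five transition times (s); ``peak_speeds`` are the
    speed maxima (mm/s) reached at boundaries 3 (irregular->deceleration) and
    5 (continuous->saturation); the envelope returns to zero ``sat_duration``
    seconds after the last boundary.
    """

    boundaries: tuple[float, float, float, float, float]
    peak_speeds: tuple[float, float]
    trough_speed: float
    sat_duration: float = 180.0

    def __post_init__(self) -> None:
        b = self.boundaries
        if not all(b[i] < b[i + 1] for i in range(4)):
            raise ConfigError(f"phase boundaries must be strictly increasing, got {b}")
        if min(self.peak_speeds) < 0 or self.trough_speed < 0:
            raise ConfigError("envelope speeds must be >= 0")

    @property
    def onset_time(self) -> float:
        """Time at which acceleration first departs from zero (before boundary 1).

        On the linear acceleration rise, boundary 1 is where acceleration
        reaches the rise fraction of its maximum, which pins the onset.
        """
        t1, t2 = self.boundaries[0], self.boundaries[1]
        return (t1 - _RISE_FRACTION * t2) / (1.0 - _RISE_FRACTION)


def envelope_params(cfg: EnvConfig, temperature_C: float | None = None) -> EnvelopeParams:
    """Envelope for the configured (or given) temperature.

    Boundary times decrease linearly with temperature; peak magnitudes grow
    linearly with temperature — hotter experiments peak earlier and faster.
    """
    t = cfg.temperature_C if temperature_C is None else float(temperature_C)
    bounds = PHASE_BOUNDARY_BASES_S + PHASE_BOUNDARY_SLOPES_S_PER_C * (t - _T_REF_C)
    v1 = 3.0 + 0.20 * (t - 20.0)
    v2 = 2.5 + 0.25 * (t - 20.0)
    trough = 0.3 * min(v1, v2)
    return EnvelopeParams(
        boundaries=tuple(float(b) for b in bounds),
        peak_speeds=(float(v1), float(v2)),
        trough_speed=float(trough),
    )


def envelope_breakpoints(p: EnvelopeParams) -> tuple[np.ndarray, np.ndarray]:
    """Knots (times, accelerations) of the piecewise-linear acceleration profile.

    Triangle lobes: rise to the first acceleration maximum M1 at boundary 2,
    fall through zero exactly at boundary 3 (first speed peak) to the
    deceleration minimum, re-cross zero at boundary 4, peak again, cross
    zero downward at boundary 5 (second speed peak), then a final negative
    lobe brings the speed back to zero (saturation). Lobe magnitudes follow
    from the peak/trough speeds by triangle areas.
    """
    t0 = p.onset_time
    t1, t2, t3, t4, t5 = p.boundaries
    v1, v2 = p.peak_speeds
    vtr = p.trough_speed
    t6 = t5 + p.sat_duration
    m1 = 2.0 * v1 / (t3 - t0)
    m2 = 2.0 * (v1 - vtr) / (t4 - t3)
    m3 = 2.0 * (v2 - vtr) / (t5 - t4)
    m4 = 2.0 * v2 / p.sat_duration
    tk = np.array(
        [t0, t2, t3, (t3 + t4) / 2.0, t4, (t4 + t5) / 2.0, t5, (t5 + t6) / 2.0, t6]
    )
    ak = np.array([0.0, m1, 0.0, -m2, 0.0, m3, 0.0, -m4, 0.0])
    return tk, ak


def envelope_acceleration(p: EnvelopeParams, t: np.ndarray | float) -> np.ndarray:
    """Acceleration envelope a(t) = dv/dt in mm/s^2 (vectorized)."""
    t = np.asarray(t, dtype=float)
    tk, ak = envelope_breakpoints(p)
    return np.interp(t, tk, ak, left=0.0, right=0.0)


def envelope_speed(p: EnvelopeParams, t: np.ndarray | float) -> np.ndarray:
    """Speed envelope v(t) in mm/s: the exact integral of the acceleration profile."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tk, ak = envelope_breakpoints(p)
    seg_dt = np.diff(tk)
    vk = np.concatenate([[0.0], np.cumsum(0.5 * (ak[:-1] + ak[1:]) * seg_dt)])
    idx = np.clip(np.searchsorted(tk, t, side="right") - 1, 0, len(tk) - 2)
    s = np.clip(t - tk[idx], 0.0, seg_dt[idx])
    slope = (ak[idx + 1] - ak[idx]) / seg_dt[idx]
    v = vk[idx] + ak[idx] * s + 0.5 * slope * s**2
    v[t < tk[0]] = 0.0
    v[t >= tk[-1]] = float(vk[-1])
    return np.maximum(v, 0.0)


#: Per-phase heading diffusion (rad / sqrt(s)): large during fluctuation and
#: irregular motion, small during the persistent continuous phase.
_PHASE_ANGULAR_SD = np.array([1.0, 1.5, 3.0, 0.8, 0.15, 0.5])


def _phase_index(t: float, boundaries: tuple[float, ...]) -> int:
    return int(np.searchsorted(np.asarray(boundaries), t, side="right"))


def _y_pattern(n: int, spacing_mm: float = 4.0) -> np.ndarray:
    """Initial droplet positions: one at the dish center, the rest on spokes."""
    pos = np.zeros((n, 2))
    angles = np.pi / 2 + 2 * np.pi * np.arange(max(n - 1, 1)) / max(n - 1, 1)
    for i in range(1, n):
        pos[i] = spacing_mm * np.array([np.cos(angles[i - 1]), np.sin(angles[i - 1])])
    return pos


def simulate_trajectories(
    f: OilFormulation,
    cfg: EnvConfig,
    duration_s: float,
    dt: float = 0.05,
    angular_noise_scale: float = 1.0,
    params: EnvelopeParams | None = None,
) -> TrajectorySet:
    """Generate per-droplet trajectories following the six-phase envelope.

    Every droplet moves at the (shared, deterministic) envelope speed with a
    heading performing phase-dependent diffusion: near-random-walk turning in
    the irregular phase, persistent heading with little angular noise in the
    continuous phase. Positions are reflected at the arena boundary. With
    ``angular_noise_scale=0`` headings stay constant between reflections and
    the path length equals the envelope integral exactly (up to quadrature).

    ``params`` overrides the temperature-derived envelope (used by fixtures,
    e.g. a zero-amplitude envelope producing stationary droplets).
    """
    if duration_s <= 0 or dt <= 0:
        raise InvalidSamplingError(f"duration_s and dt must be > 0, got {duration_s}, {dt}")
    if dt >= duration_s:
        raise InvalidSamplingError(f"dt ({dt}) must be smaller than duration_s ({duration_s})")
    p = envelope_params(cfg) if params is None else params
    n_steps = int(round(duration_s / dt))
    times = np.arange(n_steps + 1) * dt
    n = cfg.n_droplets_initial
    rng = child_rng(cfg.seed, "trajectories")
    headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
    positions = np.empty((n, n_steps + 1, 2))
    positions[:, 0, :] = _y_pattern(n)
    radius = cfg.arena_radius_mm
    # midpoint speed so the discrete path length is a midpoint-rule quadrature
    v_mid = envelope_speed(p, times[:-1] + dt / 2.0)

    for k in range(n_steps):
        t_mid = times[k] + dt / 2.0
        phase = _phase_index(t_mid, p.boundaries)
        sd = _PHASE_ANGULAR_SD[phase] * angular_noise_scale * np.sqrt(dt)
        if sd > 0:
            headings = headings + rng.normal(0.0, sd, size=n)
        step = float(v_mid[k]) * dt
        dirs = np.column_stack([np.cos(headings), np.sin(headings)])
        new = positions[:, k, :] + step * dirs
        outside = np.linalg.norm(new, axis=1) > radius
        for i in np.flatnonzero(outside):
            pos = positions[i, k].copy()
            d = dirs[i].copy()
            remaining = step
            # advance, splitting the step at arena-boundary reflections
            for _ in range(8):
                cand = pos + remaining * d
                if np.linalg.norm(cand) <= radius or remaining == 0.0:
                    pos = cand
                    break
                # solve |pos + s*d| = radius for the crossing fraction s
                b = float(np.dot(pos, d))
                c = float(np.dot(pos, pos)) - radius**2
                s = -b + np.sqrt(max(b * b - c, 0.0))
                s = min(max(s, 0.0), remaining)
                pos = pos + s * d
                normal = pos / np.linalg.norm(pos)
                d = d - 2.0 * np.dot(d, normal) * normal
                remaining -= s
            headings[i] = float(np.arctan2(d[1], d[0]))
            new[i] = pos
        positions[:, k + 1, :] = new
    return TrajectorySet(times=times, positions=positions, dt=dt)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free oracle for one (formulation, config) pair."""

    observation: BehaviorObservation
    boundary_times_s: tuple[float, float, float, float, float]
    peak_speeds_mm_s: tuple[float, float]
    peak_times_s: tuple[float, float]
    boundary_slopes_s_per_C: tuple[float, float, float, float, float]


def ground_truth(f: OilFormulation, cfg: EnvConfig) -> GroundTruth:
    """Noise-free observation and exact phase-boundary times for (f, cfg)."""
    noiseless = replace(cfg, noise_speed_sd=0.0, noise_count_sd=0.0)
    obs = simulate_experiment(f, noiseless)
    p = envelope_params(cfg)
    return GroundTruth(
        observation=obs,
        boundary_times_s=p.boundaries,
        peak_speeds_mm_s=p.peak_speeds,
        peak_times_s=(p.boundaries[2], p.boundaries[4]),
        boundary_slopes_s_per_C=tuple(float(s) for s in PHASE_BOUNDARY_SLOPES_S_PER_C),
    )
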