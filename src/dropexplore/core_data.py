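"""Domain types, experiment-log persistence, configuration, and seeded randomness.

The exploration problem lives in two small spaces:

* the **parameter space** — the 3-simplex of mixing ratios of four oils
  (octanoic acid, diethyl phthalate, 1-octanol, 1-pentanol) that make up a
  droplet formulation, and
* the **observation space** — a 2-D behavior summary of one experiment,
  (mean droplet speed in mm/s, mean droplet count in the dish).

Everything downstream (the forward model, goal sampling, coverage analytics)
works on these types plus an append-only :class:`ExplorationDataset` log.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "OIL_COMPONENTS",
    "OilFormulation",
    "BehaviorObservation",
    "ObservationBounds",
    "ExperimentRecord",
    "ExplorationDataset",
    "InvalidFormulationError",
    "DatasetParseError",
    "ConfigError",
    "normalize_formulation",
    "observation_to_goalspace",
    "save_dataset",
    "load_dataset",
    "child_rng",
    "load_yaml_config",
    "config_hash",
]

#: Fixed component order of the oil mixture.
OIL_COMPONENTS = ("octanoic_acid", "dep", "octanol", "pentanol")

_RATIO_SUM_TOL = 1e-9

_CSV_COLUMNS = [
    "index",
    "r_octanoic",
    "r_dep",
    "r_octanol",
    "r_pentanol",
    "mean_speed_mm_s",
    "mean_droplet_count",
    "temperature_C",
    "goal_x",
    "goal_y",
    "seed",
    "duration_s",
]


class InvalidFormulationError(ValueError):
    """Raised for formulations that are not valid points on the mixture simplex."""


class DatasetParseError(ValueError):
    """Raised when an experiment-log file is malformed; names the offending line/field."""


class ConfigError(ValueError):
    """Raised for invalid module configuration values."""


@dataclass(frozen=True)
class OilFormulation:
    """A point on the 4-component mixture simplex.

    Parameters
    ----------
    ratios
        Fractions of (octanoic acid, DEP, 1-octanol, 1-pentanol), each >= 0,
        summing to 1 within 1e-9.
    """

    ratios: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 4:
            raise InvalidFormulationError(f"expected 4 ratios, got {len(r)}")
        if any(not np.isfinite(x) for x in r):
            raise InvalidFormulationError(f"non-finite ratio in {r}")
        if any(x < 0 for x in r):
            raise InvalidFormulationError(f"negative ratio in {r}")
        if abs(sum(r) - 1.0) > _RATIO_SUM_TOL:
            raise InvalidFormulationError(f"ratios sum to {sum(r)!r}, expected 1")
        object.__setattr__(self, "ratios", r)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.ratios, dtype=float)


@dataclass(frozen=True)
class BehaviorObservation:
    """One experiment's behavior summary: mean speed (mm/s) and mean droplet count."""

    mean_speed: float
    mean_droplet_count: float

    def __post_init__(self) -> None:
        for name in ("mean_speed", "mean_droplet_count"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_speed, self.mean_droplet_count], dtype=float)


@dataclass(frozen=True)
class ObservationBounds:
    """Per-dimension (low, high) bounds mapping observations onto the unit square.

    Defaults cover the behavior ranges seen in practice for this droplet
    system: speeds up to ~10 mm/s and up to ~10 droplets in the dish.
    """

    speed: tuple[float, float] = (0.0, 10.0)
    count: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("speed", "count"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ConfigError(f"bounds for {name} must satisfy low < high, got {(lo, hi)}")

    def lows(self) -> np.ndarray:
        return np.array([self.speed[0], self.count[0]], dtype=float)

    def highs(self) -> np.ndarray:
        return np.array([self.speed[1], self.count[1]], dtype=float)


@dataclass(frozen=True)
class ExperimentRecord:
    """One completed experiment: what was mixed, what was observed, and why.

    ``goal`` is present iff the formulation was chosen by the curiosity
    algorithm to reach a self-generated target (absent for random picks and
    bootstrap experiments).
    """

    index: int
    formulation: OilFormulation
    observation: BehaviorObservation
    temperature_C: float | None = None
    goal: tuple[float, float] | None = None
    seed: int = 0
    duration_s: float = 90.0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"record index must be >= 0, got {self.index}")
        if self.goal is not None:
            object.__setattr__(self, "goal", (float(self.goal[0]), float(self.goal[1])))


@dataclass
class ExplorationDataset:
    """Append-only log of experiments: the exploration algorithm's only memory."""

    records: list[ExperimentRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    # array views are memoized (keyed on length) — the forward model queries
    # them thousands of times per goal inversion
    _cache: tuple[int, np.ndarray, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def append(self, record: ExperimentRecord) -> None:
        if record.index != len(self.records):
            raise ValueError(
                f"records must be appended with contiguous indices: "
                f"expected {len(self.records)}, got {record.index}"
            )
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExperimentRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ExperimentRecord:
        return self.records[i]

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None or self._cache[0] != len(self.records):
            X = np.array([r.formulation.ratios for r in self.records], dtype=float).reshape(-1, 4)
            Y = np.array(
                [
                    (r.observation.mean_speed, r.observation.mean_droplet_count)
                    for r in self.records
                ],
                dtype=float,
            ).reshape(-1, 2)
            object.__setattr__(self, "_cache", (len(self.records), X, Y))
        return self._cache[1], self._cache[2]

    def formulations(self) -> np.ndarray:
        """(n, 4) array of oil ratios."""
        return self._arrays()[0]

    def observations(self) -> np.ndarray:
        """(n, 2) array of (mean_speed, mean_droplet_count)."""
        return self._arrays()[1]


def normalize_formulation(raw: Sequence[float]) -> OilFormulation:
    """Normalize non-negative component weights to an :class:`OilFormulation`.

    Scale-invariant: any positive multiple of ``raw`` yields the same
    formulation. All-zero or negative input is rejected.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (4,):
        raise InvalidFormulationError(f"expected 4 weights, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidFormulationError(f"non-finite weight in {arr.tolist()}")
    if np.any(arr < 0):
        raise InvalidFormulationError(f"negative weight in {arr.tolist()}")
    total = float(arr.sum())
    if total <= 0:
        raise InvalidFormulationError("weights sum to zero; cannot normalize")
    ratios = arr / total
    # Guard against accumulated rounding taking the sum outside tolerance.
    ratios = ratios / ratios.sum()
    return OilFormulation(tuple(float(x) for x in ratios))


def observation_to_goalspace(
    obs: BehaviorObservation, bounds: ObservationBounds
) -> np.ndarray:
    """Map an observation to the unit square via per-dimension affine rescaling.

    Values outside the bounds are clipped to [0, 1]; the map is monotone in
    each dimension.
    """
    lo, hi = bounds.lows(), bounds.highs()
    z = (obs.as_array() - lo) / (hi - lo)
    return np.clip(z, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Persistence: one CSV row per experiment + JSON run-metadata sidecar.
# Floats are written with repr() so the text round-trips bit-exactly.
# ---------------------------------------------------------------------------


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_dataset(ds: ExplorationDataset, path: str | Path) -> Path:
    """Write a dataset as a CSV experiment log plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in ds.records:
            r = rec.formulation.ratios
            goal = rec.goal
            writer.writerow(
                [
                    str(rec.index),
                    _fmt(r[0]),
                    _fmt(r[1]),
                    _fmt(r[2]),
                    _fmt(r[3]),
                    _fmt(rec.observation.mean_speed),
                    _fmt(rec.observation.mean_droplet_count),
                    _fmt(rec.temperature_C),
                    _fmt(goal[0]) if goal is not None else "",
                    _fmt(goal[1]) if goal is not None else "",
                    str(rec.seed),
                    _fmt(rec.duration_s),
                ]
            )
    with open(_sidecar_path(path), "w") as fh:
        json.dump(ds.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _parse_float(raw: str, line: int, field_name: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise DatasetParseError(f"line {line}: field {field_name!r}: not a number: {raw!r}") from exc


def load_dataset(path: str | Path) -> ExplorationDataset:
    """Load a CSV experiment log written by :func:`save_dataset`.

    Field-level invariants (non-negative ratios summing to 1, contiguous
    indices) are re-validated; violations raise :class:`DatasetParseError`
    naming the line and field.
    """
    path = Path(path)
    records: list[ExperimentRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetParseError("line 1: empty file, expected header")
        if header != _CSV_COLUMNS:
            raise DatasetParseError(f"line 1: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_CSV_COLUMNS):
                raise DatasetParseError(
                    f"line {lineno}: expected {len(_CSV_COLUMNS)} fields, got {len(row)}"
                )
            vals = dict(zip(_CSV_COLUMNS, row))
            index = int(_parse_float(vals["index"], lineno, "index"))
            ratios = tuple(
                _parse_float(vals[c], lineno, c)
                for c in ("r_octanoic", "r_dep", "r_octanol", "r_pentanol")
            )
            try:
                formulation = OilFormulation(ratios)
            except InvalidFormulationError as exc:
                raise DatasetParseError(f"line {lineno}: invalid formulation: {exc}") from exc
            try:
                observation = BehaviorObservation(
                    _parse_float(vals["mean_speed_mm_s"], lineno, "mean_speed_mm_s"),
                    _parse_float(vals["mean_droplet_count"], lineno, "mean_droplet_count"),
                )
            except ValueError as exc:
                raise DatasetParseError(f"line {lineno}: invalid observation: {exc}") from exc
            temperature = (
                None
                if vals["temperature_C"] == ""
                else _parse_float(vals["temperature_C"], lineno, "temperature_C")
            )
            if (vals["goal_x"] == "") != (vals["goal_y"] == ""):
                raise DatasetParseError(f"line {lineno}: goal_x/goal_y must both be set or empty")
            goal = (
                None
                if vals["goal_x"] == ""
                else (
                    _parse_float(vals["goal_x"], lineno, "goal_x"),
                    _parse_float(vals["goal_y"], lineno, "goal_y"),
                )
            )
            if index != len(records):
                raise DatasetParseError(
                    f"line {lineno}: field 'index': expected {len(records)}, got {index}"
                )
            records.append(
                ExperimentRecord(
                    index=index,
                    formulation=formulation,
                    observation=observation,
                    temperature_C=temperature,
                    goal=goal,
                    seed=int(_parse_float(vals["seed"], lineno, "seed")),
                    duration_s=_parse_float(vals["duration_s"], lineno, "duration_s"),
                )
            )
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    return ExplorationDataset(records=records, metadata=metadata)


# ---------------------------------------------------------------------------
# Seeded randomness: one integer run seed fans out into named child streams
# so every consumer (goal sampling, bootstrap, environment noise, optimizer)
# draws from an independent, reproducible generator.
# ---------------------------------------------------------------------------


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Derive a named, independent random stream from a single run seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def load_yaml_config(path: str | Path) -> dict:
    """Read the shared YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def config_hash(obj) -> str:
    """Short stable hash of a configuration object, for run metadata."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
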