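"""Exploration analytics, temperature inference, and the time-temperature phase diagram.

Three concerns live here:

* quantifying an exploration run — what fraction of the discretized behavior
  space it occupied, how many "active" experiments (mean speed > 3 mm/s) it
  produced, and whether two groups of runs differ (Welch's unequal-variance
  t test);
* reading temperature back out of behavior — distance-weighted k-NN
  regression from (speed, count) observations to degC, the "droplets as
  temperature sensors" analysis;
* the phase pipeline — 2-s sliding-window speed/acceleration profiles,
  characteristic-point transition detection, per-degC binning, and linear
  fits of transition time against temperature, yielding a phase diagram
  that assigns one of six motion phases (initiation, fluctuation,
  irregular, deceleration, continuous, saturation) to any (time,
  temperature) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsRegressor

from .core_data import (
    BehaviorObservation,
    ExplorationDataset,
    ObservationBounds,
    observation_to_goalspace,
)
from .droplet_env_sim import TrajectorySet

__all__ = [
    "PHASE_LABELS",
    "CoverageResult",
    "WelchResult",
    "ProfileResult",
    "PhaseTransitions",
    "BoundaryFit",
    "PhaseDiagram",
    "occupied_cells",
    "coverage",
    "count_active",
    "welch_t_test",
    "infer_temperature",
    "speed_acceleration_profiles",
    "detect_phase_transitions",
    "build_phase_diagram",
    "classify_phase",
    "fold_change",
    "plot_coverage_curves",
    "plot_phase_diagram",
]

#: The six motion phases, in temporal order P1..P6.
PHASE_LABELS = (
    "initiation",
    "fluctuation",
    "irregular",
    "deceleration",
    "continuous",
    "saturation",
)

#: Names of the five transitions between consecutive phases.
TRANSITION_NAMES = tuple(
    f"{PHASE_LABELS[i]}->{PHASE_LABELS[i + 1]}" for i in range(5)
)


# ---------------------------------------------------------------------------
# Coverage and group comparison
# ---------------------------------------------------------------------------


def occupied_cells(
    ds: ExplorationDataset, bounds: ObservationBounds, grid: int = 20
) -> set[tuple[int, int]]:
    """Cells of the grid x grid discretization of the unit square hit by a run."""
    cells: set[tuple[int, int]] = set()
    for rec in ds:
        z = observation_to_goalspace(rec.observation, bounds)
        i = min(int(z[0] * grid), grid - 1)
        j = min(int(z[1] * grid), grid - 1)
        cells.add((i, j))
    return cells


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of one run: final fraction plus the per-prefix curve."""

    fraction: float
    prefix_curve: np.ndarray
    n_occupied: int
    n_reference: int


def coverage(
    ds: ExplorationDataset,
    bounds: ObservationBounds | None = None,
    grid: int = 20,
    reference: Sequence[ExplorationDataset] | None = None,
) -> CoverageResult:
    """Fraction of the observable behavior space a run occupied.

    Observations are mapped to the unit square and binned on a grid x grid
    lattice. The denominator is the pooled occupied-cell union of all runs
    under comparison (``reference``; the run itself is always included) —
    "total observable space" is defined by what any compared run reached,
    since the true reachable set is unknown. Without a reference the
    denominator is the full grid. The per-prefix curve is non-decreasing.
    """
    bounds = bounds or ObservationBounds()
    if grid < 2:
        raise ValueError(f"grid must be >= 2, got {grid}")
    own = occupied_cells(ds, bounds, grid)
    if reference is not None:
        pooled = set(own)
        for other in reference:
            pooled |= occupied_cells(other, bounds, grid)
        denom = len(pooled)
    else:
        denom = grid * grid
    seen: set[tuple[int, int]] = set()
    curve = np.zeros(len(ds))
    for k, rec in enumerate(ds):
        z = observation_to_goalspace(rec.observation, bounds)
        i = min(int(z[0] * grid), grid - 1)
        j = min(int(z[1] * grid), grid - 1)
        seen.add((i, j))
        curve[k] = len(seen)
    if denom > 0:
        curve = curve / denom
    frac = float(len(own) / denom) if denom > 0 else 0.0
    return CoverageResult(frac, curve, len(own), denom)


def count_active(ds: ExplorationDataset, speed_threshold: float = 3.0) -> int:
    """Number of experiments whose mean speed strictly exceeds the threshold (mm/s)."""
    return int(sum(1 for rec in ds if rec.observation.mean_speed > speed_threshold))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch unequal-variance t test with Welch-Satterthwaite df.

    If both groups have zero variance and equal means the test is degenerate
    and (t=0, p=1) is returned by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(float("inf") if a.mean() > b.mean() else float("-inf"),
                           float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def fold_change(value: float, reference: float) -> float:
    """Ratio value / reference, the fold-improvement reported between two group means."""
    if reference == 0:
        raise ZeroDivisionError("reference mean is zero")
    return float(value) / float(reference)


# ---------------------------------------------------------------------------
# Droplets as temperature sensors
# ---------------------------------------------------------------------------


def infer_temperature(
    train: Sequence[tuple[BehaviorObservation, float]],
    query: BehaviorObservation,
    bounds: ObservationBounds | None = None,
    k: int = 5,
) -> float:
    """Infer temperature (degC) from a behavior observation.

    Distance-weighted k-nearest-neighbor regression in normalized
    observation space, k = min(k, n). A query coinciding with a training
    observation returns that pair's temperature exactly.
    """
    if len(train) == 0:
        raise ValueError("need at least one training pair")
    bounds = bounds or ObservationBounds()
    X = np.array([observation_to_goalspace(obs, bounds) for obs, _ in train])
    y = np.array([t for _, t in train], dtype=float)
    model = KNeighborsRegressor(n_neighbors=min(k, len(train)), weights="distance")
    model.fit(X, y)
    zq = observation_to_goalspace(query, bounds).reshape(1, -1)
    return float(model.predict(zq)[0])


# ---------------------------------------------------------------------------
# Speed/acceleration profiles and phase-transition detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileResult:
    """Droplet-averaged smoothed speed and its time derivative on a uniform grid."""

    times_s: np.ndarray
    speed_mm_s: np.ndarray
    acceleration_mm_s2: np.ndarray
    dt: float


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    return np.convolve(x, kernel, mode="same") / np.convolve(np.ones_like(x), kernel, mode="same")


def speed_acceleration_profiles(
    trajs: TrajectorySet | Sequence[TrajectorySet],
    window_s: float = 2.0,
    median_prefilter_s: float = 1.0,
) -> ProfileResult:
    """Sliding-window mean speed and acceleration profiles of one or more experiments.

    Speeds are computed per droplet from displacements, median-filtered over
    ``median_prefilter_s`` to suppress single-sample tracking glitches (e.g.
    a droplet folding back off the dish wall within one frame interval),
    averaged across droplets (and across experiments when a sequence is
    given — all on the same time grid), then smoothed with a centered
    ``window_s`` window truncated at the ends; acceleration is the centered
    first difference of the smoothed speed divided by dt.
    """
    from scipy.ndimage import median_filter

    if isinstance(trajs, TrajectorySet):
        trajs = [trajs]
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory set")
    dt = trajs[0].dt
    n_t = trajs[0].times.shape[0]
    for other in trajs[1:]:
        if other.times.shape[0] != n_t or abs(other.dt - dt) > 1e-12:
            raise ValueError("all experiments must share one time grid for profile averaging")
    if n_t < 4:
        raise ValueError("need at least 3 speed samples (4 time points) for profiles")
    med = max(3, int(round(median_prefilter_s / dt)) | 1)
    per_run = []
    for ts in trajs:
        speeds = ts.speeds()
        if speeds.shape[1] >= med:
            speeds = median_filter(speeds, size=(1, med), mode="nearest")
        per_run.append(speeds.mean(axis=0))
    mean_speed = np.mean(per_run, axis=0)
    # speed sample k covers [t_k, t_{k+1}]; attribute it to the midpoint
    times = trajs[0].times[:-1] + dt / 2.0
    window = max(1, int(round(window_s / dt)) | 1)
    smooth = _smooth(mean_speed, window)
    accel = np.gradient(smooth, dt)
    return ProfileResult(times, smooth, accel, dt)


@dataclass(frozen=True)
class PhaseTransitions:
    """The five transition times (s); ``None`` marks a transition not present."""

    times_s: tuple[float | None, float | None, float | None, float | None, float | None]

    def as_array(self) -> np.ndarray:
        return np.array([np.nan if t is None else t for t in self.times_s])


def _broken_stick_crossing(
    t: np.ndarray, a: np.ndarray, i: int, fit_hw: int, search_hw: int
) -> float:
    """Refined zero-crossing time by a two-segment linear ("broken stick") fit.

    The acceleration around each transition is locally two line segments
    meeting at zero; fitting that model over a wide window and scanning the
    break position averages the noise without the bias a plain local line
    or parabola fit picks up from the slope asymmetry.
    """
    lo, hi = max(i - fit_hw, 0), min(i + fit_hw + 1, a.size)
    tt, aa = t[lo:hi], a[lo:hi]
    best_ss, best_tau = np.inf, float(t[i])
    for j in range(max(i - search_hw, lo + 1), min(i + search_hw + 1, hi - 1)):
        tau = float(t[j])
        X = np.column_stack([np.minimum(tt - tau, 0.0), np.maximum(tt - tau, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(X, aa, rcond=None)
        resid = aa - X @ coef
        ss = float(resid @ resid)
        if ss < best_ss:
            best_ss, best_tau = ss, tau
    return best_tau


def _broken_stick_peak(
    t: np.ndarray, a: np.ndarray, i: int, fit_hw: int, search_hw: int
) -> tuple[float, float]:
    """Refined peak (corner) time and value by a two-segment linear fit with intercept."""
    lo, hi = max(i - fit_hw, 0), min(i + fit_hw + 1, a.size)
    tt, aa = t[lo:hi], a[lo:hi]
    best = (np.inf, float(t[i]), float(a[i]))
    for j in range(max(i - search_hw, lo + 1), min(i + search_hw + 1, hi - 1)):
        tau = float(t[j])
        X = np.column_stack(
            [np.ones_like(tt), np.minimum(tt - tau, 0.0), np.maximum(tt - tau, 0.0)]
        )
        coef, _, _, _ = np.linalg.lstsq(X, aa, rcond=None)
        resid = aa - X @ coef
        ss = float(resid @ resid)
        if ss < best[0]:
            best = (ss, tau, float(coef[0]))
    return best[1], best[2]


def detect_phase_transitions(
    profile: ProfileResult,
    rise_fraction: float = 0.1,
    min_prominence_fraction: float = 0.15,
    accel_smooth_s: float = 6.0,
    persist_s: float = 20.0,
    eps_fraction: float = 0.08,
) -> PhaseTransitions:
    """Locate the five phase transitions from characteristic acceleration points.

    P1->P2: acceleration first exceeds ``rise_fraction`` of its first
    maximum. P2->P3: the first acceleration maximum. P3->P4: the first speed
    maximum (downward zero crossing of acceleration). P4->P5: the upward
    re-crossing after the acceleration minimum. P5->P6: the second speed
    maximum (second downward crossing). Transitions not supported by the
    profile (monotone or single-peak speed) are reported absent, never
    fabricated.

    Robustness to tracking noise: the acceleration is re-smoothed over
    ``accel_smooth_s``, a zero crossing counts only if the new sign holds
    (beyond a dead band of ``eps_fraction`` of the acceleration scale) for
    most of the following ``persist_s``, and the reported time is the
    linearly interpolated sign change itself, so the dead band introduces
    no bias.
    """
    t = profile.times_s
    a = _smooth(
        profile.acceleration_mm_s2, max(1, int(round(accel_smooth_s / profile.dt)) | 1)
    )
    none5 = PhaseTransitions((None, None, None, None, None))
    scale = float(np.max(np.abs(a))) if a.size else 0.0
    if scale <= 0 or float(np.max(a)) <= 0:
        return none5
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(a, prominence=min_prominence_fraction * scale)
    if peaks.size == 0:
        return none5
    i_amax = int(peaks[0])
    peak_fit_hw = int(round(30.0 / profile.dt))
    peak_search_hw = int(round(12.0 / profile.dt))
    t2, a_peak = _broken_stick_peak(t, a, i_amax, peak_fit_hw, peak_search_hw)
    thresh = rise_fraction * max(a_peak, a[i_amax])
    above = np.flatnonzero(a[: i_amax + 1] >= thresh)
    t1 = float(t[above[0]]) if above.size else None

    eps = eps_fraction * scale
    persist = max(2, int(round(persist_s / profile.dt)))

    def next_crossing(start: int, downward: bool) -> int | None:
        """Index just past a persistent sign change; walked back to the change itself."""
        sign = -1.0 if downward else 1.0
        for i in range(start + 1, a.size):
            if sign * a[i] > eps and sign * a[i - 1] <= eps:
                seg = sign * a[i : i + persist]
                if seg.size and np.mean(seg > 0) > 0.7:
                    j = i
                    while j > start + 1 and sign * a[j - 1] > 0:
                        j -= 1
                    return j
        return None

    fit_hw = int(round(35.0 / profile.dt))
    search_hw = int(round(12.0 / profile.dt))

    def crossing_time(i: int) -> float:
        return _broken_stick_crossing(t, a, i, fit_hw, search_hw)

    i3 = next_crossing(i_amax, downward=True)
    if i3 is None:
        return PhaseTransitions((t1, t2, None, None, None))
    t3 = crossing_time(i3)
    i4 = next_crossing(i3, downward=False)
    if i4 is None:
        return PhaseTransitions((t1, t2, t3, None, None))
    t4 = crossing_time(i4)
    i5 = next_crossing(i4, downward=True)
    if i5 is None:
        return PhaseTransitions((t1, t2, t3, t4, None))
    t5 = crossing_time(i5)
    return PhaseTransitions((t1, t2, t3, t4, t5))


# ---------------------------------------------------------------------------
# Phase diagram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryFit:
    """One transition boundary: time(T) = slope * T + intercept over the valid range."""

    name: str
    slope_s_per_C: float
    intercept_s: float
    temperature_range_C: tuple[float, float]
    residual_rms_s: float
    n_bins: int

    def time_at(self, temperature_C: float) -> float:
        return self.slope_s_per_C * temperature_C + self.intercept_s


@dataclass(frozen=True)
class PhaseDiagram:
    """Five linear boundaries separating the six motion phases in (time, temperature).

    ``boundaries`` maps transition index (0..4) to a :class:`BoundaryFit`;
    missing indices mark transitions that could not be fitted.
    """

    boundaries: dict[int, BoundaryFit]
    temperature_range_C: tuple[float, float]

    def __post_init__(self) -> None:
        for temp in self.temperature_range_C:
            times = [
                self.boundaries[i].time_at(temp) for i in sorted(self.boundaries)
            ]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(
                    f"boundary times must be strictly increasing P1->P6 at {temp} degC, got {times}"
                )

    def is_complete(self) -> bool:
        return len(self.boundaries) == 5

    def to_dict(self) -> dict:
        return {
            "temperature_range_C": list(self.temperature_range_C),
            "boundaries": {
                str(i): {
                    "name": b.name,
                    "slope_s_per_C": b.slope_s_per_C,
                    "intercept_s": b.intercept_s,
                    "temperature_range_C": list(b.temperature_range_C),
                    "residual_rms_s": b.residual_rms_s,
                    "n_bins": b.n_bins,
                }
                for i, b in self.boundaries.items()
            },
        }


def build_phase_diagram(
    experiments: Sequence[tuple[float, TrajectorySet]],
    bin_width_C: float = 1.0,
    window_s: float = 2.0,
) -> PhaseDiagram:
    """Bin experiments by temperature, detect per-bin transitions, fit linear boundaries.

    Experiments are grouped into ``bin_width_C`` intervals; profiles are
    averaged within each bin *before* transition detection (per-bin averaged
    curves are far less noisy than single experiments). Each transition time
    observed in at least two bins is fitted by least squares against the bin
    center temperature; transitions seen in fewer bins are absent from the
    diagram.
    """
    if len(experiments) == 0:
        raise ValueError("need at least one experiment")
    bins: dict[int, list[TrajectorySet]] = {}
    for temp, ts in experiments:
        bins.setdefault(int(np.floor(temp / bin_width_C)), []).append(ts)
    if len(bins) < 2:
        raise ValueError("need experiments in at least 2 temperature bins")
    centers: list[float] = []
    all_times: list[PhaseTransitions] = []
    for idx in sorted(bins):
        centers.append((idx + 0.5) * bin_width_C)
        profile = speed_acceleration_profiles(bins[idx], window_s=window_s)
        all_times.append(detect_phase_transitions(profile))
    centers_arr = np.asarray(centers)
    boundaries: dict[int, BoundaryFit] = {}
    for j in range(5):
        ys = np.array([pt.times_s[j] if pt.times_s[j] is not None else np.nan for pt in all_times])
        ok = ~np.isnan(ys)
        if ok.sum() < 2:
            continue
        slope, intercept = np.polyfit(centers_arr[ok], ys[ok], 1)
        resid = ys[ok] - (slope * centers_arr[ok] + intercept)
        boundaries[j] = BoundaryFit(
            name=TRANSITION_NAMES[j],
            slope_s_per_C=float(slope),
            intercept_s=float(intercept),
            temperature_range_C=(float(centers_arr[ok].min()), float(centers_arr[ok].max())),
            residual_rms_s=float(np.sqrt(np.mean(resid**2))),
            n_bins=int(ok.sum()),
        )
    return PhaseDiagram(
        boundaries=boundaries,
        temperature_range_C=(float(centers_arr.min()), float(centers_arr.max())),
    )


def plot_coverage_curves(results: dict[str, "CoverageResult"], path=None):
    """Per-prefix coverage curves for a set of labelled runs (percent of pooled cells)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, res in results.items():
        ax.plot(100.0 * res.prefix_curve, label=label)
    ax.set_xlabel("experiment")
    ax.set_ylabel("behavior space explored (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_phase_diagram(diagram: "PhaseDiagram", path=None, t_max_s: float = 900.0):
    """Time-temperature phase diagram: boundary lines and phase labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = diagram.temperature_range_C
    temps = np.linspace(lo, hi, 50)
    fig, ax = plt.subplots(figsize=(6, 4))
    prev = np.zeros_like(temps)
    for j in sorted(diagram.boundaries):
        times = np.array([diagram.boundaries[j].time_at(T) for T in temps])
        ax.plot(times, temps, "k--", lw=1)
        ax.fill_betweenx(temps, prev, times, alpha=0.25, label=PHASE_LABELS[j])
        prev = times
    ax.fill_betweenx(temps, prev, np.full_like(temps, t_max_s), alpha=0.25,
                     label=PHASE_LABELS[5])
    ax.set_xlim(0, t_max_s)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("temperature (degC)")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def classify_phase(t_s: float, temperature_C: float, diagram: PhaseDiagram) -> str:
    """Phase label at a (time, temperature) point inside the diagram's valid range."""
    lo, hi = diagram.temperature_range_C
    if not (lo <= temperature_C <= hi):
        raise ValueError(
            f"temperature {temperature_C} degC outside the diagram range [{lo}, {hi}]"
        )
    if not diagram.is_complete():
        raise ValueError("phase diagram is incomplete; cannot classify all six phases")
    label = 0
    for j in sorted(diagram.boundaries):
        if t_s >= diagram.boundaries[j].time_at(temperature_C):
            label = j + 1
    return PHASE_LABELS[label]
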