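"""Coverage, Welch test, temperature inference, and the phase-diagram pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropexplore.core_data import BehaviorObservation, ObservationBounds, normalize_formulation
from dropexplore.droplet_env_sim import (
    EnvConfig,
    EnvelopeParams,
    TrajectorySet,
    _landscape,
    envelope_params,
    envelope_speed,
    simulate_experiment,
    simulate_trajectories,
)
from dropexplore.behavior_analysis import (
    PHASE_LABELS,
    ProfileResult,
    build_phase_diagram,
    classify_phase,
    count_active,
    coverage,
    detect_phase_transitions,
    fold_change,
    infer_temperature,
    occupied_cells,
    speed_acceleration_profiles,
    welch_t_test,
)

from conftest import make_dataset


def clean_profile(temperature_C=25.0, dt=0.25, duration=900.0):
    p = envelope_params(EnvConfig(temperature_C=temperature_C))
    t = np.arange(0.0, duration, dt) + dt / 2.0
    v = envelope_speed(p, t)
    return ProfileResult(t, v, np.gradient(v, dt), dt), p


class TestCoverage:
    def test_empty_dataset_zero(self, bounds):
        from dropexplore.core_data import ExplorationDataset

        assert coverage(ExplorationDataset(), bounds).fraction == 0.0

    def test_identical_observations_one_cell(self, bounds):
        ds = make_dataset([[1, 1, 1, 1]] * 10, [[4.2, 3.1]] * 10)
        assert coverage(ds, bounds).n_occupied == 1

    def test_matches_enumeration_oracle_exactly(self, bounds):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(4), 200)
        Y = rng.uniform(0, 12, size=(200, 2))  # some observations out of bounds
        ds = make_dataset(X, Y)
        grid = 20
        # independent brute-force enumeration of occupied cells
        expected = set()
        for y in Y:
            z = np.clip(y / 10.0, 0.0, 1.0)
            expected.add((min(int(z[0] * grid), 19), min(int(z[1] * grid), 19)))
        assert occupied_cells(ds, bounds, grid) == expected
        assert coverage(ds, bounds, grid).n_occupied == len(expected)

    def test_prefix_curve_non_decreasing_and_consistent(self, bounds):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.dirichlet(np.ones(4), 100), rng.uniform(0, 10, (100, 2)))
        res = coverage(ds, bounds)
        assert np.all(np.diff(res.prefix_curve) >= 0)
        assert res.prefix_curve[-1] == pytest.approx(res.fraction)

    def test_pooled_reference_normalization(self, bounds):
        a = make_dataset([[1, 1, 1, 1]] * 2, [[1.2, 1.2], [5.2, 5.2]])
        b = make_dataset([[1, 1, 1, 1]] * 2, [[1.2, 1.2], [8.2, 8.2]])
        res = coverage(a, bounds, reference=[a, b])
        assert res.n_reference == 3  # union of distinct cells
        assert res.fraction == pytest.approx(2 / 3)


class TestCountActive:
    def test_strict_threshold(self):
        ds = make_dataset([[1, 1, 1, 1]] * 3, [[2.9, 1], [3.0, 1], [3.1, 1]])
        assert count_active(ds) == 1

    def test_empty_and_zero_threshold(self):
        from dropexplore.core_data import ExplorationDataset

        assert count_active(ExplorationDataset()) == 0
        ds = make_dataset([[1, 1, 1, 1]] * 3, [[0.5, 1], [1.0, 1], [2.0, 1]])
        assert count_active(ds, speed_threshold=0.0) == 3


class TestWelch:
    def test_identical_groups_degenerate(self):
        res = welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_separated_groups_significant(self):
        res = welch_t_test([1.0, 2.0, 3.0], [11.001, 12.0, 12.999])
        assert res.p < 0.01

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(3)
        from scipy import stats as sps

        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=5)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=7)
            res = welch_t_test(a, b)
            # independent textbook computation
            va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 7
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 6)
            p = 2.0 * sps.t.sf(abs(t), df)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_fold_change(self):
        assert fold_change(73.4, 22.5) == pytest.approx(3.26, abs=0.01)


class TestTemperatureInference:
    def test_single_pair_returns_its_temperature(self):
        obs = BehaviorObservation(4.0, 5.0)
        assert infer_temperature([(obs, 23.5)], BehaviorObservation(1.0, 1.0)) == 23.5

    def test_exact_match_returns_that_temperature(self):
        train = [
            (BehaviorObservation(2.0, 3.0), 21.0),
            (BehaviorObservation(4.0, 5.0), 25.0),
            (BehaviorObservation(6.0, 7.0), 29.0),
        ]
        assert infer_temperature(train, BehaviorObservation(4.0, 5.0)) == pytest.approx(25.0)

    def test_recovery_on_synthetic_active_recipe(self):
        """Behavior of an active recipe pins temperature to well under 2 degC."""
        sc, sa, _, _ = _landscape(EnvConfig())
        recipe = normalize_formulation(sc[np.argmax(sa)])
        rng = np.random.default_rng(42)

        def sample(n):
            pairs = []
            for _ in range(n):
                temp = float(rng.uniform(20, 30))
                cfg = EnvConfig(temperature_C=temp, seed=int(rng.integers(2**31)))
                pairs.append((simulate_experiment(recipe, cfg), temp))
            return pairs

        train, test = sample(200), sample(100)
        errors = np.array([infer_temperature(train, obs) - temp for obs, temp in test])
        assert abs(errors.mean()) < 0.3
        assert errors.std() <= 1.5


class TestProfiles:
    def test_constant_speed_zero_acceleration(self):
        times = np.arange(0, 30, 0.25)
        pos = np.stack([1.5 * times, np.zeros_like(times)], axis=1)[None]
        ts = TrajectorySet(times=times, positions=pos, dt=0.25)
        prof = speed_acceleration_profiles(ts)
        assert np.allclose(prof.speed_mm_s, 1.5, atol=1e-9)
        assert np.max(np.abs(prof.acceleration_mm_s2)) < 1e-9

    def test_linear_ramp_constant_acceleration(self):
        dt = 0.25
        times = np.arange(0, 60, dt)
        v_mid = 0.1 * (times[:-1] + dt / 2.0)
        x = np.concatenate([[0.0], np.cumsum(v_mid * dt)])
        pos = np.stack([x, np.zeros_like(x)], axis=1)[None]
        ts = TrajectorySet(times=times, positions=pos, dt=dt)
        prof = speed_acceleration_profiles(ts)
        interior = slice(20, -20)
        assert np.allclose(prof.acceleration_mm_s2[interior], 0.1, atol=1e-6)

    def test_too_few_points_rejected(self):
        ts = TrajectorySet(times=np.arange(3) * 0.25, positions=np.zeros((1, 3, 2)), dt=0.25)
        with pytest.raises(ValueError):
            speed_acceleration_profiles(ts)

    def test_two_peak_envelope_has_two_speed_maxima(self):
        from scipy.signal import find_peaks

        prof, _ = clean_profile()
        peaks, _ = find_peaks(prof.speed_mm_s, prominence=0.2)
        assert len(peaks) == 2


class TestTransitionDetection:
    def test_clean_envelope_within_two_seconds(self):
        prof, p = clean_profile()
        detected = detect_phase_transitions(prof).as_array()
        assert np.all(np.abs(detected - np.array(p.boundaries)) < 2.0)

    def test_monotone_decreasing_speed_no_transitions(self):
        t = np.arange(0, 100, 0.25)
        v = np.maximum(5.0 - 0.05 * t, 0.0)
        prof = ProfileResult(t, v, np.gradient(v, 0.25), 0.25)
        assert detect_phase_transitions(prof).times_s == (None, None, None, None, None)

    def test_single_peak_profile_lacks_final_transitions(self):
        t = np.arange(0, 400, 0.25)
        v = 4.0 * np.exp(-((t - 150.0) ** 2) / (2 * 40.0**2))
        prof = ProfileResult(t, v, np.gradient(v, 0.25), 0.25)
        times = detect_phase_transitions(prof).times_s
        assert times[0] is not None and times[1] is not None
        assert times[4] is None  # no second speed maximum


@pytest.fixture(scope="module")
def campaign():
    f = normalize_formulation((1, 1, 1, 1))
    rng = np.random.default_rng(7)
    experiments = []
    for i in range(60):
        temp = 20.0 + 10.0 * (i + 0.5) / 60.0
        cfg = EnvConfig(temperature_C=float(temp), seed=int(rng.integers(2**31)))
        experiments.append((float(temp), simulate_trajectories(f, cfg, 900.0, dt=0.25)))
    return experiments


class TestPhaseDiagram:
    def test_recovers_linear_boundaries(self, campaign):
        diagram = build_phase_diagram(campaign, bin_width_C=1.0)
        assert len(diagram.boundaries) == 5
        from dropexplore.droplet_env_sim import PHASE_BOUNDARY_SLOPES_S_PER_C

        for j, fit in diagram.boundaries.items():
            true_slope = PHASE_BOUNDARY_SLOPES_S_PER_C[j]
            assert abs(fit.slope_s_per_C - true_slope) / abs(true_slope) < 0.15

    def test_per_bin_transitions_within_two_seconds(self, campaign):
        bins: dict[int, list] = {}
        for temp, ts in campaign:
            bins.setdefault(int(temp), []).append(ts)
        for idx, group in bins.items():
            prof = speed_acceleration_profiles(group)
            detected = detect_phase_transitions(prof).as_array()
            truth = envelope_params(EnvConfig(temperature_C=idx + 0.5)).boundaries
            assert np.all(np.abs(detected - np.array(truth)) < 2.0)

    def test_temperature_independent_fixture_yields_flat_boundaries(self):
        f = normalize_formulation((1, 1, 1, 1))
        fixed = EnvelopeParams(
            boundaries=(40.0, 110.0, 180.0, 330.0, 480.0),
            peak_speeds=(4.0, 3.5),
            trough_speed=1.2,
        )
        rng = np.random.default_rng(9)
        experiments = []
        for i in range(12):
            temp = 20.5 + i % 6 * 2.0
            cfg = EnvConfig(temperature_C=float(temp), seed=int(rng.integers(2**31)))
            experiments.append(
                (float(temp), simulate_trajectories(f, cfg, 900.0, dt=0.25, params=fixed))
            )
        diagram = build_phase_diagram(experiments, bin_width_C=1.0)
        for fit in diagram.boundaries.values():
            assert abs(fit.slope_s_per_C) < 0.5

    def test_classification_partitions_time_in_order(self, campaign):
        diagram = build_phase_diagram(campaign, bin_width_C=1.0)
        for temp in (21.0, 25.0, 29.0):
            labels = [classify_phase(t, temp, diagram) for t in np.arange(0.0, 900.0, 1.0)]
            # ordered, non-repeating walk through all six phases
            dedup = [labels[0]] + [b for a, b in zip(labels, labels[1:]) if b != a]
            assert dedup == list(PHASE_LABELS)

    def test_boundary_epsilon_flips_label_consistently(self, campaign):
        diagram = build_phase_diagram(campaign, bin_width_C=1.0)
        temp = 25.0
        for j, fit in sorted(diagram.boundaries.items()):
            t_b = fit.time_at(temp)
            assert classify_phase(t_b - 0.5, temp, diagram) == PHASE_LABELS[j]
            assert classify_phase(t_b + 0.5, temp, diagram) == PHASE_LABELS[j + 1]

    def test_out_of_range_temperature_rejected(self, campaign):
        diagram = build_phase_diagram(campaign, bin_width_C=1.0)
        with pytest.raises(ValueError):
            classify_phase(100.0, 35.0, diagram)

    def test_single_bin_rejected(self):
        f = normalize_formulation((1, 1, 1, 1))
        ts = simulate_trajectories(f, EnvConfig(temperature_C=25.0, seed=1), 900.0, dt=0.25)
        with pytest.raises(ValueError):
            build_phase_diagram([(25.2, ts), (25.4, ts)])
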