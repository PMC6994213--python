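"""Tracking pipeline: detection accuracy, proximity linking, behavior metrics."""

import numpy as np
import pytest

from dropexplore.droplet_env_sim import TrajectorySet
from dropexplore.droplet_tracking import (
    ExitEvent,
    FixtureError,
    FuseEvent,
    SplitEvent,
    Track,
    VideoMeta,
    compute_behavior,
    detect_droplets,
    generate_synthetic_video,
    link_detections,
    read_frames,
    track_video,
    tracks_to_frame,
)

META = VideoMeta(fps=20.0, mm_per_px=0.1, arena_center_px=(170.0, 170.0), arena_radius_px=160.0)
DT = 1.0 / META.fps


def stationary_trajectories(positions_mm, n_frames=40):
    pos = np.repeat(np.asarray(positions_mm, dtype=float)[:, None, :], n_frames, axis=1)
    return TrajectorySet(times=np.arange(n_frames) * DT, positions=pos, dt=DT)


def y_pattern_mm():
    return np.array([[0.0, 0.0], [0.0, 4.0], [-3.46, -2.0], [3.46, -2.0]])


class TestSyntheticVideo:
    def test_empty_trajectories_blank_frames(self):
        ts = TrajectorySet(times=np.arange(10) * DT, positions=np.empty((0, 10, 2)), dt=DT)
        frames, truth = generate_synthetic_video(ts, META)
        assert truth == []
        assert np.all(frames == frames[0, 0, 0])
        assert detect_droplets(frames[0], META, threshold=100.0) == []

    def test_off_arena_trajectory_rejected(self):
        ts = stationary_trajectories([[20.0, 0.0]])
        with pytest.raises(FixtureError):
            generate_synthetic_video(ts, META)

    def test_y_pattern_renders_four_constant_truth_tracks(self):
        ts = stationary_trajectories(y_pattern_mm())
        frames, truth = generate_synthetic_video(ts, META)
        assert len(truth) == 4
        for tt in truth:
            arr = np.asarray(tt.positions_px)
            assert len(arr) == 40
            assert np.allclose(arr, arr[0])

    def test_rendered_centroid_matches_ground_truth(self):
        ts = stationary_trajectories([[2.35, -1.4]], n_frames=1)
        frames, truth = generate_synthetic_video(ts, META, noise_sd=0.0)
        dets = detect_droplets(frames[0], META)
        assert len(dets) == 1
        err = np.linalg.norm(np.array(dets[0].centroid_px) - truth[0].positions_px[0])
        assert err < 0.5


class TestDetection:
    def test_uniform_bright_frame_empty(self):
        frame = np.full((340, 340), 220, dtype=np.uint8)
        assert detect_droplets(frame, META, threshold=100.0) == []

    def test_four_disjoint_disks_detected_subpixel(self):
        ts = stationary_trajectories(y_pattern_mm(), n_frames=1)
        frames, truth = generate_synthetic_video(ts, META)
        dets = detect_droplets(frames[0], META)
        assert len(dets) == 4
        for d in dets:
            err = min(
                np.linalg.norm(np.array(d.centroid_px) - tt.positions_px[0]) for tt in truth
            )
            assert err < 0.5

    def test_overlapping_disks_merge_to_one_detection(self):
        ts = stationary_trajectories([[0.0, 0.0], [0.5, 0.0]], n_frames=1)  # 5 px apart
        frames, _ = generate_synthetic_video(ts, META, droplet_radius_px=6.0)
        dets = detect_droplets(frames[0], META)
        assert len(dets) == 1


class TestLinking:
    def test_stationary_identities_preserved(self):
        ts = stationary_trajectories(y_pattern_mm())
        frames, _ = generate_synthetic_video(ts, META)
        tracks = track_video(frames, META)
        assert len(tracks) == 4
        assert all(len(t.frames) == 40 and t.status == "active" for t in tracks)

    def test_split_event_opens_one_new_track(self):
        ts = stationary_trajectories(y_pattern_mm(), n_frames=60)
        frames, _ = generate_synthetic_video(
            ts,
            META,
            droplet_radius_px=4.0,
            events=[SplitEvent(frame=20, droplet_id=1, drift_px_per_frame=(2.0, 0.0))],
        )
        tracks = track_video(frames, META, max_link_distance_px=8.0)
        assert len(tracks) == 5
        child = max(tracks, key=lambda t: t.frames[0])
        assert child.frames[0] > 20
        assert child.track_id == 4

    def test_exit_event_closes_track_as_exited(self):
        positions = np.array([[0.0, 0.0], [14.5, 0.0]])  # second droplet near the rim
        ts = stationary_trajectories(positions, n_frames=30)
        frames, _ = generate_synthetic_video(
            ts, META, events=[ExitEvent(frame=15, droplet_id=1)]
        )
        tracks = track_video(frames, META)
        statuses = sorted(t.status for t in tracks)
        assert statuses == ["active", "exited"]

    def test_fuse_event_closes_track_as_fused(self):
        positions = np.array([[0.0, 0.0], [1.0, 0.0]])  # adjacent droplets
        ts = stationary_trajectories(positions, n_frames=30)
        frames, _ = generate_synthetic_video(
            ts, META, droplet_radius_px=4.0, events=[FuseEvent(frame=15, droplet_id=0, absorbed_id=1)]
        )
        tracks = track_video(frames, META, max_link_distance_px=12.0)
        assert sorted(t.status for t in tracks) == ["active", "fused"]

    def test_equidistant_match_goes_to_lowest_track_id(self):
        t0, t1 = Track(track_id=0), Track(track_id=1)
        t0.append(0, np.array([100.0, 100.0]), META)
        t1.append(0, np.array([120.0, 100.0]), META)
        from dropexplore.droplet_tracking import DropletDetection

        det = DropletDetection(frame_index=1, centroid_px=(110.0, 100.0), area_px2=50.0)
        tracks = link_detections([t0, t1], [det], META, max_link_distance_px=12.0, frame_index=1)
        assert len(t0.frames) == 2  # lowest id wins the tie
        assert t1.status == "fused"  # its last position is near the winner's detection


class TestBehaviorMetrics:
    def test_stationary_droplets_zero_speed_exact_count(self):
        ts = stationary_trajectories(y_pattern_mm())
        frames, _ = generate_synthetic_video(ts, META)
        obs, profiles = compute_behavior(track_video(frames, META), META)
        assert obs.mean_speed == pytest.approx(0.0, abs=1e-6)
        assert obs.mean_droplet_count == pytest.approx(4.0)
        assert len(profiles) == 4

    def test_circular_motion_speed_matches_analytic(self):
        """r = 5 mm at omega = 0.4 rad/s -> v = 2.0 mm/s."""
        times = np.arange(0, 10, DT)
        theta = 0.4 * times
        pos = np.stack([5.0 * np.cos(theta), 5.0 * np.sin(theta)], axis=1)[None]
        ts = TrajectorySet(times=times, positions=pos, dt=DT)
        frames, _ = generate_synthetic_video(ts, META)
        obs, _ = compute_behavior(track_video(frames, META), META)
        assert obs.mean_speed == pytest.approx(2.0, rel=0.02)
        assert obs.mean_droplet_count == pytest.approx(1.0)

    def test_no_tracks_is_an_error(self):
        with pytest.raises(ValueError):
            compute_behavior([], META)

    def test_speed_invariant_to_global_intensity_offset(self):
        times = np.arange(0, 5, DT)
        theta = 0.4 * times
        pos = np.stack([5.0 * np.cos(theta), 5.0 * np.sin(theta)], axis=1)[None]
        ts = TrajectorySet(times=times, positions=pos, dt=DT)
        frames, _ = generate_synthetic_video(ts, META)
        brighter = np.clip(frames.astype(int) + 20, 0, 255).astype(np.uint8)
        obs_a, _ = compute_behavior(track_video(frames, META), META)
        obs_b, _ = compute_behavior(track_video(brighter, META), META)
        assert obs_b.mean_speed == pytest.approx(obs_a.mean_speed, rel=0.01)


class TestIO:
    def test_tiff_stack_round_trip(self, tmp_path):
        import tifffile

        ts = stationary_trajectories(y_pattern_mm(), n_frames=3)
        frames, _ = generate_synthetic_video(ts, META)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, frames, photometric="minisblack")
        loaded = read_frames(path)
        assert loaded.shape == frames.shape
        assert np.array_equal(loaded, frames)

    def test_tracks_table_schema(self):
        ts = stationary_trajectories(y_pattern_mm(), n_frames=5)
        frames, _ = generate_synthetic_video(ts, META)
        df = tracks_to_frame(track_video(frames, META), META)
        assert list(df.columns) == ["track_id", "frame", "t_s", "x_mm", "y_mm", "status"]
        assert len(df) == 20
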