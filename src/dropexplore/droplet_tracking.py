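"""From image sequences to per-droplet tracks and behavior metrics.

Pipeline: threshold each grayscale frame (dyed droplets are dark on a light
background), extract connected components inside the dish, link detections
across frames with a greedy nearest-neighbor proximity rule — droplets can
split (new track), fuse (track absorbed by a neighbor), or leave the
tracking area (track exited) — then turn tracks into the behavior metrics
used as the exploration observation space: mean speed (mm/s) and mean
droplet count, with 2-s sliding-window speed profiles for phase analysis.

A synthetic video generator renders trajectories as anti-aliased dark disks
with exact ground truth, providing the test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import measure
from skimage.filters import threshold_otsu

from .core_data import BehaviorObservation
from .droplet_env_sim import TrajectorySet

__all__ = [
    "VideoMeta",
    "DropletDetection",
    "Track",
    "SpeedProfile",
    "SplitEvent",
    "FuseEvent",
    "ExitEvent",
    "TruthTrack",
    "FixtureError",
    "generate_synthetic_video",
    "detect_droplets",
    "link_detections",
    "compute_behavior",
    "track_video",
    "read_frames",
    "tracks_to_frame",
    "default_max_link_distance_px",
    "centered_moving_average",
]


class FixtureError(ValueError):
    """Raised when a synthetic-video request is inconsistent (e.g. off-arena trajectory)."""


@dataclass(frozen=True)
class VideoMeta:
    """Geometry and timing of a droplet video.

    Droplet experiments are recorded at 20 fps; ``mm_per_px`` converts pixel
    displacements to mm before any speed computation. Pixel coordinates are
    0-based, origin top-left, x rightward, y downward.
    """

    fps: float = 20.0
    mm_per_px: float = 0.1
    arena_center_px: tuple[float, float] = (170.0, 170.0)
    arena_radius_px: float = 160.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be > 0, got {self.mm_per_px}")

    def px_to_mm(self, xy_px: np.ndarray) -> np.ndarray:
        center = np.asarray(self.arena_center_px)
        return (np.asarray(xy_px, dtype=float) - center) * self.mm_per_px

    def mm_to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        center = np.asarray(self.arena_center_px)
        return np.asarray(xy_mm, dtype=float) / self.mm_per_px + center


@dataclass(frozen=True)
class DropletDetection:
    """One thresholded dark region in one frame."""

    frame_index: int
    centroid_px: tuple[float, float]
    area_px2: float
    contour: np.ndarray | None = None


@dataclass
class Track:
    """One droplet identity through time: (frame, position in mm) samples plus a status."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions_mm: list[np.ndarray] = field(default_factory=list)
    positions_px: list[np.ndarray] = field(default_factory=list)
    status: str = "active"

    @property
    def last_px(self) -> np.ndarray:
        return self.positions_px[-1]

    def append(self, frame: int, centroid_px: np.ndarray, meta: VideoMeta) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("track frame indices must be strictly increasing")
        self.frames.append(int(frame))
        self.positions_px.append(np.asarray(centroid_px, dtype=float))
        self.positions_mm.append(meta.px_to_mm(centroid_px))


@dataclass(frozen=True)
class SpeedProfile:
    """Per-track smoothed speed series (2-s centered sliding window by default)."""

    track_id: int
    times_s: np.ndarray
    speeds_mm_s: np.ndarray


# ---------------------------------------------------------------------------
# Synthetic video fixture generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitEvent:
    """From ``frame`` on, a child droplet separates from ``droplet_id`` and drifts away."""

    frame: int
    droplet_id: int
    drift_px_per_frame: tuple[float, float] = (1.0, 0.0)


@dataclass(frozen=True)
class FuseEvent:
    """From ``frame`` on, droplet ``absorbed_id`` merges into ``droplet_id`` and disappears."""

    frame: int
    droplet_id: int
    absorbed_id: int


@dataclass(frozen=True)
class ExitEvent:
    """From ``frame`` on, ``droplet_id`` has left the tracking area."""

    frame: int
    droplet_id: int


@dataclass
class TruthTrack:
    """Ground-truth identity emitted by the fixture generator."""

    track_id: int
    start_frame: int
    positions_px: list[np.ndarray]
    end_reason: str | None = None  # None (survives), "fused", "exited"

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions_px) - 1


def _render_frame(
    shape: tuple[int, int],
    centers_px: Sequence[np.ndarray],
    radius_px: float,
    bg: float = 220.0,
    fg: float = 30.0,
) -> np.ndarray:
    frame = np.full(shape, bg, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for c in centers_px:
        dist = np.hypot(xx - c[0], yy - c[1])
        cover = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)  # 1-px anti-aliasing ramp
        frame = frame - (bg - fg) * cover
    return np.clip(frame, 0, 255)


def generate_synthetic_video(
    trajs: TrajectorySet,
    meta: VideoMeta,
    droplet_radius_px: float = 6.0,
    noise_sd: float = 0.0,
    events: Sequence[SplitEvent | FuseEvent | ExitEvent] = (),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[TruthTrack]]:
    """Render trajectories as dark disks on a light background, with ground truth.

    Each trajectory sample becomes one frame (generate trajectories with
    dt = 1/fps). Scripted split/fuse/exit events alter which droplets are
    rendered; the returned :class:`TruthTrack` list is the exact identity
    bookkeeping a perfect tracker should recover.
    """
    size = int(np.ceil(2 * meta.arena_radius_px + 20))
    shape = (size, size)
    arena_mm = meta.arena_radius_px * meta.mm_per_px
    if np.any(np.linalg.norm(trajs.positions, axis=2) > arena_mm + 1e-9):
        raise FixtureError("trajectory leaves the arena circle")
    n_frames = trajs.positions.shape[1]
    truth: list[TruthTrack] = [
        TruthTrack(track_id=i, start_frame=0, positions_px=[]) for i in range(trajs.n_droplets)
    ]
    alive = {i: True for i in range(trajs.n_droplets)}
    splits = [e for e in events if isinstance(e, SplitEvent)]
    child_of: dict[int, tuple[SplitEvent, TruthTrack]] = {}
    next_id = trajs.n_droplets
    if rng is None:
        rng = np.random.default_rng(0)
    frames = np.empty((n_frames, size, size), dtype=np.uint8)
    for k in range(n_frames):
        for e in events:
            if e.frame == k:
                if isinstance(e, FuseEvent):
                    alive[e.absorbed_id] = False
                    truth[e.absorbed_id].end_reason = "fused"
                elif isinstance(e, ExitEvent):
                    alive[e.droplet_id] = False
                    truth[e.droplet_id].end_reason = "exited"
        for e in splits:
            if e.frame == k:
                child = TruthTrack(track_id=next_id, start_frame=k, positions_px=[])
                truth.append(child)
                child_of[next_id] = (e, child)
                next_id += 1
        centers: list[np.ndarray] = []
        for i in range(trajs.n_droplets):
            if alive[i]:
                c = meta.mm_to_px(trajs.positions[i, k])
                truth[i].positions_px.append(c)
                centers.append(c)
        for tid, (e, child) in child_of.items():
            parent_px = meta.mm_to_px(trajs.positions[e.droplet_id, k])
            offset = np.asarray(e.drift_px_per_frame) * (k - e.frame + 1)
            c = parent_px + offset
            child.positions_px.append(c)
            centers.append(c)
        frame = _render_frame(shape, centers, droplet_radius_px)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[k] = np.clip(frame, 0, 255).astype(np.uint8)
    return frames, truth


# ---------------------------------------------------------------------------
# Detection and linking
# ---------------------------------------------------------------------------


def detect_droplets(
    frame: np.ndarray,
    meta: VideoMeta,
    threshold: float | None = None,
    min_area_px2: float = 4.0,
    frame_index: int = 0,
    with_contours: bool = False,
) -> list[DropletDetection]:
    """Threshold one grayscale frame and extract droplet detections.

    Connected regions darker than ``threshold`` (Otsu of the frame when not
    given), inside the arena circle, of area >= ``min_area_px2``. Centroids
    are darkness-weighted, giving sub-pixel accuracy on anti-aliased disks.
    """
    img = np.asarray(frame, dtype=float)
    if threshold is None:
        threshold = float(threshold_otsu(img))
    mask = img < threshold
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    cx, cy = meta.arena_center_px
    mask &= np.hypot(xx - cx, yy - cy) <= meta.arena_radius_px
    labels = measure.label(mask, connectivity=2)
    darkness = np.clip(threshold - img, 0.0, None)
    detections: list[DropletDetection] = []
    for region in measure.regionprops(labels, intensity_image=darkness):
        if region.area < min_area_px2:
            continue
        wy, wx = region.centroid_weighted
        if np.hypot(wx - cx, wy - cy) > meta.arena_radius_px:
            continue
        contour = None
        if with_contours:
            minr, minc, _, _ = region.bbox
            padded = np.pad(region.image, 1)
            cs = measure.find_contours(padded.astype(float), 0.5)
            if cs:
                rc = cs[0] - 1.0 + np.array([minr, minc])
                contour = rc[:, ::-1]  # (y, x) -> (x, y)
        detections.append(
            DropletDetection(
                frame_index=frame_index,
                centroid_px=(float(wx), float(wy)),
                area_px2=float(region.area),
                contour=contour,
            )
        )
    return detections


def default_max_link_distance_px(meta: VideoMeta, max_speed_mm_s: float = 12.0) -> float:
    """Per-frame linking radius equivalent to ``max_speed_mm_s`` of motion."""
    return max_speed_mm_s / meta.fps / meta.mm_per_px


def link_detections(
    tracks: list[Track],
    detections: Sequence[DropletDetection],
    meta: VideoMeta,
    max_link_distance_px: float | None = None,
    frame_index: int | None = None,
    rim_fraction: float = 0.85,
) -> list[Track]:
    """Assign one frame's detections to tracks by the greedy proximity rule.

    Pairs are matched in ascending distance (ties broken toward the lowest
    existing track id). Unmatched detections open new tracks (splits);
    unmatched active tracks are closed — ``exited`` if last seen near the
    arena rim, ``fused`` if their last position lies within the linking
    radius of another track's matched detection, else ``ended``.
    """
    if max_link_distance_px is None:
        max_link_distance_px = default_max_link_distance_px(meta)
    if frame_index is None:
        frame_index = detections[0].frame_index if detections else (
            max((t.frames[-1] for t in tracks if t.frames), default=-1) + 1
        )
    active = [t for t in tracks if t.status == "active"]
    det_pos = [np.asarray(d.centroid_px, dtype=float) for d in detections]
    pairs = []
    for t in active:
        for j, p in enumerate(det_pos):
            dist = float(np.linalg.norm(t.last_px - p))
            if dist <= max_link_distance_px:
                pairs.append((dist, t.track_id, j, t))
    pairs.sort(key=lambda q: (q[0], q[1], q[2]))
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()
    for dist, tid, j, t in pairs:
        if tid in matched_tracks or j in matched_dets:
            continue
        matched_tracks.add(tid)
        matched_dets.add(j)
        t.append(frame_index, det_pos[j], meta)
    next_id = max((t.track_id for t in tracks), default=-1) + 1
    for j, d in enumerate(detections):
        if j in matched_dets:
            continue
        t = Track(track_id=next_id)
        t.append(frame_index, det_pos[j], meta)
        tracks.append(t)
        next_id += 1
    center = np.asarray(meta.arena_center_px)
    matched_positions = [det_pos[j] for j in matched_dets]
    for t in active:
        if t.track_id in matched_tracks:
            continue
        r = float(np.linalg.norm(t.last_px - center))
        if r >= rim_fraction * meta.arena_radius_px:
            t.status = "exited"
        elif any(
            float(np.linalg.norm(t.last_px - p)) <= max_link_distance_px
            for p in matched_positions
        ):
            t.status = "fused"
        else:
            t.status = "ended"
    return tracks


def track_video(
    frames: np.ndarray | Sequence[np.ndarray],
    meta: VideoMeta,
    threshold: float | None = None,
    min_area_px2: float = 4.0,
    max_link_distance_px: float | None = None,
) -> list[Track]:
    """Detect and link droplets through a whole video.

    The threshold defaults to Otsu computed on the first frame and is held
    fixed for the rest of the video.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected a (n_frames, H, W) stack, got shape {frames.shape}")
    if threshold is None:
        threshold = float(threshold_otsu(frames[0].astype(float)))
    tracks: list[Track] = []
    for k in range(frames.shape[0]):
        dets = detect_droplets(
            frames[k], meta, threshold=threshold, min_area_px2=min_area_px2, frame_index=k
        )
        link_detections(
            tracks, dets, meta, max_link_distance_px=max_link_distance_px, frame_index=k
        )
    return tracks


# ---------------------------------------------------------------------------
# Behavior metrics
# ---------------------------------------------------------------------------


def centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window truncated at the sequence ends."""
    x = np.asarray(x, dtype=float)
    if window <= 1 or x.size == 0:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def compute_behavior(
    tracks: Sequence[Track],
    meta: VideoMeta,
    window_s: float = 2.0,
    experiment_duration_s: float | None = None,
) -> tuple[BehaviorObservation, list[SpeedProfile]]:
    """Summarize tracks into the 2-D behavior observation plus per-track speed profiles.

    Instantaneous speed is the centroid displacement times fps (in mm);
    per-track profiles are smoothed with a centered ``window_s`` sliding
    window. The experiment mean speed time-averages the per-frame mean speed
    over all active tracks; the mean droplet count time-averages the number
    of tracks present per frame.
    """
    tracks = [t for t in tracks if t.frames]
    if not tracks:
        raise ValueError("no tracked frames; cannot compute behavior")
    n_frames = max(t.frames[-1] for t in tracks) + 1
    if experiment_duration_s is not None:
        n_frames = max(n_frames, int(round(experiment_duration_s * meta.fps)))
    window = max(1, int(round(window_s * meta.fps)) | 1)
    profiles: list[SpeedProfile] = []
    speed_sum = np.zeros(n_frames)
    speed_n = np.zeros(n_frames)
    count = np.zeros(n_frames)
    for t in tracks:
        frames = np.asarray(t.frames)
        count[frames] += 1
        pos = np.asarray(t.positions_mm)
        if len(frames) < 2:
            profiles.append(
                SpeedProfile(t.track_id, frames / meta.fps, np.zeros(len(frames)))
            )
            continue
        gaps = np.diff(frames)
        inst = np.linalg.norm(np.diff(pos, axis=0), axis=1) * meta.fps / gaps
        speed_sum[frames[:-1]] += inst
        speed_n[frames[:-1]] += 1
        profiles.append(
            SpeedProfile(
                t.track_id,
                frames[:-1] / meta.fps,
                centered_moving_average(inst, window),
            )
        )
    has_speed = speed_n > 0
    mean_speed = float(np.mean(speed_sum[has_speed] / speed_n[has_speed])) if has_speed.any() else 0.0
    mean_count = float(np.mean(count))
    return BehaviorObservation(mean_speed, mean_count), profiles


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_frames(path: str | Path) -> np.ndarray:
    """Read a grayscale image stack: multi-page TIFF or a directory of frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg"}
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = np.stack([np.asarray(iio.imread(p)) for p in files])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
    else:
        frames = np.asarray(iio.imread(path))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1)
    return frames


def tracks_to_frame(tracks: Sequence[Track], meta: VideoMeta) -> pd.DataFrame:
    """Tidy per-sample table: track_id, frame, t_s, x_mm, y_mm, status."""
    rows = []
    for t in tracks:
        for frame, pos in zip(t.frames, t.positions_mm):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": frame,
                    "t_s": frame / meta.fps,
                    "x_mm": float(pos[0]),
                    "y_mm": float(pos[1]),
                    "status": t.status,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_mm", "y_mm", "status"])
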