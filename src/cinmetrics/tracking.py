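"""Comet tracking: projection, DoG filtering, spot detection, LAP linking,
track filtering and speed extraction.

The linker is deliberately "simple": frame-to-frame linear assignment with
a hard displacement cap, no gap closing and no split/merge.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.optimize

__all__ = [
    "MovieStack",
    "SpotSet",
    "Track",
    "TrackSet",
    "max_project",
    "dog_filter",
    "detect_spots",
    "detect_spots_stack",
    "link_tracks",
    "filter_tracks",
    "track_speeds",
    "track_movie",
]


@dataclass
class MovieStack:
    """Frames x (optional z) x height x width intensities with metadata."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (T, H, W) or (T, Z, H, W)")

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class SpotSet:
    """Detected spots: (frame, x, y, quality) with x = column, y = row."""

    spots: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.spots.reset_index(drop=True)
        required = {"frame", "x", "y", "quality"}
        if not required.issubset(df.columns):
            raise ValueError(f"spots must have columns {sorted(required)}")
        if (df["quality"] < 0).any():
            raise ValueError("quality must be >= 0")
        self.spots = df

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class Track:
    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mean_speed_um_min: float | None = None

    @property
    def n_spots(self) -> int:
        return len(self.frames)

    @property
    def duration_frames(self) -> int:
        return int(self.frames[-1] - self.frames[0] + 1)


@dataclass
class TrackSet:
    tracks: list[Track]
    cell_mean_speed_um_min: float | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, x, y in zip(t.frames, t.x, t.y):
                rows.append((t.track_id, int(f), float(x), float(y)))
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])


def max_project(stack: MovieStack) -> MovieStack:
    """Per-pixel maximum over z; identity when no z axis is present."""
    if not stack.has_z:
        return MovieStack(stack.data, stack.pixel_size_um, stack.frame_interval_s)
    return MovieStack(
        stack.data.max(axis=1), stack.pixel_size_um, stack.frame_interval_s
    )


def dog_filter(frame: np.ndarray, sigma_small: float, sigma_large: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass, reflect-padded borders."""
    if not 0 < sigma_small < sigma_large:
        raise ValueError("need 0 < sigma_small < sigma_large")
    frame = np.asarray(frame, dtype=float)
    lo = scipy.ndimage.gaussian_filter(frame, sigma_small, mode="reflect")
    hi = scipy.ndimage.gaussian_filter(frame, sigma_large, mode="reflect")
    return lo - hi


def _quadratic_offset(vals: np.ndarray) -> float:
    """Sub-pixel offset of a parabola through three samples centered on a max."""
    denom = vals[0] - 2.0 * vals[1] + vals[2]
    if denom >= 0:
        return 0.0
    off = 0.5 * (vals[0] - vals[2]) / denom
    return float(np.clip(off, -1.0, 1.0))


def detect_spots(
    filtered: np.ndarray, radius: float, quality_threshold: float, frame: int = 0
) -> SpotSet:
    """Local maxima of a DoG response, separated by >= radius, refined to
    sub-pixel positions by a per-axis quadratic fit."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(filtered, dtype=float)
    size = 2 * int(np.ceil(radius)) + 1
    local_max = scipy.ndimage.maximum_filter(img, size=size, mode="reflect")
    peaks = (img == local_max) & (img >= quality_threshold)
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False
    rows, cols = np.nonzero(peaks)
    records = []
    for r, c in zip(rows, cols):
        dy = _quadratic_offset(img[r - 1 : r + 2, c])
        dx = _quadratic_offset(img[r, c - 1 : c + 2])
        records.append((frame, c + dx, r + dy, img[r, c]))
    return SpotSet(pd.DataFrame(records, columns=["frame", "x", "y", "quality"]))


def detect_spots_stack(
    stack: MovieStack,
    radius: float,
    quality_threshold: float,
    sigma_small: float | None = None,
    sigma_large: float | None = None,
) -> SpotSet:
    """DoG-filter and detect every frame of a (projected) movie.

    Default sigmas follow the detector scale: radius/sqrt(2) and 1.6x that.
    """
    if stack.has_z:
        stack = max_project(stack)
    if sigma_small is None:
        sigma_small = radius / np.sqrt(2.0)
    if sigma_large is None:
        sigma_large = 1.6 * sigma_small
    frames = []
    for t in range(stack.n_frames):
        response = dog_filter(stack.data[t], sigma_small, sigma_large)
        frames.append(detect_spots(response, radius, quality_threshold, frame=t).spots)
    return SpotSet(pd.concat(frames, ignore_index=True))


_FORBIDDEN = 1e30


def link_tracks(spots: SpotSet, max_disp: float) -> TrackSet:
    """Frame-to-frame linear assignment minimizing summed squared
    displacement, with per-link cost capped at max_disp^2.

    Unlinked spots start new tracks; a track with no match terminates
    (no gap closing).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    df = spots.spots.sort_values(["frame", "x", "y"], kind="stable")
    if df.empty:
        return TrackSet(tracks=[])
    cap = max_disp**2
    next_id = 0
    # active: list of [track_id, frames, xs, ys] with last frame == t_prev
    active: list[list] = []
    finished: list[list] = []
    frames_present = df["frame"].to_numpy()
    t_min, t_max = int(frames_present.min()), int(frames_present.max())
    by_frame = {int(t): sub for t, sub in df.groupby("frame", sort=True)}
    for t in range(t_min, t_max + 1):
        sub = by_frame.get(t)
        pts = (
            sub[["x", "y"]].to_numpy(dtype=float)
            if sub is not None
            else np.empty((0, 2))
        )
        if active and len(pts):
            prev = np.array([[tr[2][-1], tr[3][-1]] for tr in active])
            cost = ((prev[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(cost <= cap, cost, _FORBIDDEN)
            rows, cols = scipy.optimize.linear_sum_assignment(cost)
            linked_tracks = set()
            linked_spots = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _FORBIDDEN:
                    active[i][1].append(t)
                    active[i][2].append(pts[j, 0])
                    active[i][3].append(pts[j, 1])
                    linked_tracks.add(i)
                    linked_spots.add(j)
            still_active = [tr for i, tr in enumerate(active) if i in linked_tracks]
            finished.extend(tr for i, tr in enumerate(active) if i not in linked_tracks)
            for j in range(len(pts)):
                if j not in linked_spots:
                    still_active.append([next_id, [t], [pts[j, 0]], [pts[j, 1]]])
                    next_id += 1
            active = still_active
        else:
            finished.extend(active)
            active = []
            for j in range(len(pts)):
                active.append([next_id, [t], [pts[j, 0]], [pts[j, 1]]])
                next_id += 1
    finished.extend(active)
    tracks = [
        Track(
            track_id=tid,
            frames=np.asarray(fr, dtype=np.int64),
            x=np.asarray(xs, dtype=float),
            y=np.asarray(ys, dtype=float),
        )
        for tid, fr, xs, ys in sorted(finished, key=lambda tr: tr[0])
    ]
    return TrackSet(tracks=tracks)


def filter_tracks(tracks: TrackSet, min_duration_frames: int, min_spots: int) -> TrackSet:
    """Keep tracks with duration >= min_duration_frames and >= min_spots spots."""
    if min_duration_frames < 1 or min_spots < 1:
        raise ValueError("thresholds must be >= 1")
    kept = [
        t
        for t in tracks.tracks
        if t.duration_frames >= min_duration_frames and t.n_spots >= min_spots
    ]
    return TrackSet(tracks=kept)


def track_speeds(tracks: TrackSet, stack: MovieStack) -> TrackSet:
    """Per-track mean speed in um/min; per-cell mean is the unweighted mean
    of track means (tracks of a single spot carry no speed)."""
    out = []
    means = []
    for t in tracks.tracks:
        if t.n_spots < 2:
            out.append(
                Track(t.track_id, t.frames, t.x, t.y, mean_speed_um_min=None)
            )
            continue
        d_frames = np.diff(t.frames)
        disp_px = np.hypot(np.diff(t.x), np.diff(t.y))
        speeds = (
            disp_px * stack.pixel_size_um / (d_frames * stack.frame_interval_s) * 60.0
        )
        mean_speed = float(speeds.mean())
        out.append(Track(t.track_id, t.frames, t.x, t.y, mean_speed_um_min=mean_speed))
        means.append(mean_speed)
    cell_mean = float(np.mean(means)) if means else None
    return TrackSet(tracks=out, cell_mean_speed_um_min=cell_mean)


def track_movie(
    stack: MovieStack,
    radius: float = 3.0,
    quality_threshold: float = 5.0,
    max_disp: float = 6.0,
    min_duration_frames: int = 3,
    min_spots: int = 3,
) -> TrackSet:
    """Full chain: project, DoG-detect, link, filter, compute speeds."""
    if stack.n_frames < 2:
        raise ValueError("tracking needs >= 2 frames")
    spots = detect_spots_stack(stack, radius, quality_threshold)
    tracks = link_tracks(spots, max_disp)
    tracks = filter_tracks(tracks, min_duration_frames, min_spots)
    return track_speeds(tracks, stack)
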