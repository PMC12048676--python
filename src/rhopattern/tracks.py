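"""Spot tables, track linking and the spot-statistics CSV dialect.

Detected fluorescent molecules live in a :class:`SpotTable` (a thin wrapper
around a pandas DataFrame with the physical metadata every downstream
statistic needs: pixel size, frame interval and field-of-view extent).
Spots linked across frames become :class:`Track` objects, the substrate of
all dwell-time, landing-rate and diffusion analyses.

All coordinates are metric (µm), origin at the top-left pixel corner,
x rightward, y downward; the center of pixel ``(row=i, col=j)`` is at
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "SchemaError",
    "Spot",
    "Track",
    "SpotTable",
    "detect_spots",
    "link_tracks",
    "tracks_from_table",
    "crop_fov",
    "read_spot_csv",
    "write_spot_csv",
]

REQUIRED_COLUMNS = ("TRACK_ID", "POSITION_X", "POSITION_Y", "FRAME")


class SchemaError(ValueError):
    """A spot CSV is missing one of the required columns."""


@dataclass(frozen=True)
class Spot:
    frame: int
    x: float
    y: float
    intensity: float = np.nan
    channel: str = ""


@dataclass
class Track:
    """A time-ordered sequence of spots belonging to one molecule."""

    track_id: int
    frames: np.ndarray  # strictly increasing ints
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def death_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def dwell_frames(self) -> int:
        """Number of frames in which the molecule was observed."""
        return len(self.frames)

    def dwell_seconds(self, frame_interval: float) -> float:
        """Observed membrane dwell time, counting each observed frame."""
        return self.dwell_frames * frame_interval

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SpotTable:
    """Detected spots plus the acquisition metadata.

    ``spots`` columns: ``frame`` (int), ``x``, ``y`` (µm) and optionally
    ``intensity`` and ``track_id``.
    """

    spots: pd.DataFrame
    pixel_size: float  # µm / px
    frame_interval: float  # s
    fov_width: float  # µm
    fov_height: float  # µm
    channel: str = ""

    def __post_init__(self) -> None:
        for name, value in (
            ("pixel_size", self.pixel_size),
            ("frame_interval", self.frame_interval),
            ("fov_width", self.fov_width),
            ("fov_height", self.fov_height),
        ):
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")

    @property
    def area(self) -> float:
        """Field-of-view area in µm²."""
        return self.fov_width * self.fov_height

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def positions_by_frame(self) -> dict[int, np.ndarray]:
        """Map frame -> (N, 2) array of (x, y), in spot-table row order."""
        out: dict[int, np.ndarray] = {}
        for frame, grp in self.spots.groupby("frame", sort=True):
            out[int(frame)] = grp[["x", "y"]].to_numpy(dtype=float)
        return out


def detect_spots(
    stack: np.ndarray,
    sigma_px: float,
    threshold: float,
    *,
    pixel_size: float,
    frame_interval: float,
) -> SpotTable:
    """Laplacian-of-Gaussian spot detection with sub-pixel refinement.

    The scale-normalized LoG response (``-sigma² ∇²G * I``) is computed per
    frame; local maxima above ``threshold`` become candidate spots, whose
    positions are refined by an intensity-weighted center of mass inside a
    ``(2·ceil(2σ)+1)²`` window on the background-subtracted frame.

    Parameters are in pixels (``sigma_px``) and image units (``threshold``,
    on the LoG response: a Gaussian spot of amplitude A at matched scale
    yields a response peak of roughly A/2). Output coordinates are in µm.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty (time, y, x) stack")

    half = int(math.ceil(2 * sigma_px))
    rows = []
    for t, frame in enumerate(stack):
        response = -sigma_px**2 * ndi.gaussian_laplace(frame, sigma_px)
        peaks = peak_local_max(
            response,
            min_distance=max(1, int(round(sigma_px))),
            threshold_abs=threshold,
            exclude_border=False,
        )
        bg = float(np.median(frame))
        for i, j in peaks:
            i0, i1 = max(0, i - half), min(frame.shape[0], i + half + 1)
            j0, j1 = max(0, j - half), min(frame.shape[1], j + half + 1)
            patch = frame[i0:i1, j0:j1] - bg
            patch = np.clip(patch, 0, None)
            total = patch.sum()
            if total <= 0:
                ci, cj = float(i), float(j)
            else:
                ii, jj = np.mgrid[i0:i1, j0:j1]
                ci = float((ii * patch).sum() / total)
                cj = float((jj * patch).sum() / total)
            rows.append(
                {
                    "frame": t,
                    "x": (cj + 0.5) * pixel_size,
                    "y": (ci + 0.5) * pixel_size,
                    "intensity": float(total),
                }
            )
    spots = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"])
    return SpotTable(
        spots=spots,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        fov_width=stack.shape[2] * pixel_size,
        fov_height=stack.shape[1] * pixel_size,
    )


def link_tracks(table: SpotTable, max_disp: float, max_gap: int = 0) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate (active track, spot) pairs within ``max_disp`` µm are sorted by
    (distance, spot index, track index) and accepted one-to-one; unmatched
    spots seed new tracks; a track unmatched for more than ``max_gap``
    consecutive frames is closed. Adequate at single-molecule densities,
    where ambiguous assignments are rare; checked against exhaustive
    minimum-total-distance matching on small instances in the test suite.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    by_frame = table.positions_by_frame()
    if not by_frame:
        return []

    # active: list of [id, frames, xs, ys, last_frame]
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for frame in range(min(by_frame), max(by_frame) + 1):
        pts = by_frame.get(frame)
        # retire stale tracks
        still = []
        for tr in active:
            if frame - tr["frames"][-1] - 1 > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if pts is None or len(pts) == 0:
            continue
        pairs: list[tuple[float, int, int]] = []
        if active:
            last_pos = np.array([[tr["x"][-1], tr["y"][-1]] for tr in active])
            tree = cKDTree(last_pos)
            for s_idx, p in enumerate(pts):
                for t_idx in tree.query_ball_point(p, max_disp):
                    d = float(np.hypot(*(p - last_pos[t_idx])))
                    pairs.append((d, s_idx, t_idx))
        pairs.sort()
        used_spots: set[int] = set()
        used_tracks: set[int] = set()
        for d, s_idx, t_idx in pairs:
            if s_idx in used_spots or t_idx in used_tracks:
                continue
            used_spots.add(s_idx)
            used_tracks.add(t_idx)
            tr = active[t_idx]
            tr["frames"].append(frame)
            tr["x"].append(float(pts[s_idx, 0]))
            tr["y"].append(float(pts[s_idx, 1]))
        for s_idx, p in enumerate(pts):
            if s_idx in used_spots:
                continue
            active.append(
                {
                    "id": next_id,
                    "frames": [frame],
                    "x": [float(p[0])],
                    "y": [float(p[1])],
                }
            )
            next_id += 1
    done.extend(active)
    done.sort(key=lambda tr: tr["id"])
    return [
        Track(track_id=tr["id"], frames=tr["frames"], x=tr["x"], y=tr["y"])
        for tr in done
    ]


def tracks_from_table(table: SpotTable) -> list[Track]:
    """Group a spot table that already carries ``track_id`` into Track objects."""
    if "track_id" not in table.spots.columns:
        raise SchemaError("spot table has no track_id column; run link_tracks instead")
    tracks = []
    for tid, grp in table.spots.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                intensity=grp["intensity"].to_numpy() if "intensity" in grp else None,
            )
        )
    return tracks


def crop_fov(table: SpotTable, fraction: float) -> SpotTable:
    """Restrict analysis to the top-left rectangle of the field of view.

    ``fraction`` scales both axes, so the retained area is ``fraction²`` of
    the original (e.g. the customary 0.75 setting keeps 56.25% of the area).
    Bounds are half-open: a spot exactly on the crop boundary is excluded.
    The returned metadata is rescaled, so per-area statistics downstream use
    the cropped area automatically.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    w = fraction * table.fov_width
    h = fraction * table.fov_height
    keep = (table.spots["x"] < w) & (table.spots["y"] < h)
    return replace(
        table, spots=table.spots.loc[keep].reset_index(drop=True), fov_width=w, fov_height=h
    )


def read_spot_csv(
    path,
    *,
    pixel_size: float = 0.1,
    frame_interval: float = 0.022,
    fov_width: float | None = None,
    fov_height: float | None = None,
    channel: str = "",
) -> SpotTable:
    """Read a spot-statistics CSV (TrackMate export dialect accepted).

    Positions are expected in µm. Files exported by TrackMate carry up to
    three extra non-numeric header rows under the column names; those rows
    are skipped. Extra columns are ignored. If the field of view is not
    given it is inferred from the data extent (rounded up to whole pixels).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    sub = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    sub = sub.dropna().reset_index(drop=True)
    spots = pd.DataFrame(
        {
            "frame": sub["FRAME"].astype(int),
            "x": sub["POSITION_X"].astype(float),
            "y": sub["POSITION_Y"].astype(float),
            "track_id": sub["TRACK_ID"].astype(int),
        }
    )
    if fov_width is None:
        fov_width = _infer_extent(spots["x"], pixel_size)
    if fov_height is None:
        fov_height = _infer_extent(spots["y"], pixel_size)
    return SpotTable(
        spots=spots,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        fov_width=fov_width,
        fov_height=fov_height,
        channel=channel,
    )


def _infer_extent(values: pd.Series, pixel_size: float) -> float:
    if len(values) == 0:
        return pixel_size
    return math.ceil(float(values.max()) / pixel_size + 1) * pixel_size


def write_spot_csv(table: SpotTable, path) -> None:
    """Write a spot table in the spot-statistics dialect (lossless round trip)."""
    df = table.spots
    out = pd.DataFrame(
        {
            "TRACK_ID": df["track_id"].astype(int)
            if "track_id" in df.columns
            else np.arange(len(df)),
            "POSITION_X": df["x"],
            "POSITION_Y": df["y"],
            "FRAME": df["frame"].astype(int),
        }
    )
    out.to_csv(path, index=False)
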