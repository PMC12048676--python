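"""Dual-channel co-recruitment and colocalization statistics.

Two spots in the same frame are colocalized when their centroid distance is
at most the colocalization radius (0.5 µm by default, inclusive). A channel-A
track is *co-recruited* with channel B when it colocalizes with any B spot
during its first few observed frames after membrane recruitment (window of
3 frames by default). In experiment mode only new landing events count
(tracks born after the first movie frame); in control mode tracks already
present in the first frame are included, mirroring surface-immobilization
positive controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import SpotTable, Track

__all__ = [
    "ColocConfig",
    "CoRecruitmentSummary",
    "EmptyDenominatorError",
    "frame_colocalized",
    "classify_co_recruitment",
    "co_recruitment_fraction",
    "landing_rate",
    "colocalization_probability_by_position",
    "chance_colocalization",
]


class EmptyDenominatorError(ValueError):
    """No eligible tracks to classify."""


@dataclass(frozen=True)
class ColocConfig:
    radius: float = 0.5  # µm, inclusive
    window: int = 3  # frames after recruitment considered
    mode: str = "experiment"  # or "control"
    window_rule: str = "any"  # colocalized in any vs all of the window frames

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.mode not in ("experiment", "control"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.window_rule not in ("any", "all"):
            raise ValueError(f"unknown window_rule {self.window_rule!r}")


@dataclass(frozen=True)
class CoRecruitmentSummary:
    n_tracks: int
    n_corecruited: int
    fraction: float
    binomial_sd: float


def frame_colocalized(
    x: float, y: float, spots_b: np.ndarray | None, radius: float
) -> int | None:
    """Index of the nearest channel-B spot within ``radius`` (inclusive), else None.

    ``spots_b`` is an (N, 2) array of positions in the same frame; ties are
    broken by the lower index (``argmin`` returns the first minimum).
    """
    if spots_b is None or len(spots_b) == 0:
        return None
    d2 = (spots_b[:, 0] - x) ** 2 + (spots_b[:, 1] - y) ** 2
    idx = int(np.argmin(d2))
    if d2[idx] <= radius**2:
        return idx
    return None


def classify_co_recruitment(
    track: Track,
    b_by_frame: dict[int, np.ndarray],
    cfg: ColocConfig,
    first_movie_frame: int = 0,
) -> tuple[bool, bool]:
    """Return ``(eligible, co_recruited)`` for one channel-A track.

    The window covers the first ``cfg.window`` *observed* frames of the
    track (gap frames do not count): membrane lifetime is defined on
    observations. A track is co-recruited when it colocalizes with a B spot
    in any (or, with ``window_rule='all'``, every) window frame.
    """
    if cfg.mode == "experiment" and track.birth_frame <= first_movie_frame:
        return False, False
    hits = []
    for f, x, y in zip(
        track.frames[: cfg.window], track.x[: cfg.window], track.y[: cfg.window]
    ):
        hits.append(frame_colocalized(x, y, b_by_frame.get(int(f)), cfg.radius) is not None)
    co = any(hits) if cfg.window_rule == "any" else all(hits)
    return True, co


def co_recruitment_fraction(
    tracks_a: list[Track],
    table_b: SpotTable,
    cfg: ColocConfig,
    first_movie_frame: int = 0,
) -> CoRecruitmentSummary:
    """Fraction of eligible channel-A tracks co-recruited with channel B."""
    b_by_frame = table_b.positions_by_frame()
    n = n_co = 0
    for tr in tracks_a:
        eligible, co = classify_co_recruitment(tr, b_by_frame, cfg, first_movie_frame)
        if eligible:
            n += 1
            n_co += int(co)
    if n == 0:
        raise EmptyDenominatorError("no eligible channel-A tracks")
    f = n_co / n
    return CoRecruitmentSummary(
        n_tracks=n,
        n_corecruited=n_co,
        fraction=f,
        binomial_sd=math.sqrt(f * (1 - f) / n),
    )


def landing_rate(
    tracks: list[Track],
    area: float,
    duration: float,
    exclude_first_frame: bool = True,
    first_movie_frame: int = 0,
) -> float:
    """New membrane-binding events per second per µm².

    Tracks already present in the first frame are not landings and are
    excluded by default; ``duration`` should then be the time over which
    new landings could be observed. When the spot table was cropped, pass
    the cropped area (the metadata of :func:`~rhopattern.tracks.crop_fov`
    output does this automatically).
    """
    if area <= 0 or duration <= 0:
        raise ValueError("area and duration must be positive")
    if exclude_first_frame:
        n = sum(1 for tr in tracks if tr.birth_frame > first_movie_frame)
    else:
        n = len(tracks)
    return n / (area * duration)


def colocalization_probability_by_position(
    tracks_a: list[Track],
    table_b: SpotTable,
    cfg: ColocConfig,
    first_movie_frame: int = 0,
    max_offset: int | None = None,
) -> pd.DataFrame:
    """Colocalization probability as a function of membrane lifetime.

    For each frame offset k since recruitment, the probability that a
    channel-A track still alive at its k-th observed frame colocalizes with
    a B spot there, with a binomial SD. Offsets beyond the longest eligible
    track are absent from the output (not reported as zero). Eligibility
    follows ``cfg.mode`` exactly as in co-recruitment classification.
    """
    b_by_frame = table_b.positions_by_frame()
    counts: dict[int, int] = {}
    hits: dict[int, int] = {}
    for tr in tracks_a:
        if cfg.mode == "experiment" and tr.birth_frame <= first_movie_frame:
            continue
        upto = len(tr) if max_offset is None else min(len(tr), max_offset + 1)
        for k in range(upto):
            counts[k] = counts.get(k, 0) + 1
            matched = frame_colocalized(
                tr.x[k], tr.y[k], b_by_frame.get(int(tr.frames[k])), cfg.radius
            )
            if matched is not None:
                hits[k] = hits.get(k, 0) + 1
    rows = []
    for k in sorted(counts):
        n = counts[k]
        p = hits.get(k, 0) / n
        rows.append(
            {
                "frame_offset": k,
                "probability": p,
                "sd": math.sqrt(p * (1 - p) / n),
                "n_at_offset": n,
            }
        )
    return pd.DataFrame(rows, columns=["frame_offset", "probability", "sd", "n_at_offset"])


def chance_colocalization(density_b: float, radius: float) -> float:
    """Probability of a random encounter within ``radius`` of a spot.

    For channel-B spots scattered as a spatial Poisson process of density
    ρ (µm⁻²), the chance that at least one falls inside the colocalization
    disk is ``1 − exp(−ρ·π·r²)`` — the null against which apparent
    co-recruitment of independent channels is judged.
    """
    if density_b < 0:
        raise ValueError("density_b must be >= 0")
    return 1.0 - math.exp(-density_b * math.pi * radius**2)
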