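"""Step-size distributions, MSD curves and diffusion-coefficient estimates.

For 2-D Brownian motion the mean squared displacement grows linearly,
MSD(τ) = 4Dτ, and static localization noise of SD σ per axis adds a
constant offset of 4σ², so a line fitted to the first few lags yields
D = slope/4 and σ from the intercept. Steps across linking gaps are
excluded from step-size distributions and contribute only to the lag equal
to their true frame separation in the MSD (mixing time bases would bias
both statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import Track

__all__ = [
    "StepSizeDistribution",
    "MSDCurve",
    "step_sizes",
    "msd_curve",
    "fit_diffusion",
]


@dataclass
class StepSizeDistribution:
    """Per-frame displacements (µm), optionally labeled by membrane region."""

    steps: np.ndarray
    inside: np.ndarray | None = None  # bool per step, where a region mask was given

    def histogram(self, bins=30, range=None) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.steps, bins=bins, range=range)


@dataclass
class MSDCurve:
    lag: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # displacement pairs contributing per lag


def step_sizes(
    tracks: list[Track],
    region_mask: np.ndarray | None = None,
    *,
    pixel_size: float | None = None,
) -> StepSizeDistribution:
    """Euclidean displacements between consecutive observed frames.

    Only unit frame separations count (gap-spanning displacements are
    dropped). With ``region_mask`` (2-D boolean, image layout) and
    ``pixel_size``, each step is assigned to the region containing its
    *starting* spot.
    """
    if region_mask is not None and pixel_size is None:
        raise ValueError("pixel_size is required to index region_mask")
    steps: list[float] = []
    inside: list[bool] = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        dfr = np.diff(tr.frames)
        dx = np.diff(tr.x)
        dy = np.diff(tr.y)
        ok = dfr == 1
        d = np.hypot(dx[ok], dy[ok])
        steps.extend(d.tolist())
        if region_mask is not None:
            x0 = tr.x[:-1][ok]
            y0 = tr.y[:-1][ok]
            rows = np.clip((y0 / pixel_size).astype(int), 0, region_mask.shape[0] - 1)
            cols = np.clip((x0 / pixel_size).astype(int), 0, region_mask.shape[1] - 1)
            inside.extend(region_mask[rows, cols].tolist())
    return StepSizeDistribution(
        steps=np.asarray(steps),
        inside=np.asarray(inside, dtype=bool) if region_mask is not None else None,
    )


def msd_curve(
    tracks: list[Track],
    max_lag: int,
    frame_interval: float,
) -> MSDCurve:
    """Time-averaged then ensemble-averaged MSD for lags 1..max_lag.

    Each track contributes its time-averaged squared displacement at every
    lag it can realize (displacements are taken between observations whose
    frame numbers differ by exactly the lag); tracks are then averaged with
    equal weight. ``n_pairs`` counts the displacement pairs pooled per lag.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    sums = np.zeros(max_lag)  # sum over tracks of per-track mean
    n_tracks = np.zeros(max_lag, dtype=int)
    n_pairs = np.zeros(max_lag, dtype=int)
    for tr in tracks:
        if len(tr) < 2:
            continue
        frames = tr.frames
        # match observations separated by exactly k frames
        idx = {int(f): i for i, f in enumerate(frames)}
        for k in range(1, max_lag + 1):
            pair_sq = [
                (tr.x[idx[f + k]] - tr.x[i]) ** 2 + (tr.y[idx[f + k]] - tr.y[i]) ** 2
                for f, i in idx.items()
                if f + k in idx
            ]
            if pair_sq:
                sums[k - 1] += float(np.mean(pair_sq))
                n_tracks[k - 1] += 1
                n_pairs[k - 1] += len(pair_sq)
    with np.errstate(invalid="ignore"):
        msd = np.where(n_tracks > 0, sums / np.maximum(n_tracks, 1), np.nan)
    lag = np.arange(1, max_lag + 1) * frame_interval
    return MSDCurve(lag=lag, msd=msd, n_pairs=n_pairs)


def fit_diffusion(curve: MSDCurve, n_points: int = 4) -> tuple[float, float]:
    """Least-squares line through the first ``n_points`` MSD lags.

    Returns ``(D, intercept)`` with D = slope/4 (µm²/s); the intercept
    (µm²) estimates 4σ² of the static localization error.
    """
    ok = np.isfinite(curve.msd)
    lag = curve.lag[ok][:n_points]
    msd = curve.msd[ok][:n_points]
    if len(lag) < 2:
        raise ValueError("need at least 2 finite MSD points")
    res = stats.linregress(lag, msd)
    return res.slope / 4.0, res.intercept
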