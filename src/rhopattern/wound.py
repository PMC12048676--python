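"""Radial wound analysis: kymographs, line scans and the in vivo patterning index.

After laser wounding, signal organizes into a circular zone around the
wound center; radially averaging each frame into concentric annuli yields
a (distance × time) kymograph from which zone line scans and the in vivo
patterning index — peak intensity near the wound divided by the mean
background at least 30 µm away — are read off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "RadialKymograph",
    "radial_kymograph",
    "zone_profile",
    "wound_patterning_index",
    "estimate_wound_center",
]


@dataclass
class RadialKymograph:
    bin_centers: np.ndarray  # µm
    time: np.ndarray  # s
    intensity: np.ndarray  # (bins, frames) mean intensity per annulus
    counts: np.ndarray  # pixels per annulus
    center: tuple[float, float]  # (x, y) µm
    bin_width: float


def radial_kymograph(
    stack: np.ndarray,
    center: tuple[float, float],
    bin_width: float,
    max_radius: float,
    *,
    pixel_size: float,
    frame_interval: float = 1.0,
) -> RadialKymograph:
    """Radially average a movie around ``center`` (x, y in µm).

    Pixels are assigned to half-open annuli [k·w, (k+1)·w) by the distance
    of their centers to the wound center; each kymograph column is one
    frame. Annuli beyond the pixel coverage are truncated with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    t, h, w = stack.shape
    cx, cy = center
    if not (0 <= cx <= w * pixel_size and 0 <= cy <= h * pixel_size):
        raise ValueError("center lies outside the field of view")
    ii, jj = np.mgrid[0:h, 0:w]
    r = np.hypot((jj + 0.5) * pixel_size - cx, (ii + 0.5) * pixel_size - cy)
    n_bins = int(np.ceil(max_radius / bin_width))
    idx = np.floor(r / bin_width).astype(int)
    valid = idx < n_bins
    flat_idx = idx[valid]
    counts = np.bincount(flat_idx, minlength=n_bins)
    covered = counts > 0
    if not covered.all():
        warnings.warn(
            "max_radius exceeds the field of view; empty annuli truncated",
            stacklevel=2,
        )
        last = int(np.nonzero(covered)[0].max()) + 1
    else:
        last = n_bins
    intensity = np.empty((last, t))
    for f in range(t):
        sums = np.bincount(flat_idx, weights=stack[f][valid], minlength=n_bins)
        intensity[:, f] = sums[:last] / np.maximum(counts[:last], 1)
    return RadialKymograph(
        bin_centers=(np.arange(last) + 0.5) * bin_width,
        time=np.arange(t) * frame_interval,
        intensity=intensity,
        counts=counts[:last],
        center=(cx, cy),
        bin_width=bin_width,
    )


def _nearest_frame(kymo: RadialKymograph, t: float) -> int:
    # argmin returns the first minimum, so a time midway between two
    # frames resolves to the earlier one.
    return int(np.argmin(np.abs(kymo.time - t)))


def zone_profile(kymo: RadialKymograph, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Line scan (distance, intensity) at the frame nearest to time ``t``."""
    f = _nearest_frame(kymo, t)
    return kymo.bin_centers, kymo.intensity[:, f]


def wound_patterning_index(
    kymo: RadialKymograph,
    t: float,
    background_min_distance: float = 30.0,
) -> float:
    """Peak/background intensity ratio at time ``t``.

    The peak is the maximum over distance bins; background is the mean
    over all annuli whose centers lie at least ``background_min_distance``
    µm from the wound (a region, not a single bin).
    """
    f = _nearest_frame(kymo, t)
    profile = kymo.intensity[:, f]
    bg_bins = kymo.bin_centers >= background_min_distance
    if not bg_bins.any():
        raise ValueError(
            f"kymograph does not extend beyond {background_min_distance} µm"
        )
    return float(profile.max() / profile[bg_bins].mean())


def estimate_wound_center(
    frame: np.ndarray,
    *,
    pixel_size: float,
    roi: tuple[slice, slice] | None = None,
    smooth_px: float = 2.0,
) -> tuple[float, float]:
    """Wound center as the intensity minimum of a (smoothed) frame.

    A convenience for movies where the wound appears as a dark hole; pass
    ``roi`` (row, col slices) to restrict the search. Returns (x, y) µm.
    """
    frame = np.asarray(frame, dtype=float)
    sm = ndi.gaussian_filter(frame, smooth_px)
    region = sm[roi] if roi is not None else sm
    i, j = np.unravel_index(np.argmin(region), region.shape)
    if roi is not None:
        i += roi[0].start or 0
        j += roi[1].start or 0
    return ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)
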