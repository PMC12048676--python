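"""Lipid-pattern segmentation and the patterning index.

The pipeline mirrors a standard two-label membrane-domain workflow:
per-frame non-local-means denoising, contrast-limited adaptive histogram
equalization (CLAHE), seeded random-walker segmentation into inside/outside
labels, and morphological cleanup (binary closing then opening). The
patterning index PI = ⟨I_in⟩ / ⟨I_out⟩ is always computed on the *raw*
intensities — equalization exists only to make segmentation robust and
would destroy the very ratio the statistic measures.

Walker seeds are placed from intensity quartiles: pixels at or above the
75th percentile seed the inside label, pixels at or below the 25th
percentile seed the outside label, and the middle band is left for the
walker to assign. This is deterministic and invariant to positive scaling
of the input (percentiles and the min-max normalization in
:func:`preprocess` are scale-free).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.exposure import equalize_adapthist
from skimage.restoration import denoise_nl_means, estimate_sigma
from skimage.segmentation import random_walker

__all__ = [
    "NoContrastError",
    "preprocess",
    "segment_frame",
    "segment_stack",
    "clean_mask",
    "patterning_index_series",
    "normalize_pi",
]


class NoContrastError(ValueError):
    """Frame has no intensity spread to segment."""


def preprocess(
    stack: np.ndarray,
    *,
    patch_size: int = 5,
    patch_distance: int = 6,
    h_rel: float = 0.8,
    clip_limit: float = 0.01,
    kernel_size: int | None = None,
) -> np.ndarray:
    """Denoise (non-local means) and equalize (CLAHE) a single-channel stack.

    Each frame is min-max normalized to [0, 1], denoised with non-local
    means (filtering strength ``h = h_rel · σ̂`` with σ̂ the estimated noise
    SD), then CLAHE-equalized. Output values are in [0, 1]. A constant
    frame passes through unchanged up to the normalization offset.
    """
    stack = np.asarray(stack, dtype=float)
    squeeze = stack.ndim == 2
    if squeeze:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a 2-D frame or a (time, y, x) stack")
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        lo, hi = float(frame.min()), float(frame.max())
        if hi == lo:
            out[i] = 0.0
            continue
        f = (frame - lo) / (hi - lo)
        sigma = float(estimate_sigma(f))
        if sigma > 0 and h_rel > 0:
            f = denoise_nl_means(
                f,
                patch_size=patch_size,
                patch_distance=patch_distance,
                h=h_rel * sigma,
                fast_mode=True,
            )
        f = equalize_adapthist(
            np.clip(f, 0, 1), clip_limit=clip_limit, kernel_size=kernel_size
        )
        lo, hi = float(f.min()), float(f.max())
        out[i] = (f - lo) / (hi - lo) if hi > lo else 0.0
    return out[0] if squeeze else out


def segment_frame(
    frame: np.ndarray,
    *,
    beta: float = 130.0,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
    clean_iterations: int = 5,
    swap: bool = False,
) -> np.ndarray:
    """Two-label random-walker segmentation of one preprocessed frame.

    Pixels ≥ the ``high_pct`` percentile seed the inside-pattern label,
    pixels ≤ the ``low_pct`` percentile seed the outside label, and the
    walker (diffusion parameter ``beta``) assigns the middle band. The
    result passes through :func:`clean_mask`. ``swap=True`` treats the dim
    phase as the pattern (inverted-contrast inputs).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D frame")
    p_low, p_high = np.percentile(frame, [low_pct, high_pct])
    if p_high <= p_low:
        raise NoContrastError("frame has no contrast between percentile bands")
    markers = np.zeros(frame.shape, dtype=np.uint8)
    markers[frame <= p_low] = 1
    markers[frame >= p_high] = 2
    if (markers == 0).any():
        labels = random_walker(frame, markers, beta=beta, mode="bf")
    else:
        labels = markers  # two-level image: every pixel already seeded
    mask = labels == (1 if swap else 2)
    return clean_mask(mask, iterations=clean_iterations)


def segment_stack(stack: np.ndarray, **kwargs) -> np.ndarray:
    """Per-frame independent segmentation of a (time, y, x) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (time, y, x) stack")
    return np.stack([segment_frame(f, **kwargs) for f in stack])


def clean_mask(mask: np.ndarray, iterations: int = 5) -> np.ndarray:
    """Binary closing then opening (3×3 structure, ``iterations`` each).

    The mask is edge-padded before the morphology so regions touching the
    image border are not eroded by the boundary condition.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)
    pad = iterations + 1
    m = np.pad(mask, pad, mode="edge")
    m = ndi.binary_closing(m, structure=structure, iterations=iterations)
    m = ndi.binary_opening(m, structure=structure, iterations=iterations)
    return m[pad:-pad, pad:-pad]


def patterning_index_series(
    stack: np.ndarray,
    masks: np.ndarray,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Per-frame inside/outside mean intensities and their ratio.

    ``stack`` must be the raw (not preprocessed) channel to quantify;
    ``masks`` the per-frame inside-pattern truth or segmentation (a single
    2-D mask is broadcast over frames). Frames where either region is
    empty get ``pi = NaN`` and ``valid = False`` rather than being dropped.
    Columns: time, mean_in, mean_out, pi, valid.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, stack.shape)
    if masks.shape != stack.shape:
        raise ValueError("stack and masks shapes differ")
    rows = []
    for f, (frame, mask) in enumerate(zip(stack, masks)):
        n_in = int(mask.sum())
        n_out = mask.size - n_in
        mean_in = float(frame[mask].mean()) if n_in else np.nan
        mean_out = float(frame[~mask].mean()) if n_out else np.nan
        valid = n_in > 0 and n_out > 0 and mean_out != 0
        rows.append(
            {
                "time": f * frame_interval,
                "mean_in": mean_in,
                "mean_out": mean_out,
                "pi": mean_in / mean_out if valid else np.nan,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows, columns=["time", "mean_in", "mean_out", "pi", "valid"])


def normalize_pi(series: pd.DataFrame, baseline_window: int) -> pd.DataFrame:
    """Divide the PI series by its mean over the first ``baseline_window`` frames.

    Returns a copy with a ``normalized_pi`` column; used to compare
    perturbation responses across conditions with different baselines.
    """
    if not (0 < baseline_window <= len(series)):
        raise ValueError("baseline_window must cover 1..len(series) frames")
    baseline = series["pi"].iloc[:baseline_window]
    if baseline.isna().all():
        raise ValueError("baseline window contains no valid PI values")
    out = series.copy()
    out["normalized_pi"] = series["pi"] / baseline.mean()
    return out
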