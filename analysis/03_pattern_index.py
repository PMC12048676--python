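#!/usr/bin/env python
"""Lipid-pattern segmentation and patterning-index time course.

Simulates a GEF-addition experiment on a patterned bilayer: a baseline
segment where the activity reporter is uniform (PI_true = 1.0) followed by
a response segment where it enriches in the GEF-containing domains
(PI_true = 1.35) while total GTPase stays uniform. The lipid channel is
segmented per frame (denoise -> CLAHE -> random walker -> morphology) and
the patterning index is computed on raw intensities, then normalized to
the pre-addition baseline.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rhopattern.segmentation import (
    normalize_pi,
    patterning_index_series,
    preprocess,
    segment_stack,
)
from rhopattern.synthetic import PatternConfig, simulate_pattern_movie


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    segments = []  # (reporter PI_true, total PI_true, n_frames)
    for pi_rep, n_frames in ((1.0, 5), (1.35, 10)):
        pc = PatternConfig(
            geometry="blobs", contrast_ratio=2.0,
            channel_pi_true=(pi_rep, 1.0), noise_sd=10.0, seed=args.seed,
        )
        stacks, truth = simulate_pattern_movie(pc, shape=(96, 96), n_frames=n_frames)
        segments.append((stacks, truth))

    lipid = np.concatenate([s["lipid"] for s, _ in segments])
    reporter = np.concatenate([s["reporter_0"] for s, _ in segments])
    total = np.concatenate([s["reporter_1"] for s, _ in segments])
    truth_mask = np.concatenate([t.mask for _, t in segments])

    masks = segment_stack(preprocess(lipid))
    dice = np.array(
        [2 * (m & g).sum() / (m.sum() + g.sum()) for m, g in zip(masks, truth_mask)]
    )

    series = patterning_index_series(reporter, masks)
    series = normalize_pi(series, baseline_window=5)
    series["pi_total"] = patterning_index_series(total, masks)["pi"]
    series.to_csv(args.out / "patterning_index.csv", index=False)

    base = series.pi[:5].mean()
    resp = series.pi[5:].mean()
    print(f"segmentation Dice vs truth: min {dice.min():.3f}, mean {dice.mean():.3f}")
    print(f"activity reporter PI: baseline {base:.3f} -> after GEF {resp:.3f} "
          f"(generator truth 1.0 -> 1.35)")
    print(f"normalized PI plateau: {series.normalized_pi[5:].mean():.3f}")
    print(f"total GTPase PI stays at {series.pi_total.mean():.3f} (uniform)")
    print(f"series written to {args.out / 'patterning_index.csv'}")


if __name__ == "__main__":
    main()
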