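# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the parameters that matter, and the
numerical choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Single-molecule landing model

Channel-A molecules (the GTPase) land on the membrane as a spatially and
temporally homogeneous Poisson process with intensity λ
(events s⁻¹ µm⁻²; default 0.02, the trace-concentration regime at
~100 pM of GTPase:GDI complex). Time is discretized at the frame interval
Δt (default 22 ms, matching continuous-illumination streaming): a landing
occupies the start of its birth frame, and a dwell drawn from
Exp(k_off) covers `max(1, ceil(τ/Δt))` frames. Each molecule performs 2-D
Brownian motion with per-axis step variance 2·D·Δt (default D = 1 µm²/s,
typical of a prenylated protein on a fluid supported bilayer). With
probability `colabel_fraction` a channel-B partner (the GDI) is emitted
at the same true positions from the birth frame until an exponential
bleach time (default rate 2 s⁻¹: under the high power densities needed
for 22 ms streaming the partner fluorophore bleaches within a few hundred
milliseconds). Observed positions in both channels carry independent
Gaussian localization noise (default σ = 20 nm).

Molecules whose Brownian path leaves the field of view are terminated and
flagged in the ground truth. This choice avoids boundary artifacts but
censors preferentially *long* dwells (the probability of wandering out
grows with lifetime), so dwell-rate estimates conditioned on staying
in-view are biased high by a few percent when the diffusion length over a
mean dwell is not small compared to the FOV. Analyses that quantify dwell
kinetics therefore use slow-diffusion regimes (D ≈ 0.3 µm²/s,
20 × 20 µm FOV) where the bias is ~1–2%, and the dwell-ratio statistic
cancels most of what remains because both regions share the geometry.

A single `numpy` generator seeded from the configuration drives each
simulation, so identical configurations are bit-identical.

What the generator does *not* emulate: camera shot noise and EMCCD gain,
multi-step or reversible photophysics, anomalous or anisotropic
diffusion, vesicle geometry. Passing recovery tests therefore demonstrate
estimator correctness under the stated stochastic model, not robustness
to detector artifacts.

## Colocalization and co-recruitment

Two spots in the same frame are colocalized when their centroid distance
is **at most** 0.5 µm (inclusive threshold). Matching is A→nearest-B
without exclusivity: at single-molecule densities double-assignment is
rare, and only a distance rule is defined; ties break to the lower spot
index.

A channel-A track is *co-recruited* when it colocalizes with any B spot
in its first `window = 3` *observed* frames (membrane lifetime is defined
on observations; gap frames do not count). "Any of the window" is the
default; requiring all window frames is available via `window_rule="all"`.
In experiment mode only new landings count — tracks already present in
the first movie frame are excluded from the denominator; control mode
(surface-immobilization experiments) includes them, evaluated over their
first observed frames.

The random-encounter null for a Poisson partner field of density ρ_B is
`P₁ = 1 − exp(−ρ_B π r²)` per frame, and `1 − (1 − P₁)^w` over a
w-frame window. Recovery tests compare the measured co-recruitment
fraction against `f_true + (1 − f_true)·(1 − (1 − P₁)^w)` — the truth of
the *statistic*, since chance encounters are part of what the estimator
measures. Empirical null checks restrict probe positions to the FOV
interior (margin = r), because the closed form assumes a fully covered
colocalization disk, which fails within r of the boundary.

Landing rate is the number of tracks born after the first frame divided
by (area × duration); pass the duration over which new landings could be
observed, i.e. (n_frames − 1)·Δt for a movie analyzed from frame 0. When
the field of view is cropped to its top-left fraction q (the customary
0.75 setting), both axes are scaled, so the retained area is q² — 56.25%
for q = 0.75 — and the cropped metadata feeds per-area statistics
automatically. Crop bounds are half-open: a coordinate exactly on the
boundary is excluded.

## Spot detection and linking

Detection computes the scale-normalized Laplacian-of-Gaussian response
per frame, takes local maxima above an absolute threshold, and refines
each peak by an intensity-weighted center of mass in a
(2·ceil(2σ)+1)² window on the background-subtracted frame (background =
frame median). On noiseless rendered movies at single-molecule density
this localizes isolated spots to better than 0.1 px; overlapping PSFs
(closer than ~2σ) merge and are not deblended — deliberate, since the
analyses operate in regimes where overlaps are rare.

Linking is greedy nearest-neighbor: candidate (track, spot) pairs within
`max_disp` are sorted by (distance, spot index, track index) and accepted
one-to-one; unmatched spots seed tracks; tracks may survive up to
`max_gap` missed frames. Greedy matching equals global minimum-cost
matching whenever assignments are unambiguous, which holds at the
simulated densities; the test suite checks it against exhaustive
minimum-total-distance matching on small crossing configurations. No
motion model (LAP/Kalman) is used.

## Pattern segmentation and patterning index

Per frame: min-max normalization → non-local-means denoising (strength
h = 0.8·σ̂, with σ̂ the wavelet noise estimate; patch size 5, patch
distance 6) → CLAHE (clip limit 0.01) → seeded random walker →
5 iterations of binary closing then opening (3×3 structure, edge-padded
so border-touching regions are not eroded by the boundary condition).

Walker seeds come from intensity quartiles: ≥ P75 seeds the
inside-pattern label, ≤ P25 the outside label, and the middle band is
assigned by the walker (β = 130, a tuning default). Quartile seeding is
deterministic and scale-free — the whole pipeline is invariant to
multiplying a frame by a positive constant — but it presumes the two
domains are roughly area-balanced, which holds for the mutually exclusive
lipid domains being segmented (the synthetic blob geometry covers
~40–55% of the frame for the same reason). Heavily unbalanced patterns
would need user-set seed percentiles, which are exposed as parameters. A
frame whose P25 and P75 coincide has no contrast and raises an error
rather than returning an arbitrary mask.

The patterning index is always computed on **raw** intensities using the
segmentation mask; equalized images exist only for segmentation, because
histogram equalization destroys the intensity ratio the statistic
measures. Frames with an empty region yield NaN flagged invalid, never a
silent drop. Normalized PI divides the series by its mean over a
pre-perturbation baseline window.

## Diffusion statistics

Step sizes are Euclidean displacements between consecutive observed
frames; displacements across linking gaps are excluded. With a region
mask, a step belongs to the region containing its starting spot. The MSD
is time-averaged within each track (displacements between observations
exactly k frames apart), then ensemble-averaged across tracks with equal
weight — the both-averaged convention. `fit_diffusion` fits a line
through the first 4 lags: D = slope/4; the intercept estimates 4σ² of
the static localization error (no motion-blur term is modeled since the
generator does not integrate exposure). Recovery at ~1000 tracks of ≥ 30
frames: D within 5%, intercept within 15%.

## Survival curves and mono-exponential fits

The survival fraction is `S(t) = P(dwell ≥ t)` evaluated at t = 0 and at
every distinct uncensored dwell time — the step function read directly
off disappearance data. Right-censored dwells (molecules alive at movie
end) are excluded from the fraction but reported in `n_censored` so the
user can bound the bias; no Kaplan–Meier correction is applied.

All kinetic fits share one nonlinear least-squares layer (Levenberg–
Marquardt via lmfit): one-phase decay `y = C + A e^(−kt)` or growth
`y = C + A(1 − e^(−kt))`. Starting values unless overridden: C = min(y),
A = range(y), k from a log-linear regression on the early
baseline-subtracted points. Fits are unweighted by default (per-point σ
optional); the offset can be pinned (0 for survival fractions). A
constant input or a non-positive optimal rate yields a result flagged
`degenerate` instead of a fabricated rate; non-convergence raises. Every
reported fit satisfies t½·k = ln 2 identically because t½ is derived,
not fitted. Calibration at 200 points / 2% noise over 100 seeds: median
rate bias < 2%, ±2·SE coverage ≥ 90%. Unweighted LS on survival steps is
slightly biased relative to the exponential MLE (it overweights the
sparse tail); the two agree within 5% at n = 5000 dwells, and ratios of
half-times cancel most of the residual bias.

The dwell-ratio statistic t½(in)/t½(out) propagates the two rate SEs in
quadrature (t½ ∝ 1/k); the propagated SE treats the survival points as
independent, which they are not, so it understates the true uncertainty
— use it for ranking, not inference.

## Wound radial analysis

Pixels are binned by the distance of their centers to the wound center
into half-open annuli [k·w, (k+1)·w); each kymograph column is one frame
of per-annulus means. Annuli beyond pixel coverage are truncated with a
warning. Line scans take the column nearest in time (ties round down).
The in vivo patterning index is the profile peak divided by the mean over
all annuli at least 30 µm from the center — a region, not a single bin.
The wound center is supplied by the user or estimated as the smoothed
frame-0 intensity minimum within an ROI. Radial averaging is rotation
invariant up to resampling error (< 1% for smooth images).

## Mass-action estimators

The 1:1 equilibrium solves `(A_t − x)(B_t − x) = K_D·x` with every output
computed from a cancellation-free quadratic root: the complex via
`x = 2ab/(s + √(s² − 4ab))`, and each free concentration via its own
root rather than `total − x`, which loses precision when K_D ≪ totals
(here K_D/total ≈ 1.5×10⁻⁴). Conservation and the equilibrium relation
hold to 1e−9 relative over randomized parameter sweeps.

Landing-rate extrapolation is linear in the concentration of the *total*
complex pool (the mode that reproduces the printed cellular-rate bound);
scaling in the free species is the user's choice of reference inputs.
Surface coverage uses a circular footprint whose diameter is the maximum
pairwise atom distance of the structure (exact all-pairs to 10⁴ points,
convex-hull reduction above) — faithful to the stated estimation
procedure even though it overestimates the true molecular cross-section.
Where no structure file is supplied, analyses use an effective diameter
of 11.9 nm for the membrane-tethered GEF module, the value consistent
with ~450 molecules µm⁻² covering ~5% of the bilayer. Spike-in density
assumes labeled and unlabeled molecules bind identically.

## Problem sizes

Recovery analyses use ~1000–4000 tracks per condition, 10⁴ frames for
null calibration, 96×96 px pattern movies of 8–20 frames, and 100 seeded
fits for rate calibration — sizes at which every targeted tolerance
(binomial 3 SD, 5% on rates and PI, 15% on MSD intercepts, Dice ≥ 0.95)
is resolvable in seconds to minutes on a single core.

## Known limitations

- No drift correction or image registration; advection-corrected inputs
  are assumed.
- Intensity-based colocalization (Pearson/Manders) and >2-channel logic
  are out of scope.
- The greedy linker is not suited to dense fields; it targets
  single-molecule densities.
- Dwell statistics ignore blinking (a blink longer than `max_gap`
  truncates a track).
- The equilibrium module covers a single 1:1 species pair; no
  competition or cooperativity.
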