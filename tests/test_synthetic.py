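"""Generator contracts: determinism, Poisson landings, dwell statistics, rendering."""

import numpy as np
import pytest
from scipy import stats

from rhopattern.synthetic import (
    PatternConfig,
    SimConfig,
    render_movie,
    simulate_decay_trace,
    simulate_pattern_movie,
    simulate_tracks,
    simulate_wound_movie,
)
from rhopattern.tracks import tracks_from_table


def test_same_seed_is_bit_identical():
    cfg = SimConfig(n_frames=200, seed=77)
    a1, b1, g1 = simulate_tracks(cfg)
    a2, b2, g2 = simulate_tracks(cfg)
    assert a1.spots.equals(a2.spots)
    assert b1.spots.equals(b2.spots)
    assert g1.tracks.equals(g2.tracks)


def test_zero_landing_rate_gives_empty_channel():
    a, b, g = simulate_tracks(SimConfig(landing_rate=0.0, seed=1))
    assert a.n_spots == 0 and b.n_spots == 0 and len(g.tracks) == 0


def test_forced_pairing_puts_partner_on_every_frame():
    cfg = SimConfig(
        n_frames=300,
        colabel_fraction=1.0,
        partner_bleach_rate=0.0,
        landing_rate=0.05,
        seed=2,
    )
    a, b, _ = simulate_tracks(cfg)
    assert a.n_spots > 0
    merged = a.spots.merge(b.spots, on=["track_id", "frame"], suffixes=("_a", "_b"))
    assert len(merged) == a.n_spots  # B present wherever A is
    d = np.hypot(merged.x_a - merged.x_b, merged.y_a - merged.y_b)
    # two independent localization draws of SD sigma per axis
    assert d.max() < 10 * cfg.localization_sigma


def test_landing_count_is_poisson_with_rate_area_duration():
    # lambda * A * T = 0.02 * 100 * 50 = 100 expected tracks
    n_frames = int(round(50.0 / 0.022))
    cfg = SimConfig(
        fov_width=10, fov_height=10, landing_rate=0.02, n_frames=n_frames, seed=3
    )
    _, _, g = simulate_tracks(cfg)
    expected = cfg.landing_rate * cfg.area * cfg.duration
    assert abs(len(g.tracks) - expected) <= 3 * np.sqrt(expected)


def test_landing_counts_mean_matches_variance():
    counts = [
        len(simulate_tracks(SimConfig(n_frames=100, landing_rate=0.5, seed=s))[2].tracks)
        for s in range(200)
    ]
    counts = np.array(counts)
    assert abs(counts.var() / counts.mean() - 1.0) < 0.25  # Fano factor ~ 1


def test_dwell_times_are_exponential():
    cfg = SimConfig(
        fov_width=40,
        fov_height=40,
        n_frames=400,
        landing_rate=0.9,
        dissociation_rate=2.0,
        colabel_fraction=0,
        seed=4,
    )
    _, _, g = simulate_tracks(cfg)
    dwells = g.tracks.true_dwell_time.to_numpy()
    assert len(dwells) >= 5000
    res = stats.kstest(dwells[:5000], "expon", args=(0, 1 / cfg.dissociation_rate))
    assert res.pvalue > 0.01


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(landing_rate=-1)
    with pytest.raises(ValueError):
        SimConfig(colabel_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(diffusion_coeff=float("nan"))


def test_render_empty_table_is_pure_background():
    a, _, _ = simulate_tracks(SimConfig(landing_rate=0.0, seed=1))
    stack = render_movie(a, psf_sigma=0.15, background=42.0, n_frames=3)
    assert np.all(stack == 42.0)


def test_render_single_spot_peak_and_integral():
    import pandas as pd

    from rhopattern.tracks import SpotTable

    tab = SpotTable(
        pd.DataFrame({"frame": [0], "x": [5.05], "y": [5.05], "intensity": [1.0]}),
        pixel_size=0.1,
        frame_interval=0.022,
        fov_width=10,
        fov_height=10,
    )
    psf, amp, bg = 0.15, 1000.0, 100.0
    stack = render_movie(tab, psf_sigma=psf, background=bg, amplitude=amp, noise_sd=0)
    i, j = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
    assert (i, j) == (50, 50)  # spot at pixel-center (50, 50)
    total = (stack[0] - bg).sum()
    expected = amp * 2 * np.pi * (psf / 0.1) ** 2  # Gaussian integral in px²
    assert total == pytest.approx(expected, rel=0.01)


def test_render_rejects_bad_psf():
    a, _, _ = simulate_tracks(SimConfig(landing_rate=0.0, seed=1))
    with pytest.raises(ValueError):
        render_movie(a, psf_sigma=0.0)


def test_pattern_contrast_exact_without_noise():
    pc = PatternConfig(contrast_ratio=2.0, channel_pi_true=(1.0,), noise_sd=0.0)
    stacks, gt = simulate_pattern_movie(pc, shape=(64, 64), n_frames=2)
    m = gt.mask[0]
    lipid = stacks["lipid"][0]
    assert lipid[m].mean() / lipid[~m].mean() == pytest.approx(2.0)
    rep = stacks["reporter_0"][0]
    assert rep[m].mean() == pytest.approx(rep[~m].mean())  # PI_true = 1: uniform


def test_pattern_mask_shape_matches_movie():
    stacks, gt = simulate_pattern_movie(PatternConfig(), shape=(48, 32), n_frames=4)
    assert gt.mask.shape == stacks["lipid"].shape == (4, 48, 32)


def test_pattern_rejects_unknown_geometry():
    with pytest.raises(ValueError):
        PatternConfig(geometry="stripes")


def test_decay_trace_known_values():
    t, y = simulate_decay_trace(1.0, 0.0, 0.5, 1.0, 10, mode="decay")
    assert np.allclose(y, 1.5)  # k=0: constant A + C
    t, y = simulate_decay_trace(1.0, 0.01, 0.0, 69.3, 2, mode="decay")
    assert y[1] == pytest.approx(0.5, abs=1e-3)  # half-time ln2/k = 69.3 s
    t, y = simulate_decay_trace(2.0, 0.5, 1.0, 10.0, 200, mode="growth")
    assert y[-1] == pytest.approx(3.0, abs=1e-6)  # growth asymptote A + C


def test_wound_movie_flat_without_amplitude():
    stack = simulate_wound_movie(
        (64, 64), (31.5, 31.5), 5.0, 2.0, amplitude=0.0, background=7.0, n_frames=2
    )
    assert np.all(stack == 7.0)
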