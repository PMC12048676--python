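"""Colocalization rules, co-recruitment fractions and the random-encounter null."""

import numpy as np
import pytest

from rhopattern.colocalization import (
    ColocConfig,
    EmptyDenominatorError,
    chance_colocalization,
    classify_co_recruitment,
    co_recruitment_fraction,
    colocalization_probability_by_position,
    frame_colocalized,
    landing_rate,
)
from rhopattern.synthetic import SimConfig, scatter_spots, simulate_tracks
from rhopattern.tracks import Track, tracks_from_table


def test_threshold_is_inclusive_at_half_micron():
    b = np.array([[1.5, 1.0]])
    assert frame_colocalized(1.0, 1.0, b, 0.5) == 0  # exactly 0.5 µm counts
    assert frame_colocalized(1.01, 1.0, b, 0.5) == 0  # 0.49 µm
    assert frame_colocalized(0.99, 1.0, b, 0.5) is None  # 0.51 µm


def test_nearest_candidate_wins():
    b = np.array([[1.4, 1.0], [1.2, 1.0]])  # 0.4 and 0.2 µm away
    assert frame_colocalized(1.0, 1.0, b, 0.5) == 1


def test_track_born_in_first_frame_excluded_in_experiment_mode():
    tr = Track(0, frames=[0, 1, 2], x=[1, 1, 1], y=[1, 1, 1])
    eligible, _ = classify_co_recruitment(tr, {}, ColocConfig(mode="experiment"))
    assert not eligible
    eligible, _ = classify_co_recruitment(tr, {}, ColocConfig(mode="control"))
    assert eligible


def test_partner_in_any_window_frame_is_enough():
    # B present only at the birth frame, gone before frame 1 (fast bleach)
    tr = Track(0, frames=[5, 6, 7, 8], x=[1, 1, 1, 1], y=[1, 1, 1, 1])
    b = {5: np.array([[1.1, 1.0]])}
    _, co = classify_co_recruitment(tr, b, ColocConfig(window=3))
    assert co
    _, co_all = classify_co_recruitment(tr, b, ColocConfig(window=3, window_rule="all"))
    assert not co_all


def test_control_mode_counts_each_first_frame_track_once():
    cfg = SimConfig(n_frames=6, landing_rate=20.0, colabel_fraction=0, seed=9)
    a, b, gt = simulate_tracks(cfg)
    tracks = tracks_from_table(a)
    n_frame0 = int((gt.tracks.birth_frame == 0).sum())
    assert n_frame0 > 0
    summary = co_recruitment_fraction(tracks, b, ColocConfig(mode="control"))
    assert summary.n_tracks == len(tracks)  # frame-0 tracks included exactly once
    exp = co_recruitment_fraction(tracks, b, ColocConfig(mode="experiment"))
    assert exp.n_tracks == len(tracks) - n_frame0


def test_empty_denominator_raises():
    tr = Track(0, frames=[0], x=[1], y=[1])
    b, _, _ = simulate_tracks(SimConfig(landing_rate=0, seed=1))
    with pytest.raises(EmptyDenominatorError):
        co_recruitment_fraction([tr], b, ColocConfig(mode="experiment"))


def test_disjoint_channels_give_zero_fraction():
    cfg = SimConfig(n_frames=2000, landing_rate=0.05, colabel_fraction=0, seed=10)
    a, b, _ = simulate_tracks(cfg)  # colabel 0 -> B channel empty
    s = co_recruitment_fraction(tracks_from_table(a), b, ColocConfig())
    assert s.fraction == 0.0


def test_corecruitment_recovers_generator_truth():
    cfg = SimConfig(
        fov_width=10, fov_height=10, n_frames=8000,
        landing_rate=0.02, colabel_fraction=0.63, seed=11,
    )
    a, b, gt = simulate_tracks(cfg)
    s = co_recruitment_fraction(tracks_from_table(a), b, ColocConfig())
    realized = gt.tracks.loc[gt.tracks.birth_frame > 0, "colabeled"].mean()
    # estimator >= per-track truth; surplus only from random encounters
    rho_b = b.n_spots / cfg.n_frames / a.area
    p_win = 1 - (1 - chance_colocalization(rho_b, 0.5)) ** 3
    assert s.fraction >= realized - 1e-12
    assert s.fraction - realized <= (1 - realized) * p_win + 3 * np.sqrt(
        p_win / s.n_tracks
    )


def test_all_colabeled_gives_fraction_one():
    cfg = SimConfig(
        n_frames=3000, landing_rate=0.02, colabel_fraction=1.0,
        partner_bleach_rate=0.0, seed=12,
    )
    a, b, _ = simulate_tracks(cfg)
    s = co_recruitment_fraction(tracks_from_table(a), b, ColocConfig())
    assert s.fraction == 1.0


def test_landing_rate_arithmetic_and_recovery():
    # 100 new tracks over 100 µm² and 50 s -> 0.02 s⁻¹µm⁻²
    tracks = [Track(i, frames=[1, 2], x=[1, 1], y=[1, 1]) for i in range(100)]
    assert landing_rate(tracks, 100.0, 50.0) == pytest.approx(0.02)
    assert landing_rate([], 100.0, 50.0) == 0.0
    cfg = SimConfig(n_frames=9000, landing_rate=0.05, colabel_fraction=0, seed=13)
    a, _, _ = simulate_tracks(cfg)
    tr = tracks_from_table(a)
    dur = (cfg.n_frames - 1) * cfg.frame_interval
    est = landing_rate(tr, a.area, dur)
    n = sum(1 for t in tr if t.birth_frame > 0)
    assert abs(est - 0.05) <= 3 * np.sqrt(n) / (a.area * dur)


def test_position_profile_decays_with_partner_bleaching():
    cfg = SimConfig(
        fov_width=15, fov_height=15, n_frames=4000, landing_rate=0.04,
        colabel_fraction=1.0, partner_bleach_rate=8.0, dissociation_rate=0.3, seed=14,
    )
    a, b, _ = simulate_tracks(cfg)
    prof = colocalization_probability_by_position(
        tracks_from_table(a), b, ColocConfig(), max_offset=6
    )
    p = prof.probability.to_numpy()
    assert p[0] == pytest.approx(1.0)  # partner always present at recruitment
    assert np.all(np.diff(p[:5]) < 0)  # monotone decay over first offsets
    assert np.all(np.diff(prof.n_at_offset.to_numpy()) <= 0)


def test_position_profile_flat_for_independent_channels():
    cfg = SimConfig(
        fov_width=20, fov_height=20, n_frames=3000, landing_rate=0.03,
        colabel_fraction=0.0, dissociation_rate=0.3, seed=15,
    )
    a, _, _ = simulate_tracks(cfg)
    rho = 0.15
    b = scatter_spots(
        rho, cfg.n_frames, fov_width=20, fov_height=20,
        rng=np.random.default_rng(16),
    )
    prof = colocalization_probability_by_position(
        tracks_from_table(a), b, ColocConfig(), max_offset=5
    )
    p_null = chance_colocalization(rho, 0.5)
    for row in prof.itertuples():
        sd = max(np.sqrt(p_null * (1 - p_null) / row.n_at_offset), 1e-9)
        assert abs(row.probability - p_null) < 4 * sd + 0.1 * p_null  # edge effects


def test_profile_empty_beyond_longest_track():
    tr = [Track(0, frames=[1, 2], x=[1, 1], y=[1, 1])]
    b, _, _ = simulate_tracks(SimConfig(landing_rate=0, seed=1))
    prof = colocalization_probability_by_position(tr, b, ColocConfig())
    assert list(prof.frame_offset) == [0, 1]  # offset 2 absent, not zero


def test_chance_colocalization_closed_form():
    assert chance_colocalization(0.0, 0.5) == 0.0
    assert chance_colocalization(1.0, 0.5) == pytest.approx(
        1 - np.exp(-np.pi / 4)
    )  # ≈ 0.544
    assert chance_colocalization(1.0, 1e-9) == pytest.approx(0.0, abs=1e-12)
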