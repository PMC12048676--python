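"""Spot detection, greedy linking (vs exhaustive oracle), FOV crop and CSV dialect."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from rhopattern.synthetic import SimConfig, render_movie, simulate_tracks
from rhopattern.tracks import (
    SchemaError,
    SpotTable,
    crop_fov,
    detect_spots,
    link_tracks,
    read_spot_csv,
    tracks_from_table,
    write_spot_csv,
)

META = dict(pixel_size=0.1, frame_interval=0.022, fov_width=10.0, fov_height=10.0)


def make_table(rows):
    return SpotTable(
        pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"]), **META
    )


# ---------------------------------------------------------------- detection


def test_blank_stack_yields_no_spots():
    det = detect_spots(np.full((2, 50, 50), 100.0), 1.5, 10, pixel_size=0.1, frame_interval=0.022)
    assert det.n_spots == 0


def test_detect_rejects_bad_sigma():
    with pytest.raises(ValueError):
        detect_spots(np.zeros((1, 10, 10)), 0.0, 1, pixel_size=0.1, frame_interval=0.022)


def test_single_noiseless_spot_localized_within_tenth_pixel():
    for true_x, true_y in [(5.05, 5.05), (4.98, 5.11), (5.031, 4.973)]:
        tab = make_table([{"frame": 0, "x": true_x, "y": true_y, "intensity": 1.0}])
        stack = render_movie(tab, psf_sigma=0.15, noise_sd=0)
        det = detect_spots(stack, 1.5, 50, pixel_size=0.1, frame_interval=0.022)
        assert det.n_spots == 1
        err_px = np.hypot(det.spots.x[0] - true_x, det.spots.y[0] - true_y) / 0.1
        assert err_px < 0.1


def test_two_separated_spots_detected_as_two():
    tab = make_table(
        [
            {"frame": 0, "x": 3.05, "y": 5.05, "intensity": 1.0},
            {"frame": 0, "x": 4.05, "y": 5.05, "intensity": 1.0},  # 10 px apart
        ]
    )
    stack = render_movie(tab, psf_sigma=0.15, noise_sd=0)
    det = detect_spots(stack, 1.5, 50, pixel_size=0.1, frame_interval=0.022)
    assert det.n_spots == 2


def test_detect_render_round_trip_recovers_nearly_all_spots():
    """Noiseless movie at single-molecule density: >=99% recovery, <0.1 px error."""
    cfg = SimConfig(
        fov_width=15, fov_height=15, n_frames=60, landing_rate=0.02,
        localization_sigma=0.0, colabel_fraction=0, seed=8,
    )
    a, _, _ = simulate_tracks(cfg)
    stack = render_movie(a, psf_sigma=0.15, background=100, noise_sd=0, n_frames=60)
    det = detect_spots(stack, 1.5, 50, pixel_size=0.1, frame_interval=0.022)
    margin = 0.5  # PSFs clipped at the border localize worse by construction
    inner = a.spots[
        a.spots.x.between(margin, 15 - margin) & a.spots.y.between(margin, 15 - margin)
    ]
    found = 0
    for f, grp in inner.groupby("frame"):
        dd = det.spots[det.spots.frame == f]
        if len(dd) == 0:
            continue
        d, _ = cKDTree(dd[["x", "y"]].to_numpy()).query(grp[["x", "y"]].to_numpy())
        found += int((d < 0.1 * 0.1).sum())
    assert found / len(inner) >= 0.99


# ---------------------------------------------------------------- linking


def test_two_stationary_spots_make_two_full_tracks():
    rows = []
    for f in range(10):
        rows.append({"frame": f, "x": 1.0, "y": 1.0, "intensity": 1.0})
        rows.append({"frame": f, "x": 8.0, "y": 8.0, "intensity": 1.0})
    tracks = link_tracks(make_table(rows), max_disp=0.5)
    assert len(tracks) == 2
    assert all(len(t) == 10 for t in tracks)


def test_gap_closing_resumes_track():
    rows = [{"frame": f, "x": 2.0, "y": 2.0, "intensity": 1.0} for f in (0, 1, 4, 5)]
    assert len(link_tracks(make_table(rows), max_disp=0.5, max_gap=2)) == 1
    assert len(link_tracks(make_table(rows), max_disp=0.5, max_gap=1)) == 2


def test_no_spot_assigned_twice_in_one_frame():
    rng = np.random.default_rng(0)
    rows = [
        {"frame": f, "x": x, "y": y, "intensity": 1.0}
        for f in range(20)
        for x, y in rng.uniform(0, 10, size=(30, 2))
    ]
    tracks = link_tracks(make_table(rows), max_disp=1.0)
    seen = set()
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            key = (int(f), float(x), float(y))
            assert key not in seen
            seen.add(key)
    assert len(seen) == 20 * 30


def _brute_force_assignment(prev, cur, max_disp):
    """Minimal-total-distance one-to-one matching (exhaustive, <=4 spots)."""
    best, best_cost = None, np.inf
    n, m = len(prev), len(cur)
    for k in range(min(n, m), -1, -1):
        for prev_idx in itertools.permutations(range(n), k):
            for cur_idx in itertools.combinations(range(m), k):
                d = [
                    np.hypot(*(np.array(prev[i]) - np.array(cur[j])))
                    for i, j in zip(prev_idx, cur_idx)
                ]
                if any(x > max_disp for x in d):
                    continue
                if sum(d) < best_cost and k == min(n, m):
                    best_cost, best = sum(d), dict(zip(prev_idx, cur_idx))
        if best is not None:
            break
    return best or {}


def test_crossing_pair_matches_exhaustive_assignment():
    # two molecules approaching and passing; greedy must match min-cost matching
    frames = []
    for f in range(6):
        frames.append([(1.0 + 0.3 * f, 2.0), (3.0 - 0.3 * f, 2.2)])
    rows = [
        {"frame": f, "x": x, "y": y, "intensity": 1.0}
        for f, pts in enumerate(frames)
        for x, y in pts
    ]
    tracks = link_tracks(make_table(rows), max_disp=0.6)
    assert len(tracks) == 2
    # replay brute force
    expected = {0: [frames[0][0]], 1: [frames[0][1]]}
    for f in range(1, 6):
        prev = [expected[0][-1], expected[1][-1]]
        match = _brute_force_assignment(prev, frames[f], 0.6)
        for tid in (0, 1):
            expected[tid].append(frames[f][match[tid]])
    got = sorted([list(zip(t.x, t.y)) for t in tracks])
    want = sorted([expected[0], expected[1]])
    assert np.allclose(np.array(got, dtype=float), np.array(want, dtype=float))


# ---------------------------------------------------------------- crop


def test_crop_identity_and_idempotence():
    rng = np.random.default_rng(1)
    rows = [
        {"frame": 0, "x": x, "y": y, "intensity": 1.0}
        for x, y in rng.uniform(0, 10, size=(500, 2))
    ]
    tab = make_table(rows)
    assert crop_fov(tab, 1.0).n_spots == tab.n_spots
    once = crop_fov(tab, 0.75)
    twice = crop_fov(crop_fov(tab, 0.75), 1.0)
    assert once.spots.equals(twice.spots)
    assert once.fov_width == pytest.approx(7.5)


def test_crop_retains_area_fraction_of_uniform_spots():
    rng = np.random.default_rng(2)
    n = 4000
    rows = [
        {"frame": 0, "x": x, "y": y, "intensity": 1.0}
        for x, y in rng.uniform(0, 10, size=(n, 2))
    ]
    kept = crop_fov(make_table(rows), 0.75).n_spots / n
    p = 0.75**2  # both axes scaled: area fraction 0.5625
    assert abs(kept - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_crop_boundary_spot_excluded():
    tab = make_table([{"frame": 0, "x": 7.5, "y": 3.0, "intensity": 1.0}])
    assert crop_fov(tab, 0.75).n_spots == 0  # exactly on boundary: half-open


def test_crop_rejects_bad_fraction():
    tab = make_table([])
    for bad in (0.0, -0.1, 1.2):
        with pytest.raises(ValueError):
            crop_fov(tab, bad)


# ---------------------------------------------------------------- CSV dialect


def test_csv_round_trip_lossless(tmp_path):
    a, _, _ = simulate_tracks(SimConfig(n_frames=100, landing_rate=0.1, seed=5))
    path = tmp_path / "spots.csv"
    write_spot_csv(a, path)
    back = read_spot_csv(path, fov_width=10, fov_height=10)
    for col in ("frame", "x", "y", "track_id"):
        assert np.allclose(back.spots[col], a.spots[col])


def test_trackmate_style_extra_header_rows_skipped(tmp_path):
    path = tmp_path / "tm.csv"
    path.write_text(
        "LABEL,ID,TRACK_ID,POSITION_X,POSITION_Y,FRAME,QUALITY\n"
        "Label,Spot ID,Track ID,X,Y,Frame,Quality\n"
        "Label,Spot ID,Track ID,(micron),(micron),Frame,(quality)\n"
        ",,,,,,\n"
        "ID1,1,0,1.5,2.5,0,100\n"
        "ID2,2,0,1.6,2.4,1,90\n"
    )
    tab = read_spot_csv(path)
    assert tab.n_spots == 2
    assert list(tab.spots.frame) == [0, 1]
    assert tab.spots.x.iloc[0] == pytest.approx(1.5)


def test_missing_column_raises_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("TRACK_ID,POSITION_X,FRAME\n0,1.0,0\n")
    with pytest.raises(SchemaError, match="POSITION_Y"):
        read_spot_csv(path)


def test_tracks_from_table_orders_frames():
    a, _, _ = simulate_tracks(SimConfig(n_frames=50, landing_rate=0.2, seed=6))
    for t in tracks_from_table(a):
        assert np.all(np.diff(t.frames) > 0)
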