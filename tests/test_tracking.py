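"""Linker: predictive assignment, conservation, determinism."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from nuctrack.tracking import LinkerParams, link_movie, track_table


def make_objects(paths: dict[int, np.ndarray]) -> pd.DataFrame:
    """Build an object table from {identity: (n_frames, 2) positions}."""
    rows = []
    oid = 0
    n_frames = max(len(p) for p in paths.values())
    for t in range(n_frames):
        for k in sorted(paths):
            p = paths[k]
            if t < len(p):
                rows.append((oid, t, p[t, 0], p[t, 1], k))
                oid += 1
    return pd.DataFrame(rows, columns=["object_id", "frame", "x_um", "y_um", "true_id"])


def brute_force_nearest_linker(objects: pd.DataFrame, max_dist: float):
    """Independent oracle: per frame pair, enumerate all one-to-one
    assignments of previous positions to current objects and keep the one
    with minimal summed distance (links beyond max_dist forbidden)."""
    frames = sorted(objects["frame"].unique())
    prev = objects[objects["frame"] == frames[0]].copy()
    assignment = {int(r.object_id): int(r.object_id) for r in prev.itertuples()}
    for f0, f1 in zip(frames[:-1], frames[1:]):
        cur = objects[objects["frame"] == f1]
        p_xy = prev[["x_um", "y_um"]].to_numpy()
        c_xy = cur[["x_um", "y_um"]].to_numpy()
        n, m = len(p_xy), len(c_xy)
        best, best_cost = None, np.inf
        for perm in permutations(range(m), min(n, m)):
            cost, ok = 0.0, True
            for i, j in enumerate(perm[:n]):
                d = np.linalg.norm(p_xy[i] - c_xy[j])
                if d > max_dist:
                    ok = False
                    break
                cost += d
            if ok and cost < best_cost:
                best, best_cost = perm, cost
        assert best is not None
        p_ids = prev["object_id"].to_numpy()
        c_ids = cur["object_id"].to_numpy()
        for i, j in enumerate(best[: len(p_ids)]):
            assignment[int(c_ids[j])] = assignment[int(p_ids[i])]
        prev = cur
    return assignment  # object_id -> root object id of its chain


class TestLinkMovie:
    def test_parallel_lines_two_full_tracks(self):
        t = np.arange(100, dtype=float)
        paths = {
            0: np.column_stack([2 * t, np.zeros(100)]),
            1: np.column_stack([2 * t, np.full(100, 50.0)]),
        }
        result = link_movie(make_objects(paths))
        assert len(result.tracks) == 2
        assert all(tr.n_frames == 100 for tr in result.tracks)
        assert not result.discarded

    def test_momentum_preserves_identity_through_crossing(self):
        # head-on passage: at the crossing frame nearest-neighbor distances
        # nearly tie, but the AR prediction separates the hypotheses
        t = np.arange(21, dtype=float)
        a = np.column_stack([2 * t, np.full(21, 0.4)])
        b = np.column_stack([40.0 - 2 * t, np.full(21, -0.4)])
        objects = make_objects({0: a, 1: b})
        params = LinkerParams(max_link_distance_um=10.0, momentum=0.9,
                              min_track_frames=5)
        result = link_movie(objects, params)
        assert len(result.tracks) == 2
        for tr in result.tracks:
            assert tr.objects["true_id"].nunique() == 1
            assert tr.n_frames == 21

        # brute-force check on the crossing frame: the true continuation
        # has lower predictive cost than the swap
        t_cross = 10
        prev_a, prev_b = a[t_cross - 1], b[t_cross - 1]
        pred_a = prev_a + 0.9 * (a[t_cross - 1] - a[t_cross - 2])
        pred_b = prev_b + 0.9 * (b[t_cross - 1] - b[t_cross - 2])
        true_cost = np.linalg.norm(pred_a - a[t_cross]) + np.linalg.norm(
            pred_b - b[t_cross]
        )
        swap_cost = np.linalg.norm(pred_a - b[t_cross]) + np.linalg.norm(
            pred_b - a[t_cross]
        )
        assert true_cost < swap_cost

    def test_zero_momentum_equals_nearest_assignment_oracle(self):
        rng = np.random.default_rng(12)
        paths = {
            k: np.cumsum(rng.normal(0, 2.0, size=(15, 2)), axis=0)
            + rng.uniform(0, 100, size=2)
            for k in range(5)
        }
        objects = make_objects(paths)
        params = LinkerParams(max_link_distance_um=1e6, momentum=0.0,
                              min_track_frames=1)
        result = link_movie(objects, params)
        oracle = brute_force_nearest_linker(objects, 1e6)
        ours = {}
        for tr in result.tracks:
            root = int(tr.objects["object_id"].iloc[0])
            for oid in tr.objects["object_id"]:
                ours[int(oid)] = root
        assert ours == oracle

    def test_conservation_of_objects(self, small_rendered):
        from nuctrack.segmentation import Movie, segment_movie

        cfg, _, frames = small_rendered
        objects = segment_movie(Movie(frames, cfg.pixel_size_um, cfg.frame_interval_min))
        result = link_movie(objects, LinkerParams(min_track_frames=8))
        assert result.n_objects == len(objects)
        all_ids = sorted(
            int(i)
            for tr in result.tracks + result.discarded
            for i in tr.objects["object_id"]
        )
        assert all_ids == sorted(objects["object_id"])

    def test_track_count_monotone_in_gate(self):
        rng = np.random.default_rng(3)
        paths = {
            k: np.cumsum(rng.normal(0, 3.0, size=(20, 2)), axis=0)
            + rng.uniform(0, 200, size=2)
            for k in range(8)
        }
        objects = make_objects(paths)
        counts = []
        for gate in (2.0, 5.0, 10.0, 50.0):
            res = link_movie(objects, LinkerParams(gate, 0.0, 0, 1))
            counts.append(len(res.tracks) + len(res.discarded))
        assert counts == sorted(counts, reverse=True)

    def test_gap_bridging_and_gap_record(self):
        t = np.arange(30, dtype=float)
        path = np.column_stack([3 * t, np.zeros(30)])
        objects = make_objects({0: path})
        objects = objects[objects["frame"] != 14]  # one missed detection
        result = link_movie(objects, LinkerParams(max_link_distance_um=20.0))
        assert len(result.tracks) == 1
        assert result.tracks[0].gaps == [14]
        assert result.tracks[0].n_frames == 29

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {"object_id": [0, 0], "frame": [0, 1], "x_um": [0.0, 1.0], "y_um": [0, 0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            link_movie(df)

    def test_empty_input(self):
        res = link_movie(pd.DataFrame(columns=["object_id", "frame", "x_um", "y_um"]))
        assert res.tracks == [] and res.discarded == []


class TestTrackTable:
    def test_row_count_and_gap_rows_absent(self):
        t = np.arange(100, dtype=float)
        paths = {
            0: np.column_stack([t, np.zeros(100)]),
            1: np.column_stack([t, np.full(100, 30.0)]),
        }
        objects = make_objects(paths)
        objects = objects[~((objects["frame"] == 50) & (objects["y_um"] == 0.0))]
        result = link_movie(objects, LinkerParams(max_link_distance_um=5.0))
        table = track_table(result.tracks)
        assert len(table) == 199
        gappy = table.groupby("track_id")["frame"].count().min()
        assert gappy == 99

    def test_csv_round_trip_precision(self, tmp_path):
        from nuctrack.io import read_table, write_table

        t = np.arange(12, dtype=float)
        path = np.column_stack([t * np.pi / 3, t * np.e / 7])
        objects = make_objects({0: path})
        result = link_movie(objects, LinkerParams(min_track_frames=1))
        table = track_table(result.tracks)
        write_table(tmp_path / "t.csv", table)
        back = read_table(tmp_path / "t.csv")
        assert back["track_id"].equals(table["track_id"])
        assert back["frame"].equals(table["frame"])
        np.testing.assert_allclose(back["x_um"], table["x_um"], rtol=1e-9)
        np.testing.assert_allclose(back["y_um"], table["y_um"], rtol=1e-9)
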