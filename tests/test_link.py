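"""Gap-tolerant linking and merging: greedy matching semantics checked
against an exhaustive oracle, and conservation laws."""

import itertools

import numpy as np
import pytest

import smlmkit as sk
from smlmkit.link import LinkParams, link_localizations, merge_linked


def make_table(rows):
    """rows: (frame, x, y[, intensity])"""
    rows = [r if len(r) == 4 else (*r, 1000.0) for r in rows]
    f, x, y, i = zip(*rows)
    return sk.LocalizationTable.from_arrays(f, x, y, i)


def greedy_link_oracle(rows, max_jump, max_gap):
    """Literal re-implementation of the documented linking rule on plain
    tuples: per target frame, per gap (smaller gaps first), match heads to
    unclaimed localizations in globally ascending distance order with ties
    broken by (head row, candidate row)."""
    n = len(rows)
    track = [-1] * n
    head_row = {}  # track id -> row
    next_id = 0
    frames = sorted({r[0] for r in rows})
    for t in frames:
        targets = [i for i in range(n) if rows[i][0] == t]
        unclaimed = set(targets)
        for gap in range(max_gap + 1):
            s = t - 1 - gap
            if s < 0 or not unclaimed:
                break
            heads = [i for i in range(n)
                     if rows[i][0] == s and track[i] != -1 and head_row.get(track[i]) == i]
            pairs = []
            for hr in heads:
                for cr in unclaimed:
                    d = np.hypot(rows[hr][1] - rows[cr][1], rows[hr][2] - rows[cr][2])
                    if d <= max_jump:
                        pairs.append((d, hr, cr))
            used = set()
            for d, hr, cr in sorted(pairs):
                if hr in used or cr not in unclaimed:
                    continue
                track[cr] = track[hr]
                head_row[track[hr]] = cr
                used.add(hr)
                unclaimed.discard(cr)
        for r in sorted(unclaimed):
            track[r] = next_id
            head_row[next_id] = r
            next_id += 1
    return track


def test_simple_pair_linked():
    t = make_table([(0, 0.0, 0.0), (1, 0.1, 0.0)])
    out = link_localizations(t, LinkParams(0.5, 0))
    assert out.df["track_id"].tolist() == [0, 0]


def test_gap_semantics():
    t = make_table([(0, 0.0, 0.0), (2, 0.1, 0.0)])
    linked = link_localizations(t, LinkParams(0.5, 1))
    assert linked.df["track_id"].nunique() == 1
    unlinked = link_localizations(t, LinkParams(0.5, 0))
    assert unlinked.df["track_id"].tolist() == [0, 1]


def test_gap_priority_next_frame_first():
    # head at frame 0 must take the frame-1 candidate even though the
    # frame-2 one is closer
    t = make_table([(0, 0.0, 0.0), (1, 0.3, 0.0), (2, 0.05, 0.0)])
    out = link_localizations(t, LinkParams(0.5, 1))
    # 0-1 linked first; then the track head (row 1) links to row 2
    assert out.df["track_id"].tolist() == [0, 0, 0]


def test_crossing_pair_matches_oracle():
    rows = [(0, 0.0, 0.0), (0, 1.0, 0.0), (1, 0.1, 0.0), (1, 0.0, 0.12)]
    t = make_table(rows)
    out = link_localizations(t, LinkParams(2.0, 0))
    assert out.df["track_id"].tolist() == greedy_link_oracle(rows, 2.0, 0)


@pytest.mark.parametrize("trial", range(12))
def test_random_instances_match_oracle(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(3, 7))
    rows = [(int(rng.integers(0, 4)), float(rng.uniform(0, 3)), float(rng.uniform(0, 3)))
            for _ in range(n)]
    rows.sort(key=lambda r: r[0])
    max_jump = float(rng.uniform(0.5, 2.5))
    max_gap = int(rng.integers(0, 3))
    t = make_table(rows)
    out = link_localizations(t, LinkParams(max_jump, max_gap))
    assert out.df["track_id"].tolist() == greedy_link_oracle(rows, max_jump, max_gap)


def test_unsorted_input_rejected_or_sorted():
    t = make_table([(1, 0.0, 0.0), (0, 0.1, 0.0)])
    with pytest.raises(ValueError, match="sorted"):
        link_localizations(t, LinkParams(0.5, 0))
    with pytest.warns(UserWarning):
        out = link_localizations(t, LinkParams(0.5, 0), auto_sort=True)
    assert out.df["track_id"].nunique() == 1


def test_determinism():
    rng = np.random.default_rng(5)
    rows = [(int(f), float(x), float(y)) for f, x, y in
            zip(np.sort(rng.integers(0, 10, 40)), rng.uniform(0, 5, 40), rng.uniform(0, 5, 40))]
    t = make_table(rows)
    a = link_localizations(t, LinkParams(1.0, 1)).df["track_id"]
    b = link_localizations(t, LinkParams(1.0, 1)).df["track_id"]
    assert a.tolist() == b.tolist()


class TestMerge:
    def test_weighted_mean_min_frame_summed_intensity(self):
        t = make_table([(1, 0.0, 0.0, 100.0), (2, 0.2, 0.0, 300.0)])
        linked = link_localizations(t, LinkParams(0.5, 0))
        merged = merge_linked(linked)
        assert len(merged) == 1
        row = merged.df.iloc[0]
        assert row["frame"] == 1
        assert row["x"] == pytest.approx(0.15)
        assert row["intensity"] == pytest.approx(400.0)

    def test_singleton_unchanged(self):
        t = make_table([(0, 1.5, 2.5, 777.0)])
        linked = link_localizations(t, LinkParams(0.5, 0))
        merged = merge_linked(linked)
        assert len(merged) == 1
        assert merged.df.iloc[0]["x"] == 1.5
        assert merged.df.iloc[0]["intensity"] == 777.0

    def test_intensity_conservation_and_row_count(self, rng):
        rows = [(int(f), float(x), float(y), float(i)) for f, x, y, i in zip(
            np.sort(rng.integers(0, 20, 100)), rng.uniform(0, 10, 100),
            rng.uniform(0, 10, 100), rng.uniform(100, 1000, 100))]
        t = make_table(rows)
        linked = link_localizations(t, LinkParams(0.8, 2))
        merged = merge_linked(linked)
        assert merged.df["intensity"].sum() == pytest.approx(t.df["intensity"].sum())
        assert len(merged) == linked.df["track_id"].nunique()

    def test_tiny_max_jump_merging_is_identity(self, rng):
        rows = [(int(f), float(x), float(y)) for f, x, y in zip(
            range(30), rng.uniform(0, 10, 30), rng.uniform(0, 10, 30))]
        t = make_table(rows)
        linked = link_localizations(t, LinkParams(1e-9, 0))
        merged = merge_linked(linked)
        assert len(merged) == len(t)
        np.testing.assert_allclose(np.sort(merged.df["x"]), np.sort(t.df["x"]))

    def test_excluded_ids_pass_through(self):
        t = make_table([(0, 0.0, 0.0, 10.0), (1, 0.1, 0.0, 20.0),
                        (0, 5.0, 5.0, 9e5), (1, 5.0, 5.0, 9e5)])
        linked = link_localizations(t.sorted_by_frame(), LinkParams(0.5, 0))
        fid_id = linked.df.loc[linked.df["intensity"] > 1e5, "track_id"].iloc[0]
        merged = merge_linked(linked, exclude_ids={int(fid_id)})
        assert (merged.df["track_id"] == fid_id).sum() == 2  # untouched
        assert len(merged) == 3

    def test_zero_intensity_track_warns_unweighted_mean(self):
        t = make_table([(0, 0.0, 0.0, 0.0), (1, 1.0, 0.0, 0.0)])
        linked = link_localizations(t, LinkParams(2.0, 0))
        with pytest.warns(UserWarning, match="zero total intensity"):
            merged = merge_linked(linked)
        assert merged.df.iloc[0]["x"] == pytest.approx(0.5)

    def test_unassigned_rows_rejected(self):
        t = make_table([(0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="track_id"):
            merge_linked(t)

    def test_merged_precision_improves_like_sqrt_n(self):
        # a blinking emitter re-detected over n frames: the merged position
        # std shrinks ~ 1/sqrt(n) relative to single-frame std
        rng = np.random.default_rng(8)
        sigma, n_frames, n_rep = 0.05, 16, 400
        singles, merged_xs = [], []
        for _ in range(n_rep):
            xs = rng.normal(5.0, sigma, n_frames)
            ys = rng.normal(5.0, sigma, n_frames)
            t = make_table([(f, xs[f], ys[f], 1000.0) for f in range(n_frames)])
            linked = link_localizations(t, LinkParams(1.0, 2))
            assert linked.df["track_id"].nunique() == 1
            m = merge_linked(linked)
            merged_xs.append(m.df.iloc[0]["x"])
            singles.append(xs[0])
        ratio = np.std(singles) / np.std(merged_xs)
        assert ratio == pytest.approx(np.sqrt(n_frames), rel=0.25)
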