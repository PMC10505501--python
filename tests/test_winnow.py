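"""Rolling minmer index vs brute force, window queries, scheme diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minmers.hashing import hash_stream_from_values, kmer_hash_sequence
from minmers.simdata import random_dna, random_hash_stream
from minmers.winnow import (
    MinmerIndex,
    WinnowParams,
    brute_force_index,
    build_minmer_index,
    check_window_guarantee,
    empirical_density,
    empirical_density_factor,
    minmer_positions,
    window_sketch,
)
from minmers.winnow import _winnow_scan, interval_count, overlapping_minmers


def stream(values):
    return hash_stream_from_values(np.asarray(values, dtype=np.float64))


@pytest.mark.parametrize("duplicates", [False, True])
def test_rolling_matches_brute_force_randomized(rng, duplicates):
    for _ in range(60):
        n = int(rng.integers(1, 130))
        w = int(rng.integers(1, 21))
        s = int(rng.integers(1, w + 1))
        if duplicates:
            xs = rng.integers(0, max(2, n // 5), n).astype(np.float64)
        else:
            xs = rng.random(n)
        hs = stream(xs)
        p = WinnowParams(w=w, s=s)
        got = build_minmer_index(hs, p)
        exp = brute_force_index(hs, p)
        assert got.as_tuples() == exp.as_tuples()
        assert minmer_positions(hs, p) == set(
            np.flatnonzero(exp.sampled).tolist()
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    xs=st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=40),
    w=st.integers(min_value=1, max_value=12),
    data=st.data(),
)
def test_rolling_matches_brute_force_property(xs, w, data):
    s = data.draw(st.integers(min_value=1, max_value=w))
    hs = stream(xs)
    p = WinnowParams(w=w, s=s)
    assert build_minmer_index(hs, p).as_tuples() == brute_force_index(hs, p).as_tuples()


def test_increasing_hashes_staircase():
    hs = stream(np.arange(40, dtype=float))
    for w, s in [(5, 1), (5, 3), (8, 8)]:
        p = WinnowParams(w=w, s=s)
        assert build_minmer_index(hs, p).as_tuples() == brute_force_index(hs, p).as_tuples()
    # bottom-s of each window is always its first s elements
    idx = build_minmer_index(hs, WinnowParams(w=5, s=2))
    for j in range(36):
        assert np.array_equal(window_sketch(idx, j), [float(j), float(j + 1)])


def test_decreasing_hashes_every_window_min_is_entering():
    n, w = 30, 4
    hs = stream(np.arange(n, 0, -1, dtype=float))
    p = WinnowParams(w=w, s=1)
    idx = build_minmer_index(hs, p)
    assert idx.as_tuples() == brute_force_index(hs, p).as_tuples()
    # each full window's minimum is its last element: length-1 intervals
    assert all(b - a == 1 for a, b in zip(idx.starts, idx.ends))
    assert len(idx) == n - w + 1
    assert minmer_positions(hs, p) == set(range(w - 1, n))


def test_s_equals_w_samples_everything(rng):
    hs = stream(rng.random(200))
    p = WinnowParams(w=10, s=10)
    pos = minmer_positions(hs, p)
    assert pos == set(range(200))
    assert empirical_density(pos, 200) == 1.0


def test_all_equal_hashes_counter_merged_intervals():
    hs = stream(np.zeros(37))
    p = WinnowParams(w=5, s=2)
    idx = build_minmer_index(hs, p)
    assert idx.as_tuples() == brute_force_index(hs, p).as_tuples()
    # one hash in sketch throughout; runs split into chunks of length <= w
    assert all(b - a <= 5 for a, b in zip(idx.starts, idx.ends))
    assert minmer_positions(hs, p) == set(range(37))


def test_window_sketch_equals_direct_bottom_s(rng):
    xs = rng.random(1000)
    hs = stream(xs)
    idx = build_minmer_index(hs, WinnowParams(w=50, s=5))
    for j in range(0, 951):
        direct = np.sort(xs[j : j + 50])[:5]
        assert np.array_equal(window_sketch(idx, j), direct)
    with pytest.raises(IndexError):
        window_sketch(idx, 951)


def test_larger_window_sketch_is_subset_of_overlapping_minmers(rng):
    xs = rng.random(600)
    hs = stream(xs)
    w, w2, s = 50, 80, 5
    idx = build_minmer_index(hs, WinnowParams(w=w, s=s))
    for j in range(0, 600 - w2 + 1, 13):
        direct = set(np.sort(xs[j : j + w2])[:s].tolist())
        combined = set(overlapping_minmers(idx, j, j + w2 - w).tolist())
        assert direct <= combined


def test_minmer_positions_reduce_to_minimizers_at_s1(rng):
    xs = rng.random(300)
    hs = stream(xs)
    w = 12
    got = minmer_positions(hs, WinnowParams(w=w, s=1))
    expected = {j + int(np.argmin(xs[j : j + w])) for j in range(300 - w + 1)}
    assert got == expected


def test_minmers_contain_minimizers_and_match_index_positions(rng):
    xs = rng.random(500)
    hs = stream(xs)
    p = WinnowParams(w=10, s=3)
    pos = minmer_positions(hs, p)
    mini = minmer_positions(hs, WinnowParams(w=10, s=1))
    assert mini < pos  # strict superset in this regime
    idx = build_minmer_index(hs, p)
    assert pos == set(idx.poss.tolist())  # duplicate-free input


def test_window_guarantee_holds_and_detects_violation(rng):
    xs = rng.random(400)
    hs = stream(xs)
    p = WinnowParams(w=20, s=4)
    pos = minmer_positions(hs, p)
    ok, viol = check_window_guarantee(pos, hs, p)
    assert ok and viol is None
    # floor(w/s)-minimizers also satisfy the (w, s) guarantee
    mini = minmer_positions(hs, WinnowParams(w=5, s=1))
    ok, _ = check_window_guarantee(mini, hs, p)
    assert ok
    # deleting a sampled position from a window holding exactly s samples
    # breaks the guarantee, and the violated window is reported
    tight = next(
        j
        for j in range(400 - p.w + 1)
        if sum(1 for q in pos if j <= q < j + p.w) == p.s
    )
    victim = next(q for q in sorted(pos) if tight <= q < tight + p.w)
    ok, viol = check_window_guarantee(pos - {victim}, hs, p)
    assert not ok
    assert max(0, victim - p.w + 1) <= viol <= victim


def test_density_monotone_in_s_and_density_factor(rng):
    xs = rng.random(3000)
    hs = stream(xs)
    w = 30
    dens = [
        empirical_density(minmer_positions(hs, WinnowParams(w=w, s=s)), 3000)
        for s in (1, 2, 5, 10, 30)
    ]
    assert all(a <= b for a, b in zip(dens, dens[1:]))
    assert dens[-1] == 1.0
    df = empirical_density_factor(
        minmer_positions(hs, WinnowParams(w=w, s=1)), 3000, w
    )
    assert 1.5 < df < 2.5  # random-order minimizers have df ~ 2


def test_non_forward_witness_same_position_two_intervals(rng):
    """Minmers are non-forward: a position can be sampled for two disjoint
    window ranges with a gap in between (two intervals, same pos)."""
    found = False
    for trial in range(50):
        xs = rng.random(80)
        idx = build_minmer_index(stream(xs), WinnowParams(w=10, s=3))
        by_pos = {}
        for h, p, a, b in idx.as_tuples():
            by_pos.setdefault(p, []).append((a, b))
        for p, ivs in by_pos.items():
            ivs.sort()
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if b1 < a2:
                    found = True
        if found:
            break
    assert found


def test_exactly_s_intervals_stab_each_window(rng):
    for dup in (False, True):
        xs = (
            rng.integers(0, 40, 300).astype(float) if dup else rng.random(300)
        )
        hs = stream(xs)
        w, s = 20, 4
        idx = build_minmer_index(hs, WinnowParams(w=w, s=s))
        starts, ends = idx.starts, idx.ends
        for j in range(0, 281, 7):
            n_distinct = len(set(xs[j : j + w].tolist()))
            stabbed = int(((starts <= j) & (ends > j)).sum())
            if n_distinct >= s:
                assert stabbed == s
            else:
                assert stabbed == n_distinct


def test_heap_prunes_are_amortized(rng):
    hs = stream(rng.random(20_000))
    for w, s in [(50, 5), (200, 20)]:
        _, _, _, n_prunes = _winnow_scan(hs, w, s, collect_intervals=False)
        assert n_prunes <= 20_000 / w


def test_short_sequence_single_window(rng):
    xs = rng.random(7)
    hs = stream(xs)
    p = WinnowParams(w=20, s=3)
    idx = build_minmer_index(hs, p)
    assert idx.as_tuples() == brute_force_index(hs, p).as_tuples()
    assert np.array_equal(window_sketch(idx, 0), np.sort(xs)[:3])


def test_index_serialization_round_trip(tmp_path, rng):
    # integer hashes from DNA (with strand bits) and float hashes
    dna = random_dna(800, seed=9)
    hs = kmer_hash_sequence(dna, 13, seed=4, name="ref")
    idx = build_minmer_index(hs, WinnowParams(w=40, s=6, k=13), seed=4)
    path = tmp_path / "idx.tsv"
    idx.save(path)
    back = MinmerIndex.load(path)
    assert back.as_tuples() == idx.as_tuples()
    assert back.params == idx.params
    assert back.n == idx.n and back.ref_name == idx.ref_name
    assert back.strand_by_hash == idx.strand_by_hash
    fl = build_minmer_index(stream(rng.random(200)), WinnowParams(w=10, s=2))
    p2 = tmp_path / "f.tsv"
    fl.save(p2)
    assert MinmerIndex.load(p2).as_tuples() == fl.as_tuples()


def test_interval_count_matches_index_len(rng):
    hs = stream(rng.random(5000))
    p = WinnowParams(w=100, s=10)
    assert interval_count(hs, p) == len(build_minmer_index(hs, p))
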