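"""Candidate sweep, hypergeometric filter, rolling minhash, full mapping."""

import numpy as np
import pytest

from minmers.hashing import hash_stream_from_values, kmer_hash_sequence, revcomp
from minmers.mapper import (
    CandidateRegion,
    MapParams,
    delta_ani_prefilter,
    map_sequence,
    minhash_numerator_pmf,
    segment_complexity,
    stage1_candidates,
    stage2_rolling_minhash,
)
from minmers.sketch import bottom_sketch, minhash_jaccard
from minmers.simdata import MutationSpec, mutate, random_dna
from minmers.winnow import MinmerIndex, WinnowParams, build_minmer_index, window_sketch


def _toy_index(rows, w, s, n, k=1):
    hs = np.asarray([r[0] for r in rows], dtype=np.float64)
    ps = np.asarray([r[1] for r in rows], dtype=np.int64)
    aa = np.asarray([r[2] for r in rows], dtype=np.int64)
    bb = np.asarray([r[3] for r in rows], dtype=np.int64)
    return MinmerIndex(
        params=WinnowParams(w=w, s=s, k=k), n=n, ref_name="toy",
        hashes=hs, poss=ps, starts=aa, ends=bb,
    )


def test_stage1_hand_sweep():
    # matched intervals [2,7), [5,9), [6,8): only window 6 reaches count 3
    rows = [(0.1, 2, 2, 7), (0.2, 5, 5, 9), (0.3, 6, 6, 8)]
    idx = _toy_index(rows, w=5, s=3, n=20)
    q = bottom_sketch([0.1, 0.2, 0.3], 3)
    regions = stage1_candidates(q, idx, MapParams(ani_threshold=0.95))
    assert regions == [
        CandidateRegion(ref_name="toy", start=6, end=7, max_overlap=3)
    ]


def test_stage1_no_matches_is_empty():
    idx = _toy_index([(0.5, 3, 3, 8)], w=5, s=1, n=20)
    q = bottom_sketch([0.9], 1)
    assert stage1_candidates(q, idx) == []


def test_numerator_pmf_degenerate_and_mean():
    s = 100
    assert minhash_numerator_pmf(s, s).pmf(s) == pytest.approx(1.0)
    assert minhash_numerator_pmf(s, 0).pmf(0) == pytest.approx(1.0)
    for c in (10, 50, 90):
        d = minhash_numerator_pmf(s, c)
        assert d.mean() == pytest.approx(s * c / (2 * s - c))
    with pytest.raises(ValueError):
        minhash_numerator_pmf(10, 11)


def test_prefilter_behaviors():
    s, k = 100, 19
    mk = lambda c: CandidateRegion("r", 0, 10, c)
    # huge delta_ani -> kappa = 0 -> nothing dropped
    params = MapParams(delta_ani=1.0)
    regions = [mk(100), mk(10), mk(3)]
    assert delta_ani_prefilter(regions, params, s, k) == regions
    # tight delta: region with ci < kappa dropped with certainty
    params = MapParams(delta_ani=0.0, filter_confidence=0.999)
    kept = delta_ani_prefilter([mk(100), mk(50)], params, s, k)
    assert mk(100) in kept and mk(50) not in kept
    # the best region always survives its own filter
    kept = delta_ani_prefilter([mk(60)], params, s, k)
    assert kept == [mk(60)]


def test_stage2_equals_direct_minhash_everywhere(rng):
    for _ in range(15):
        xs = rng.random(1000)
        hs = hash_stream_from_values(xs)
        idx = build_minmer_index(hs, WinnowParams(w=200, s=20))
        q = bottom_sketch(rng.random(200), 20)
        region = CandidateRegion("r", 0, idx.n_windows, 20)
        pos, nums, dens, jacc = stage2_rolling_minhash(q, idx, region)
        assert len(pos) == idx.n_windows
        for i in range(0, len(pos), 29):
            num, den, j = minhash_jaccard(q, window_sketch(idx, int(pos[i])))
            assert (num, den) == (nums[i], dens[i])
            assert j == jacc[i]


def test_map_exact_copy_and_revcomp():
    ref = random_dna(60_000, seed=21)
    k, w, s = 19, 1000, 20
    hs = kmer_hash_sequence(ref, k, seed=42, name="ref")
    idx = build_minmer_index(hs, WinnowParams(w=w, s=s, k=k), seed=42)
    q = ref[20_000:30_018]
    fwd = map_sequence("q", q, idx)
    assert len(fwd) == 10
    for m in fwd:
        assert m.jaccard == 1.0 and m.ani == 1.0 and m.strand == "+"
    # segment at query offset 0 maps at (or just left of) ref offset 20000
    first = min(fwd, key=lambda m: m.query_start)
    assert first.ref_start <= 20_000 < first.ref_start + w
    rev = map_sequence("qr", revcomp(q), idx)
    assert len(rev) == 10
    assert all(m.strand == "-" and m.jaccard == 1.0 for m in rev)
    assert sorted(m.ref_start for m in rev) == sorted(m.ref_start for m in fwd)


def test_map_mutated_copy_recovers_offset_and_divergence():
    ref = random_dna(200_000, seed=22)
    k, w, s = 19, 5000, 50
    idx = build_minmer_index(
        kmer_hash_sequence(ref, k, seed=42, name="ref"),
        WinnowParams(w=w, s=s, k=k),
        seed=42,
    )
    q = ref[100_000:105_018]
    mut, div, _ = mutate(q, MutationSpec(rate=0.03, seed=8, k=k))
    ms = map_sequence("m", mut, idx)
    assert len(ms) == 1
    m = ms[0]
    assert abs(m.ref_start - 100_000) < 500
    assert m.strand == "+"
    assert 0.01 < 1 - m.ani < 0.06


def test_map_random_query_finds_nothing():
    ref = random_dna(100_000, seed=23)
    idx = build_minmer_index(
        kmer_hash_sequence(ref, 19, seed=42, name="ref"),
        WinnowParams(w=2000, s=50, k=19),
        seed=42,
    )
    assert map_sequence("rand", random_dna(10_000, seed=99), idx) == []


def test_query_shorter_than_k_is_empty():
    ref = random_dna(5_000, seed=2)
    idx = build_minmer_index(
        kmer_hash_sequence(ref, 19, seed=42, name="ref"),
        WinnowParams(w=500, s=10, k=19),
        seed=42,
    )
    assert map_sequence("tiny", "ACGTACGT", idx) == []


def test_early_termination_is_lossless_small():
    ref = random_dna(120_000, seed=31)
    k, w, s = 19, 1000, 20
    idx = build_minmer_index(
        kmer_hash_sequence(ref, k, seed=42, name="ref"),
        WinnowParams(w=w, s=s, k=k),
        seed=42,
    )
    rng = np.random.default_rng(5)
    for i in range(8):
        off = int(rng.integers(0, 100_000))
        q, _, _ = mutate(
            ref[off : off + 4_018],
            MutationSpec(rate=0.02, seed=i, k=k),
        )
        base = MapParams(delta_ani=0.03, all_mappings=True)
        on = map_sequence("q", q, idx, base)
        off_p = MapParams(
            delta_ani=0.03, all_mappings=True, early_termination=False
        )
        assert on == map_sequence("q", q, idx, off_p)


def test_segment_complexity():
    assert segment_complexity(np.array([1.0, 1.0, 2.0, 3.0]), 4) == 0.75
    assert segment_complexity(np.arange(10.0), 10) == 1.0
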