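"""Two-stage homology mapping over a minmer interval index.

Stage 1 sweeps the reference intervals whose hashes occur in the query's
bottom-s sketch: sorting their endpoints and keeping a running overlap
count yields, for every window start j, the exact intersection size
c_j = |pi_s(A) n pi_s(B_j)| without touching the windows themselves.
Maximal runs where c_j reaches the numerator implied by the ANI threshold
become candidate regions, annotated with their maximum overlap ci.

Conditioned on c, the minhash numerator Y is hypergeometric: the union of
two size-s sketches sharing c members has 2s - c distinct values, of which
the union's bottom-s capture Y ~ Hypergeom(N=2s-c, K=c, n=s) shared ones.
This gives a cheap probabilistic filter: regions unlikely (probability
below 1 - filter_confidence) to land within dANI of the best candidate are
dropped before the expensive stage, and processing candidate regions in
decreasing ci order allows lossless early termination once ci falls below
the numerator kappa needed to stay within dANI of the best ANI seen.

Stage 2 computes the minhash for every window start in a region. Because
the window sketch only changes where a minmer interval starts or ends, the
estimator is evaluated per event and held constant in between; each value
equals the direct minhash of the stabbed window sketch exactly.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .hashing import HashSequence, kmer_hash_sequence
from .sketch import BottomSketch, ani_to_jaccard, bottom_sketch, jaccard_to_ani
from .winnow import MinmerIndex, window_sketch

logger = logging.getLogger(__name__)

__all__ = [
    "MapParams",
    "CandidateRegion",
    "Mapping",
    "stage1_candidates",
    "minhash_numerator_pmf",
    "delta_ani_prefilter",
    "stage2_rolling_minhash",
    "map_query",
    "map_sequence",
    "segment_complexity",
]


@dataclass(frozen=True)
class MapParams:
    """Mapping thresholds and reporting flags.

    ani_threshold : minimum reported ANI (MashMap's default 0.85).
    delta_ani : report/retain mappings within this ANI margin of the best.
    filter_confidence : stage-1 pruning keeps any region with at least a
        (1 - filter_confidence) chance of reaching within delta_ani of the
        best candidate.
    all_mappings : report every candidate region's best mapping within
        delta_ani of the overall best, instead of only the single best.
    """

    ani_threshold: float = 0.85
    delta_ani: float = 0.0
    filter_confidence: float = 0.999
    all_mappings: bool = False
    prefilter: bool = True
    early_termination: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.ani_threshold <= 1.0):
            raise ValueError("ani_threshold must lie in (0, 1]")
        if self.delta_ani < 0.0:
            raise ValueError("delta_ani must be >= 0")


@dataclass(frozen=True)
class CandidateRegion:
    """Window-start range [start, end) with max interval overlap ci."""

    ref_name: str
    start: int
    end: int
    max_overlap: int


@dataclass(frozen=True)
class Mapping:
    """A (query segment, reference offset) homology call."""

    query_name: str
    query_start: int  # bp
    query_end: int  # bp
    ref_name: str
    ref_start: int  # bp
    ref_end: int  # bp
    strand: str
    numerator: int
    denominator: int
    jaccard: float
    ani: float
    complexity: float


def min_numerator(denominator: int, ani: float, k: int) -> int:
    """Smallest minhash numerator consistent with the given ANI."""
    if ani <= 0.0:
        return 0
    return max(0, math.ceil(denominator * ani_to_jaccard(ani, k) - 1e-12))


def minhash_numerator_pmf(s: int, c: int):
    """Distribution of the minhash numerator given sketch intersection c.

    Y ~ Hypergeom(population 2s - c, successes c, draws s): among the
    union's bottom-s, Y of the c shared values are captured. Returns the
    frozen scipy distribution (``.pmf``, ``.sf`` available). Degenerate at
    Y = s when c = s and Y = 0 when c = 0.
    """
    if not (0 <= c <= s):
        raise ValueError("require 0 <= c <= s")
    return hypergeom(2 * s - c, c, s)


def stage1_candidates(
    query_sketch: BottomSketch,
    index: MinmerIndex,
    params: MapParams = MapParams(),
) -> list[CandidateRegion]:
    """Sweep matched minmer intervals into candidate regions.

    The returned regions are the maximal window-start runs where the
    matched-interval overlap count meets the minimum numerator implied by
    the ANI threshold; each carries its maximum overlap.
    """
    k = index.params.k
    denom = min(query_sketch.s, len(query_sketch))
    thr = max(1, min_numerator(denom, params.ani_threshold, k))
    lut = index.lookup
    rows: list[np.ndarray] = [
        lut[h] for h in query_sketch.hashes.tolist() if h in lut
    ]
    if not rows:
        return []
    idx = np.concatenate(rows)
    starts = index.starts[idx]
    ends = index.ends[idx]
    pos = np.concatenate([starts, ends])
    delta = np.concatenate(
        [np.ones(len(starts), dtype=np.int64), -np.ones(len(ends), dtype=np.int64)]
    )
    uniq, inv = np.unique(pos, return_inverse=True)
    net = np.bincount(inv, weights=delta).astype(np.int64)
    counts = np.cumsum(net)
    hot = counts >= thr
    regions: list[CandidateRegion] = []
    i = 0
    m = len(uniq)
    n_win = index.n_windows
    while i < m:
        if hot[i]:
            j = i
            while j + 1 < m and hot[j + 1]:
                j += 1
            a = int(uniq[i])
            b = int(uniq[j + 1]) if j + 1 < m else int(uniq[j]) + 1
            a = max(a, 0)
            b = min(b, n_win)
            if a < b:
                regions.append(
                    CandidateRegion(
                        ref_name=index.ref_name,
                        start=a,
                        end=b,
                        max_overlap=int(counts[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions


def delta_ani_prefilter(
    regions: list[CandidateRegion],
    params: MapParams,
    s: int,
    k: int,
) -> list[CandidateRegion]:
    """Drop regions unlikely to fall within delta_ani of the best candidate.

    The best achievable ANI is predicted from the largest overlap c_max;
    kappa is the numerator matching (best ANI - delta_ani); a region is
    kept iff Pr(Y >= kappa | c_i) >= 1 - filter_confidence. Regions with
    c_i < kappa are dropped with certainty since Y <= c always.
    """
    if not regions:
        return []
    c_max = min(s, max(r.max_overlap for r in regions))
    # predicted best Jaccard = E[Y]/s given intersection c_max
    best_ani = jaccard_to_ani(c_max / (2 * s - c_max), k)
    target = best_ani - params.delta_ani
    kappa = min_numerator(s, target, k)
    if kappa == 0:
        return list(regions)
    eps = 1.0 - params.filter_confidence
    kept = []
    for r in regions:
        c = min(r.max_overlap, s)
        if c < kappa:
            continue  # Pr(Y >= kappa) = 0
        if minhash_numerator_pmf(s, c).sf(kappa - 1) >= eps:
            kept.append(r)
    return kept


def _merge_estimate(qs: list, rs: list, s_cap: int) -> tuple[int, int]:
    """(numerator, denominator) of the minhash over two sorted hash lists."""
    i = j = 0
    num = den = 0
    nq, nr = len(qs), len(rs)
    limit = min(s_cap, nq + nr)
    while den < limit and (i < nq or j < nr):
        if j >= nr or (i < nq and qs[i] < rs[j]):
            den += 1
            i += 1
        elif i >= nq or rs[j] < qs[i]:
            den += 1
            j += 1
        else:  # shared value
            den += 1
            num += 1
            i += 1
            j += 1
    return num, den


def stage2_rolling_minhash(
    query_sketch: BottomSketch,
    index: MinmerIndex,
    region: CandidateRegion,
):
    """Minhash estimate at every window start of a candidate region.

    Returns (positions, numerators, denominators, jaccards) arrays. The
    reference window sketch is advanced by interval start/end events
    (binary-searched insert/remove on a sorted array of sketch hashes);
    between events the estimator is constant. Every value equals the
    direct minhash of the stabbed window sketch.
    """
    w_eff = min(index.params.w, index.n)
    a = max(0, region.start)
    b = min(region.end, index.n_windows)
    if a >= b:
        z = np.empty(0)
        return z.astype(np.int64), z.astype(np.int64), z.astype(np.int64), z
    # rows possibly overlapping [a, b): start in (a - w, b)
    lo = np.searchsorted(index.starts, a - w_eff, side="right")
    hi = np.searchsorted(index.starts, b, side="left")
    r_starts = index.starts[lo:hi]
    r_ends = index.ends[lo:hi]
    r_hashes = index.hashes[lo:hi]
    live = r_ends > a
    r_starts = np.maximum(r_starts[live], a)
    r_ends = np.minimum(r_ends[live], b)
    r_hashes = r_hashes[live]

    events: dict[int, list] = {}
    for p, e, h in zip(r_starts.tolist(), r_ends.tolist(), r_hashes.tolist()):
        events.setdefault(p, []).append((h, 1))
        if e < b:
            events.setdefault(e, []).append((h, -1))
    ev_pos = sorted(events)

    qs = query_sketch.hashes.tolist()
    s_cap = min(query_sketch.s, index.params.s)
    cur: dict = {}
    rs: list = []

    n_pos = b - a
    nums = np.zeros(n_pos, dtype=np.int64)
    dens = np.zeros(n_pos, dtype=np.int64)
    jacc = np.zeros(n_pos, dtype=np.float64)
    prev = a
    cur_num = cur_den = 0
    for p in ev_pos + [b]:
        if p > prev:
            nums[prev - a : p - a] = cur_num
            dens[prev - a : p - a] = cur_den
            jacc[prev - a : p - a] = cur_num / cur_den if cur_den else 0.0
            prev = p
        if p == b:
            break
        for h, d in events[p]:
            c = cur.get(h, 0) + d
            if c == 0:
                del cur[h]
                del rs[bisect_left(rs, h)]
            else:
                cur[h] = c
                if c == 1 and d == 1:
                    insort(rs, h)
        cur_num, cur_den = _merge_estimate(qs, rs, s_cap)
    positions = np.arange(a, b, dtype=np.int64)
    return positions, nums, dens, jacc


def segment_complexity(hashes: np.ndarray, w: int) -> float:
    """Ratio of observed distinct k-mers in a segment to w."""
    if w <= 0:
        return 0.0
    return len(np.unique(hashes)) / w


def _strand_vote(
    query_strand_by_hash: dict, index: MinmerIndex, shared: np.ndarray
) -> str:
    vote = 0
    for h in shared.tolist():
        vote += query_strand_by_hash.get(h, 0) * index.strand_by_hash.get(h, 0)
    return "-" if vote < 0 else "+"


def map_sequence(
    name: str,
    seq: str,
    index: MinmerIndex,
    params: MapParams = MapParams(),
) -> list[Mapping]:
    """Map a query DNA sequence against an indexed reference.

    The query is split into non-overlapping segments of w k-mers (a final
    partial segment is retained when at least w/2 k-mers long, mapped with
    its own effective window); each segment is sketched, swept for
    candidate regions, filtered, and scored by the rolling minhash with
    early termination. Reported mappings meet the ANI threshold; by
    default only the best mapping per segment is returned.
    """
    k = index.params.k
    if len(seq) < k:
        logger.warning("query %s shorter than k=%d; nothing to map", name, k)
        return []
    seed = index.seed if index.seed is not None else 42
    hs = kmer_hash_sequence(seq, k, seed=seed, canonical=True, name=name)
    return map_query(hs, index, params)


def map_query(
    hseq: HashSequence,
    index: MinmerIndex,
    params: MapParams = MapParams(),
) -> list[Mapping]:
    """Map a query hash sequence (see :func:`map_sequence`)."""
    w = index.params.w
    s = index.params.s
    k = index.params.k
    n_k = hseq.n
    if n_k == 0:
        return []
    bounds = []
    n_full = n_k // w
    for t in range(n_full):
        bounds.append((t * w, (t + 1) * w))
    rem = n_k - n_full * w
    if n_full == 0:
        bounds.append((0, n_k))
    elif rem >= w / 2:
        bounds.append((n_full * w, n_k))

    out: list[Mapping] = []
    for a, b in bounds:
        seg = hseq.slice(a, b)
        seg_hashes = seg.hashes[seg.valid]
        if seg_hashes.size == 0:
            continue
        sketch = bottom_sketch(seg_hashes, s)
        regions = stage1_candidates(sketch, index, params)
        if params.prefilter:
            regions = delta_ani_prefilter(regions, params, s, k)
        if not regions:
            continue
        regions.sort(key=lambda r: (-r.max_overlap, r.start))

        q_strand = {}
        if seg.strand is not None:
            st = seg.strand[seg.valid]
            for h, sv in zip(seg_hashes.tolist(), st.tolist()):
                if h not in q_strand:
                    q_strand[h] = sv

        best: tuple | None = None  # (jhat, -num?) keep (jhat, pos) leftmost
        cand: list[tuple] = []  # (jhat, num, den, pos)
        kappa = 0
        for r in regions:
            if (
                params.early_termination
                and best is not None
                and r.max_overlap < kappa
            ):
                break
            pos_arr, nums, dens, jacc = stage2_rolling_minhash(sketch, index, r)
            if len(pos_arr) == 0:
                continue
            i_best = int(np.argmax(jacc))
            jhat = float(jacc[i_best])
            if jhat <= 0.0:
                continue
            cand.append(
                (jhat, int(nums[i_best]), int(dens[i_best]), int(pos_arr[i_best]))
            )
            if best is None or jhat > best[0]:
                best = (jhat, int(dens[i_best]))
                best_ani = jaccard_to_ani(jhat, k)
                kappa = min_numerator(best[1], best_ani - params.delta_ani, k)
        if best is None:
            continue
        best_ani = jaccard_to_ani(best[0], k)
        keep_ani = max(params.ani_threshold, best_ani - params.delta_ani)
        comp = segment_complexity(seg_hashes, min(w, b - a))
        chosen = cand if params.all_mappings else [max(cand, key=lambda c: (c[0], -c[3]))]
        for jhat, num, den, pos in chosen:
            ani = jaccard_to_ani(jhat, k)
            if ani < keep_ani - 1e-12:
                continue
            shared = np.intersect1d(sketch.hashes, window_sketch(index, pos))
            strand = _strand_vote(q_strand, index, shared)
            w_ref = min(w, index.n - pos)
            out.append(
                Mapping(
                    query_name=hseq.source_name,
                    query_start=a,
                    query_end=b + k - 1,
                    ref_name=index.ref_name,
                    ref_start=pos,
                    ref_end=pos + w_ref + k - 1,
                    strand=strand,
                    numerator=num,
                    denominator=den,
                    jaccard=jhat,
                    ani=ani,
                    complexity=comp,
                )
            )
    return out


def to_paf_row(m: Mapping, query_len: int, ref_len: int) -> str:
    """PAF-like TSV row with ANI and complexity tags."""
    fields = [
        m.query_name,
        str(query_len),
        str(m.query_start),
        str(m.query_end),
        m.strand,
        m.ref_name,
        str(ref_len),
        str(m.ref_start),
        str(m.ref_end),
        str(m.numerator),
        str(m.denominator),
        "255",
        f"an:f:{m.ani:.6f}",
        f"cm:f:{m.complexity:.4f}",
        f"jc:f:{m.jaccard:.6f}",
    ]
    return "\t".join(fields)
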