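"""Minmer winnowing: rolling bottom-s sketch and the minmer interval index.

A (w, s) minmer scheme samples every k-mer that is among the s smallest
(under a random hash ordering) in *any* window of w consecutive k-mers that
contains it. With s = 1 this reduces to the classic minimizer scheme; for
s > 1 it is a non-forward local scheme: a k-mer can be sampled for two
disjoint ranges of windows with an unsampled gap in between.

The index stores *minmer intervals* (hash, pos, start, end): the k-mer is in
the bottom-s sketch of every window whose start lies in [start, end).
Stabbing the interval set at window start j therefore recovers the exact
bottom-s sketch of window j with no sorting — the property that makes the
downstream minhash Jaccard estimator unbiased.

Construction is a single left-to-right sweep maintaining

* ``M`` — the current bottom-s distinct hashes with their open intervals
  (a bisect-maintained sorted list plus a dict), and
* ``H`` — a lazy min-heap of the remaining in-window hashes, pruned by full
  rebuild whenever it exceeds 2w entries.

Duplicate k-mers share one sketch slot per distinct hash with a counter of
active positions; a hash's in-sketch run can then exceed w window starts and
is split into adjacent chunks of length <= w (the mapping stage relies on
this bound).
"""

from __future__ import annotations

import heapq
from bisect import bisect_left, insort
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hashing import HashSequence

__all__ = [
    "WinnowParams",
    "MinmerInterval",
    "MinmerIndex",
    "build_minmer_index",
    "brute_force_index",
    "window_sketch",
    "minmer_positions",
    "check_window_guarantee",
    "empirical_density",
    "empirical_density_factor",
]


@dataclass(frozen=True)
class WinnowParams:
    """Winnowing parameters: window length w (in k-mers), sketch size s, k."""

    w: int
    s: int
    k: int = 1

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not (1 <= self.s <= self.w):
            raise ValueError("require 1 <= s <= w")


@dataclass(frozen=True)
class MinmerInterval:
    """Interval (i, a, b): k-mer at pos i is in the bottom-s of windows [a, b)."""

    hash: int | float
    pos: int
    start: int
    end: int


class MinmerIndex:
    """Sorted minmer interval list plus hash -> intervals lookup for a reference."""

    def __init__(
        self,
        params: WinnowParams,
        n: int,
        ref_name: str,
        hashes: np.ndarray,
        poss: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        sampled: np.ndarray | None = None,
        strand_by_hash: dict | None = None,
        seed: int | None = None,
    ) -> None:
        self.params = params
        self.n = n  # number of k-mer positions in the reference
        self.ref_name = ref_name
        order = np.lexsort((ends, poss, starts))
        self.hashes = hashes[order]
        self.poss = poss[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.sampled = sampled
        self.strand_by_hash = strand_by_hash or {}
        self.seed = seed
        self._lookup: dict | None = None

    # -- basic views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_windows(self) -> int:
        return max(0, self.n - min(self.params.w, self.n) + 1)

    @property
    def intervals(self) -> list[MinmerInterval]:
        return [
            MinmerInterval(h, int(p), int(a), int(b))
            for h, p, a, b in zip(self.hashes, self.poss, self.starts, self.ends)
        ]

    @property
    def lookup(self) -> dict:
        """Hash value -> array of interval row indices, ordered by start."""
        if self._lookup is None:
            lut: dict = {}
            for idx, h in enumerate(self.hashes.tolist()):
                lut.setdefault(h, []).append(idx)
            self._lookup = {h: np.asarray(v) for h, v in lut.items()}
        return self._lookup

    def as_tuples(self) -> list[tuple]:
        """(hash, pos, start, end) rows sorted by (start, pos, end)."""
        return list(
            zip(self.hashes.tolist(), self.poss.tolist(), self.starts.tolist(),
                self.ends.tolist())
        )

    # -- serialization -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the index as a tab-separated text file with a header."""
        is_float = np.issubdtype(self.hashes.dtype, np.floating)
        with open(path, "w") as fh:
            fh.write(f"#minmer-index\tv1\n")
            fh.write(
                f"#w={self.params.w}\ts={self.params.s}\tk={self.params.k}"
                f"\tseed={self.seed if self.seed is not None else ''}"
                f"\tref={self.ref_name}\tn={self.n}"
                f"\tdtype={'f' if is_float else 'u'}\n"
            )
            for h, p, a, b in zip(
                self.hashes.tolist(), self.poss.tolist(),
                self.starts.tolist(), self.ends.tolist(),
            ):
                hs = repr(h) if is_float else str(h)
                st = self.strand_by_hash.get(h, 0)
                fh.write(f"{hs}\t{p}\t{a}\t{b}\t{st}\n")

    @classmethod
    def load(cls, path: str | Path) -> "MinmerIndex":
        with open(path) as fh:
            magic = fh.readline()
            if not magic.startswith("#minmer-index"):
                raise ValueError("not a minmer index file")
            meta = dict(
                kv.split("=", 1) for kv in fh.readline().lstrip("#").strip().split("\t")
            )
            is_float = meta["dtype"] == "f"
            conv = float if is_float else int
            hs, ps, aa, bb, strands = [], [], [], [], {}
            for line in fh:
                h, p, a, b, st = line.rstrip("\n").split("\t")
                hv = conv(h)
                hs.append(hv)
                ps.append(int(p))
                aa.append(int(a))
                bb.append(int(b))
                if int(st):
                    strands[hv] = int(st)
        params = WinnowParams(w=int(meta["w"]), s=int(meta["s"]), k=int(meta["k"]))
        seed = int(meta["seed"]) if meta.get("seed") else None
        dtype = np.float64 if is_float else np.uint64
        return cls(
            params=params,
            n=int(meta["n"]),
            ref_name=meta["ref"],
            hashes=np.asarray(hs, dtype=dtype),
            poss=np.asarray(ps, dtype=np.int64),
            starts=np.asarray(aa, dtype=np.int64),
            ends=np.asarray(bb, dtype=np.int64),
            strand_by_hash=strands,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# rolling construction
# ---------------------------------------------------------------------------


def _winnow_scan(
    hseq: HashSequence,
    w: int,
    s: int,
    collect_intervals: bool = True,
    collect_sampled: bool = True,
):
    """Single sweep over the hash sequence.

    Returns (intervals, sampled, n_intervals, n_prunes) where intervals is a
    list of (hash, pos, start, end) or None, and sampled a boolean array
    over positions or None.
    """
    n = hseq.n
    out: list | None = [] if collect_intervals else None
    sampled = np.zeros(n, dtype=bool) if collect_sampled else None
    n_intervals = 0
    n_prunes = 0
    if n == 0:
        return out, sampled, 0, 0

    w_eff = min(w, n)
    n_windows = n - w_eff + 1
    xs = hseq.hashes.tolist()
    valid = hseq.valid
    all_valid = bool(valid.all())

    positions: dict = {}  # hash -> deque of active (in-window) positions
    sketch_vals: list = []  # sorted values currently in the bottom-s
    sketch_info: dict = {}  # hash -> [start_window, rep_pos]
    H: list = []  # (hash, pos) lazy min-heap of non-sketch in-window hashes
    split_q: list = []  # (start + w_eff, hash): pending length-w splits

    def emit(v, info, end):
        nonlocal n_intervals
        if end > info[0]:
            n_intervals += 1
            if out is not None:
                out.append((v, info[1], info[0], end))

    def mark_all(v):
        if sampled is not None:
            for p in positions[v]:
                sampled[p] = True

    def insert_sketch(v, j):
        insort(sketch_vals, v)
        sketch_info[v] = [j, positions[v][0]]
        heapq.heappush(split_q, (j + w_eff, v))
        mark_all(v)

    # --- initial window ------------------------------------------------
    for p in range(w_eff):
        if all_valid or valid[p]:
            v = xs[p]
            if v in positions:
                positions[v].append(p)
            else:
                positions[v] = deque([p])
    for v in sorted(positions)[:s]:
        insert_sketch(v, 0)
    if len(positions) > s:
        H = [(v, positions[v][-1]) for v in positions if v not in sketch_info]
        heapq.heapify(H)

    # --- slide ----------------------------------------------------------
    for j in range(1, n_windows):
        e = j - 1
        q = j + w_eff - 1
        e_ok = all_valid or valid[e]
        q_ok = all_valid or valid[q]
        ve = xs[e] if e_ok else None
        vq = xs[q] if q_ok else None

        if e_ok and q_ok and ve == vq:
            dq = positions[ve]
            dq.popleft()
            dq.append(q)
            if ve in sketch_info and sampled is not None:
                sampled[q] = True
        else:
            if e_ok:
                dq = positions[ve]
                dq.popleft()
                if not dq:
                    del positions[ve]
                    if ve in sketch_info:
                        emit(ve, sketch_info.pop(ve), j)
                        del sketch_vals[bisect_left(sketch_vals, ve)]
            if q_ok:
                if vq in positions:
                    positions[vq].append(q)
                    if vq in sketch_info:
                        if sampled is not None:
                            sampled[q] = True
                    else:
                        heapq.heappush(H, (vq, q))
                else:
                    positions[vq] = deque([q])
                    if len(sketch_vals) >= s and vq < sketch_vals[-1]:
                        vmax = sketch_vals.pop()
                        emit(vmax, sketch_info.pop(vmax), j)
                        heapq.heappush(H, (vmax, positions[vmax][-1]))
                        insert_sketch(vq, j)
                    else:
                        # compete with heap candidates via the refill below
                        heapq.heappush(H, (vq, q))
            # refill empty sketch slots from the heap
            while len(sketch_vals) < s and H:
                v, _ = heapq.heappop(H)
                if v in sketch_info or v not in positions:
                    continue  # expired or already promoted
                insert_sketch(v, j)

        # split any in-sketch run reaching length w
        while split_q and split_q[0][0] <= j:
            key, v = heapq.heappop(split_q)
            info = sketch_info.get(v)
            if info is not None and info[0] == key - w_eff:
                emit(v, info, key)
                info[0] = key
                info[1] = positions[v][0]
                heapq.heappush(split_q, (key + w_eff, v))

        # prune the heap when it accumulates too many stale entries
        if len(H) > 2 * w:
            H = [
                (v, positions[v][-1]) for v in positions if v not in sketch_info
            ]
            heapq.heapify(H)
            n_prunes += 1

    # close remaining open intervals at one past the last window index
    for v, info in sketch_info.items():
        emit(v, info, n_windows)

    return out, sampled, n_intervals, n_prunes


def build_minmer_index(
    hseq: HashSequence, params: WinnowParams, seed: int | None = None
) -> MinmerIndex:
    """Build the sorted minmer interval index I and lookup table T.

    The rolling sweep applies, at every slide, the case determined by
    whether the exiting and entering hashes are in the current bottom-s;
    closed intervals are appended to the index and empty sketch slots are
    refilled from the heap, discarding expired entries lazily.

    Sequences with fewer than w k-mers are treated as a single window of
    their full length with sketch size min(s, #distinct).
    """
    out, sampled, _, _ = _winnow_scan(hseq, params.w, params.s)
    if out:
        hs = np.asarray([t[0] for t in out], dtype=hseq.hashes.dtype)
        ps = np.asarray([t[1] for t in out], dtype=np.int64)
        aa = np.asarray([t[2] for t in out], dtype=np.int64)
        bb = np.asarray([t[3] for t in out], dtype=np.int64)
    else:
        hs = np.empty(0, dtype=hseq.hashes.dtype)
        ps = aa = bb = np.empty(0, dtype=np.int64)
    strand_by_hash = {}
    if hseq.strand is not None and hseq.strand.any():
        st = hseq.strand
        strand_by_hash = {
            h: int(st[p]) for h, p in zip(hs.tolist(), ps.tolist()) if st[p]
        }
    return MinmerIndex(
        params=params,
        n=hseq.n,
        ref_name=hseq.source_name,
        hashes=hs,
        poss=ps,
        starts=aa,
        ends=bb,
        sampled=sampled,
        strand_by_hash=strand_by_hash,
        seed=seed,
    )


def minmer_positions(hseq: HashSequence, params: WinnowParams) -> set[int]:
    """All positions sampled by the (w, s) scheme (Definition-level minmers).

    With duplicate hashes, every active position of an in-sketch hash is a
    minmer, so this set can be larger than the set of interval ``pos``
    fields (which keep one representative per merged interval).
    """
    _, sampled, _, _ = _winnow_scan(
        hseq, params.w, params.s, collect_intervals=False
    )
    if sampled is None:
        return set()
    return set(np.flatnonzero(sampled).tolist())


def interval_count(hseq: HashSequence, params: WinnowParams) -> int:
    """Number of minmer intervals |I| without materializing them."""
    _, _, cnt, _ = _winnow_scan(
        hseq, params.w, params.s, collect_intervals=False, collect_sampled=False
    )
    return cnt


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


def window_sketch(index: MinmerIndex, j: int) -> np.ndarray:
    """Bottom-s sketch of window W_j by interval stabbing at j.

    Returns the sorted distinct hash values whose minmer intervals contain
    j; no raw window contents are sorted.
    """
    w_eff = min(index.params.w, index.n)
    if not (0 <= j <= index.n - w_eff):
        raise IndexError(f"window start {j} out of range [0, {index.n - w_eff}]")
    # interval length <= w, so any interval containing j starts in (j-w, j]
    lo = np.searchsorted(index.starts, j - w_eff, side="right")
    hi = np.searchsorted(index.starts, j, side="right")
    mask = index.ends[lo:hi] > j
    vals = index.hashes[lo:hi][mask]
    return np.sort(vals)


def overlapping_minmers(index: MinmerIndex, lo: int, hi: int) -> np.ndarray:
    """Distinct hashes whose intervals overlap window-start range [lo, hi].

    The bottom-s sketch of any larger window of w' > w k-mers starting at
    lo (with hi = lo + w' - w) is a subset of these combined minmers.
    """
    w_eff = min(index.params.w, index.n)
    a = np.searchsorted(index.starts, lo - w_eff, side="right")
    b = np.searchsorted(index.starts, hi, side="right")
    mask = index.ends[a:b] > lo
    return np.unique(index.hashes[a:b][mask])


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_index(hseq: HashSequence, params: WinnowParams) -> MinmerIndex:
    """Quadratic-time reference construction: sort every window directly.

    Defines ground truth for the rolling construction. For every window j
    the bottom-s distinct hashes are found by a full sort; per-hash
    membership runs become intervals, split into chunks of length <= w.
    """
    n = hseq.n
    w, s = params.w, params.s
    w_eff = min(w, n)
    rows: list[tuple] = []
    sampled = np.zeros(n, dtype=bool)
    if n:
        xs = hseq.hashes.tolist()
        valid = hseq.valid
        n_windows = n - w_eff + 1
        runs: dict = {}  # hash -> list of window indices where in bottom-s
        pos_by_hash: dict = {}
        for p in range(n):
            if valid[p]:
                pos_by_hash.setdefault(xs[p], []).append(p)
        for j in range(n_windows):
            window_vals = sorted(
                {xs[p] for p in range(j, j + w_eff) if valid[p]}
            )[:s]
            for v in window_vals:
                runs.setdefault(v, []).append(j)
                for p in pos_by_hash[v]:
                    if j <= p < j + w_eff:
                        sampled[p] = True
        for v, js in runs.items():
            # maximal consecutive runs
            a = js[0]
            prev = js[0]
            segments = []
            for j in js[1:]:
                if j != prev + 1:
                    segments.append((a, prev + 1))
                    a = j
                prev = j
            segments.append((a, prev + 1))
            for a, b in segments:
                # split into chunks of at most w windows
                c = a
                while c < b:
                    d = min(c + w_eff, b)
                    rep = next(
                        p for p in pos_by_hash[v] if c <= p < c + w_eff
                    )
                    rows.append((v, rep, c, d))
                    c = d
    if rows:
        hs = np.asarray([t[0] for t in rows], dtype=hseq.hashes.dtype)
        ps = np.asarray([t[1] for t in rows], dtype=np.int64)
        aa = np.asarray([t[2] for t in rows], dtype=np.int64)
        bb = np.asarray([t[3] for t in rows], dtype=np.int64)
    else:
        hs = np.empty(0, dtype=hseq.hashes.dtype)
        ps = aa = bb = np.empty(0, dtype=np.int64)
    return MinmerIndex(
        params=params, n=n, ref_name=hseq.source_name,
        hashes=hs, poss=ps, starts=aa, ends=bb, sampled=sampled,
    )


# ---------------------------------------------------------------------------
# scheme diagnostics
# ---------------------------------------------------------------------------


def check_window_guarantee(
    positions: set[int], hseq: HashSequence, params: WinnowParams
) -> tuple[bool, int | None]:
    """Verify the (w, s)-window guarantee.

    Every window of w k-mers must contain at least min(#distinct, s)
    sampled positions. Returns (ok, first_violating_window_start).
    """
    n = hseq.n
    w, s = params.w, params.s
    w_eff = min(w, n)
    xs = hseq.hashes.tolist()
    valid = hseq.valid
    for j in range(max(0, n - w_eff + 1)):
        window = [p for p in range(j, j + w_eff) if valid[p]]
        n_distinct = len({xs[p] for p in window})
        n_sampled = sum(1 for p in window if p in positions)
        if n_sampled < min(n_distinct, s):
            return False, j
    return True, None


def empirical_density(positions, n: int) -> float:
    """Fraction of the n k-mer positions that were sampled."""
    if n <= 0:
        raise ValueError("n must be positive")
    return len(positions) / n


def empirical_density_factor(positions, n: int, w: int) -> float:
    """Expected sampled positions per window of w + 1 k-mers: density * (w+1)."""
    return empirical_density(positions, n) * (w + 1)
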