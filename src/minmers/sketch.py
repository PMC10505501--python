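"""Bottom-s sketching, the minhash Jaccard estimator, and Jaccard <-> ANI.

The bottom-s sketch of a k-mer set is its s smallest distinct hash values
under a random ordering. For two sets A, B the minhash estimator

    Jhat(A, B) = |pi_s(A u B) n pi_s(A) n pi_s(B)| / |pi_s(A u B)|

is unbiased for the true Jaccard J(A, B) with standard deviation
O(1/sqrt(s)). ANI conversion uses the binomial k-mer mutation model: each
of the k bases of a k-mer survives substitution independently, so a
per-base divergence d gives shared k-mer fraction (1-d)^k and expected
Jaccard j = (1-d)^k / (2 - (1-d)^k), inverted exactly as
d = 1 - (2j / (1+j))^(1/k). (The classic Mash distance
-(1/k) ln(2j/(1+j)) is the Poisson approximation of this inversion; the
exact form avoids a d^2/2 overestimate of divergence that becomes visible
beyond a few percent.)

Also provided: the minimizer-based "winnowed minhash" estimator of earlier
MashMap versions, kept as a baseline. It sketches the *minimizer subset*
of each sequence rather than the full k-mer set, which systematically
underestimates Jaccard (and hence ANI) — the bias the minmer scheme
removes.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BottomSketch",
    "bottom_sketch",
    "minhash_jaccard",
    "jaccard_to_ani",
    "ani_to_jaccard",
    "divergence_from_jaccard",
    "minimizer_set",
    "winnowed_minhash_jaccard",
]


@dataclass(frozen=True)
class BottomSketch:
    """The s smallest distinct hash values of a set, sorted ascending."""

    hashes: np.ndarray
    s: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "hashes", np.asarray(self.hashes))

    def __len__(self) -> int:
        return len(self.hashes)


def bottom_sketch(hashes, s: int) -> BottomSketch:
    """Bottom-s sketch: the s smallest distinct values, ascending.

    Duplicates collapse (set semantics); if fewer than s distinct values
    exist, all of them are returned. Empty input gives an empty sketch.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    arr = np.asarray(hashes)
    if arr.size == 0:
        return BottomSketch(hashes=arr[:0], s=s)
    if arr.size > 4 * s:
        # cheap pre-selection before the dedup sort
        arr = np.partition(arr, min(2 * s, arr.size - 1))[: 2 * s + 1]
        distinct = np.unique(arr)[:s]
        if len(distinct) < s:  # duplicates may have hidden values; redo fully
            distinct = np.unique(np.asarray(hashes))[:s]
    else:
        distinct = np.unique(arr)[:s]
    return BottomSketch(hashes=distinct, s=s)


def minhash_jaccard(a, b) -> tuple[int, int, float]:
    """Minhash Jaccard estimate between two bottom-s sketches.

    Returns (numerator, denominator, estimate): the number of values in the
    bottom-s of the merged union that occur in both sketches, the size of
    that union sketch (<= s), and their ratio.
    """
    ah = a.hashes if isinstance(a, BottomSketch) else np.asarray(a)
    bh = b.hashes if isinstance(b, BottomSketch) else np.asarray(b)
    s = min(
        a.s if isinstance(a, BottomSketch) else len(ah),
        b.s if isinstance(b, BottomSketch) else len(bh),
    )
    if ah.size == 0 and bh.size == 0:
        raise ValueError("Jaccard of two empty sketches is undefined")
    union = np.union1d(ah, bh)[:s]
    shared = np.intersect1d(ah, bh, assume_unique=True)
    num = int(np.isin(union, shared, assume_unique=True).sum())
    den = int(union.size)
    return num, den, num / den


def jaccard_to_ani(j_hat: float, k: int) -> float:
    """ANI under the binomial k-mer mutation model; 0 is the no-similarity sentinel."""
    if not (0.0 <= j_hat <= 1.0):
        raise ValueError("j_hat must lie in [0, 1]")
    if j_hat == 0.0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - divergence_from_jaccard(j_hat, k)))


def divergence_from_jaccard(j_hat: float, k: int) -> float:
    """Per-base divergence d = 1 - (2j / (1+j))^(1/k). Requires j_hat > 0."""
    return 1.0 - (2.0 * j_hat / (1.0 + j_hat)) ** (1.0 / k)


def ani_to_jaccard(ani: float, k: int) -> float:
    """Exact inverse of :func:`jaccard_to_ani` on (0, 1]."""
    if not (0.0 < ani <= 1.0):
        raise ValueError("ani must lie in (0, 1]")
    e = ani**k
    return e / (2.0 - e)


# ---------------------------------------------------------------------------
# minimizer-based baseline (the biased estimator minmers replace)
# ---------------------------------------------------------------------------


def minimizer_set(hashes, w: int) -> np.ndarray:
    """Distinct hash values of the w-minimizers of a hash sequence.

    Classic winnowing: the minimum of every window of w consecutive
    hashes, left-most on ties, via a monotone deque.
    """
    xs = np.asarray(hashes)
    n = len(xs)
    if n == 0:
        return xs[:0]
    w = min(w, n)
    vals = xs.tolist()
    dq: deque = deque()  # indices, increasing value
    chosen = set()
    for i in range(n):
        v = vals[i]
        while dq and vals[dq[-1]] > v:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w:
            dq.popleft()
        if i >= w - 1:
            chosen.add(dq[0])
    return np.unique(xs[sorted(chosen)])


def winnowed_minhash_jaccard(
    query_hashes, ref_hashes, w_prime: int, s: int
) -> tuple[int, int, float]:
    """Minimizer-winnowed minhash estimate (biased baseline).

    Both inputs are first reduced to their w'-minimizer sets and the
    minhash is computed between the bottom-s sketches of those subsets —
    the estimator of minimizer-based MashMap. Because a sequence's
    minimizer set need not contain all of its s smallest hashes, the
    estimator is *not* unbiased for the true Jaccard.
    """
    qa = bottom_sketch(minimizer_set(query_hashes, w_prime), s)
    ra = bottom_sketch(minimizer_set(ref_hashes, w_prime), s)
    return minhash_jaccard(qa, ra)
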