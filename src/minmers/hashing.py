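"""k-mer hashing with strand canonicalization.

A DNA sequence of length L yields L - k + 1 overlapping k-mers. Each k-mer
is packed into a 2-bit-per-base integer code and scrambled through a
seedable 64-bit finalizer (splitmix64), giving an approximately uniform,
deterministic ordering on k-mers — the random total order pi that winnowing
and minhash sketching assume. With ``canonical=True`` a k-mer and its
reverse complement hash identically (the lexicographically smaller spelling
is hashed), so sketches are strand-invariant; a per-position strand bit
records which spelling won, which the mapper later uses for strand calls.

Positions whose k-mer contains an ambiguous base (N) are masked: they keep
their coordinate but carry no usable hash.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HashSequence",
    "kmer_hash_sequence",
    "hash_stream_from_values",
    "read_fasta",
    "write_fasta",
    "revcomp",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case
_BASE_CODE[ord("N")] = -2
_BASE_CODE[ord("n")] = -2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer on uint64 arrays."""
    z = x + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@dataclass
class HashSequence:
    """Sequence of per-position k-mer hash values x_0 .. x_{n-1}.

    Attributes
    ----------
    hashes : np.ndarray
        One hash per k-mer position (uint64 for DNA-derived hashes,
        float64 in [0, 1] for synthetic i.i.d. streams). Masked positions
        hold an arbitrary value; consult ``valid``.
    valid : np.ndarray of bool
        False where the k-mer window contained an ambiguous base.
    strand : np.ndarray of int8
        +1 if the canonical spelling is the forward one, -1 if the reverse
        complement, 0 for palindromes or non-canonical hashing.
    k : int
        k-mer length in bases (1 for abstract hash streams).
    source_name : str
        Identifier of the originating sequence.
    """

    hashes: np.ndarray
    k: int
    source_name: str = ""
    valid: np.ndarray | None = None
    strand: np.ndarray | None = None
    seq_len: int | None = None

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes)
        if self.valid is None:
            self.valid = np.ones(len(self.hashes), dtype=bool)
        if self.strand is None:
            self.strand = np.zeros(len(self.hashes), dtype=np.int8)
        if self.seq_len is None:
            self.seq_len = len(self.hashes) + self.k - 1 if len(self.hashes) else 0

    @property
    def n(self) -> int:
        """Number of k-mer positions (= seq_len - k + 1 for plain DNA)."""
        return len(self.hashes)

    def __len__(self) -> int:
        return len(self.hashes)

    def normalized(self) -> np.ndarray:
        """Hashes mapped to [0, 1] floats (identity for float streams)."""
        if np.issubdtype(self.hashes.dtype, np.floating):
            return self.hashes
        return self.hashes.astype(np.float64) / float(2**64)

    def slice(self, start: int, stop: int) -> "HashSequence":
        """Sub-sequence of k-mer positions [start, stop)."""
        return HashSequence(
            hashes=self.hashes[start:stop],
            k=self.k,
            source_name=self.source_name,
            valid=self.valid[start:stop],
            strand=self.strand[start:stop],
            seq_len=max(0, stop - start) + self.k - 1,
        )


def _pack_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement packed 2-bit codes for every k-mer.

    Returns (fwd, rc) uint64 arrays of length n = len(codes) - k + 1.
    Requires 2k <= 64, i.e. k <= 32.
    """
    n = len(codes) - k + 1
    c = codes.astype(np.uint64)
    rc_c = _U64(3) - c[::-1]
    from numpy.lib.stride_tricks import sliding_window_view

    pow_f = (_U64(4) ** np.arange(k - 1, -1, -1, dtype=_U64))
    # windowed dot products in chunks to bound memory
    fwd = np.empty(n, dtype=_U64)
    rc_rev = np.empty(n, dtype=_U64)
    chunk = 1 << 16
    wf = sliding_window_view(c, k)
    wr = sliding_window_view(rc_c, k)
    with np.errstate(over="ignore"):
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            fwd[lo:hi] = (wf[lo:hi] * pow_f).sum(axis=1, dtype=_U64)
            rc_rev[lo:hi] = (wr[lo:hi] * pow_f).sum(axis=1, dtype=_U64)
    # rc code of k-mer at position i is the window at mirrored position
    rc = rc_rev[::-1].copy()
    return fwd, rc


def kmer_hash_sequence(
    seq: str,
    k: int,
    seed: int = 42,
    canonical: bool = True,
    name: str = "",
) -> HashSequence:
    """Hash every k-mer of a DNA sequence.

    Parameters
    ----------
    seq : str
        DNA over {A, C, G, T, N} (case-insensitive).
    k : int
        k-mer length, 1 <= k <= 32.
    seed : int
        Hash seed; changing it applies an independent random ordering.
    canonical : bool
        Hash the lexicographically smaller of each k-mer and its reverse
        complement, making hashes strand-invariant.

    Returns
    -------
    HashSequence
        len(seq) - k + 1 hashes (empty when len(seq) < k). Positions whose
        window covers an N are masked via ``valid``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 32:
        raise ValueError("k must be <= 32 (2-bit packing)")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    if np.any(codes == -1):
        bad = seq[int(np.argmax(codes == -1))]
        raise ValueError(f"invalid DNA symbol {bad!r} (expected A/C/G/T/N)")
    n = len(seq) - k + 1
    if n <= 0:
        return HashSequence(
            hashes=np.empty(0, dtype=_U64), k=k, source_name=name, seq_len=len(seq)
        )
    is_n = codes == -2
    codes = np.where(is_n, 0, codes)
    fwd, rc = _pack_kmer_codes(codes, k)
    if canonical:
        canon = np.minimum(fwd, rc)
        strand = np.zeros(n, dtype=np.int8)
        strand[fwd < rc] = 1
        strand[fwd > rc] = -1
    else:
        canon = fwd
        strand = np.zeros(n, dtype=np.int8)
    with np.errstate(over="ignore"):
        mixed = _splitmix64(canon ^ _splitmix64(np.full(n, seed, dtype=_U64)))
    # a position is valid iff no N falls inside its window
    if is_n.any():
        cs = np.concatenate([[0], np.cumsum(is_n)])
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(n, dtype=bool)
    return HashSequence(
        hashes=mixed, k=k, source_name=name, valid=valid, strand=strand,
        seq_len=len(seq),
    )


def hash_stream_from_values(values, name: str = "stream") -> HashSequence:
    """Wrap raw hash values (e.g. i.i.d. uniforms) as a HashSequence (k=1)."""
    return HashSequence(hashes=np.asarray(values), k=1, source_name=name)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) for each record of a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)


def write_fasta(path: str | Path, records: Iterator[tuple[str, str]] | list) -> None:
    """Write (name, sequence) pairs to a FASTA file."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, str(path), "fasta")
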