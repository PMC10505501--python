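"""Synthetic inputs: i.i.d. hash streams, random DNA, point-mutated copies.

The mutation model is the ideal-sequence substitution model used for
validating Jaccard/ANI estimators: exactly round(r * L) positions of a
length-L sequence are substituted to a different base, optionally with the
constraint that no k-mer occurs twice in either the original or the mutant
(so k-mer sets behave like ideal random sets and the true Jaccard follows
directly from the number of disrupted k-mers). All randomness flows from
explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hashing import HashSequence, hash_stream_from_values, write_fasta

__all__ = [
    "MutationSpec",
    "random_hash_stream",
    "random_dna",
    "mutate",
    "write_mutation_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationSpec:
    """Substitution mutation parameters.

    rate : per-base substitution probability (exactly round(rate*L)
        positions are mutated).
    seed : RNG seed.
    forbid_duplicate_kmers : resample until no k-mer occurs twice in either
        sequence (bounded retries), so mutated k-mers never collide with
        existing ones.
    k : k-mer length used for the duplicate check.
    """

    rate: float
    seed: int = 0
    forbid_duplicate_kmers: bool = False
    k: int = 19
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate < 1.0):
            raise ValueError("rate must lie in [0, 1)")


def random_hash_stream(n: int, seed: int) -> HashSequence:
    """n i.i.d. Uniform(0, 1) hash values as a HashSequence (k = 1)."""
    rng = np.random.default_rng(seed)
    return hash_stream_from_values(rng.random(n), name=f"stream-{seed}")


def random_dna(n: int, seed: int, gc: float = 0.5) -> str:
    """Random DNA of length n with the given expected GC fraction."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def _has_duplicate_kmers(arr: np.ndarray, k: int) -> bool:
    from numpy.lib.stride_tricks import sliding_window_view

    if len(arr) < k:
        return False
    km = sliding_window_view(arr, k)
    view = np.ascontiguousarray(km).view(
        np.dtype((np.void, km.dtype.itemsize * k))
    ).ravel()
    return len(np.unique(view)) < len(view)


def mutate(seq: str, spec: MutationSpec) -> tuple[str, float, np.ndarray]:
    """Substitute exactly round(rate * len(seq)) positions of a sequence.

    Returns (mutated sequence, realized divergence, mutated positions).
    Substituted bases are drawn uniformly from the three alternatives.
    With ``forbid_duplicate_kmers`` the substitution set is resampled until
    neither sequence contains a repeated k-mer; retry exhaustion raises
    (use a longer or less repetitive input).
    """
    L = len(seq)
    n_mut = int(round(spec.rate * L))
    rng = np.random.default_rng(spec.seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if n_mut == 0:
        return seq, 0.0, np.empty(0, dtype=np.int64)
    for _ in range(spec.max_retries):
        out = arr.copy()
        pos = rng.choice(L, size=n_mut, replace=False)
        for p in pos:
            alts = _BASES[_BASES != out[p]]
            out[p] = alts[rng.integers(3)]
        if spec.forbid_duplicate_kmers and (
            _has_duplicate_kmers(out, spec.k) or _has_duplicate_kmers(arr, spec.k)
        ):
            if _has_duplicate_kmers(arr, spec.k):
                raise ValueError(
                    "original sequence already contains duplicate k-mers; "
                    "use a longer or more random sequence"
                )
            continue
        mutated = out.tobytes().decode("ascii")
        return mutated, n_mut / L, np.sort(pos)
    raise ValueError(
        "could not avoid duplicate k-mers after retries; "
        "use a longer or more random sequence"
    )


def write_mutation_fixture(
    out_dir: str | Path,
    seq: str,
    spec: MutationSpec,
    name: str = "synthetic",
) -> dict:
    """Emit paired FASTA files plus a truth TSV for a mutated copy.

    Returns paths and the realized divergence. The truth table lists one
    row per mutated position: position, reference base, alternate base.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mut, div, pos = mutate(seq, spec)
    ref_fa = out_dir / f"{name}_ref.fa"
    qry_fa = out_dir / f"{name}_mut.fa"
    truth = out_dir / f"{name}_truth.tsv"
    write_fasta(ref_fa, [(f"{name}_ref", seq)])
    write_fasta(qry_fa, [(f"{name}_mut", mut)])
    with open(truth, "w") as fh:
        fh.write(f"#divergence={div}\n")
        fh.write("position\tref_base\talt_base\n")
        for p in pos.tolist():
            fh.write(f"{p}\t{seq[p]}\t{mut[p]}\n")
    return {"ref": ref_fa, "query": qry_fa, "truth": truth, "divergence": div}
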