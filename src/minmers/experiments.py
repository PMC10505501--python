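"""Replicable ANI-prediction study on ideal (duplicate-free) sequences.

Segments of a random reference are copied, point-mutated at a controlled
rate r, and mapped back; the predicted divergence (1 - ANI) of the best
mapping is compared with r across replicates. A minimizer-based
winnowed-minhash estimate (window floor(w/s), same sketch size) is
computed per segment at the true offset as the biased baseline the minmer
scheme replaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hashing import kmer_hash_sequence
from .mapper import MapParams, map_sequence
from .simdata import MutationSpec, mutate, random_dna
from .sketch import divergence_from_jaccard, winnowed_minhash_jaccard
from .winnow import WinnowParams, build_minmer_index


def divergence_prediction_experiment(
    rates=(0.01, 0.05, 0.10),
    n_segments: int = 100,
    ref_len: int = 1_000_000,
    segment_len: int = 10_018,
    k: int = 19,
    w: int = 10_000,
    s: int = 78,
    seed: int = 11,
    hash_seed: int = 42,
    baseline: bool = True,
    map_params: MapParams | None = None,
) -> pd.DataFrame:
    """Map mutated reference segments back and record predicted divergences.

    Returns a DataFrame with one row per (rate, segment): the true rate,
    the minmer pipeline's predicted divergence (NaN if the segment did not
    map), and optionally the minimizer-baseline prediction at the true
    offset. Segments whose original copy happens to contain a duplicate
    k-mer are redrawn, keeping the ideal-sequence assumption exact.
    """
    params = map_params or MapParams()
    ref = random_dna(ref_len, seed=seed)
    hs = kmer_hash_sequence(ref, k, seed=hash_seed, canonical=True, name="ref")
    index = build_minmer_index(hs, WinnowParams(w=w, s=s, k=k), seed=hash_seed)
    rng = np.random.default_rng(seed + 1)
    w_prime = max(2, w // s)
    rows = []
    for r in rates:
        done = 0
        while done < n_segments:
            off = int(rng.integers(0, ref_len - segment_len))
            seg = ref[off : off + segment_len]
            spec = MutationSpec(
                rate=r,
                seed=int(rng.integers(2**31)),
                forbid_duplicate_kmers=True,
                k=k,
            )
            try:
                mut, true_div, _ = mutate(seg, spec)
            except ValueError:
                continue  # duplicate k-mer in the draw; take another segment
            mappings = map_sequence(f"seg_{r}_{done}", mut, index, params)
            pred = (
                1.0 - max(mappings, key=lambda m: m.jaccard).ani
                if mappings
                else np.nan
            )
            row = {
                "rate": r,
                "segment": done,
                "offset": off,
                "true_divergence": true_div,
                "predicted_divergence": pred,
            }
            if baseline:
                qh = kmer_hash_sequence(mut, k, seed=hash_seed).hashes
                rh = hs.hashes[off : off + segment_len - k + 1]
                _, _, jb = winnowed_minhash_jaccard(qh, rh, w_prime, s)
                row["baseline_divergence"] = (
                    divergence_from_jaccard(jb, k) if jb > 0 else 1.0
                )
            rows.append(row)
            done += 1
    return pd.DataFrame(rows)
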