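"""MinHash sketching and Mash-distance reference prefiltering.

Each sample is compared with every catalogue genome through bottom-s
MinHash sketches of canonical k-mers; genomes within a Mash distance of
0.10 (~90% identity) are retained as the per-sample reference set.

The k-mer hash is a fixed 64-bit mix (splitmix64 finalizer) of the
2-bit-packed canonical k-mer, salted with a version constant so sketches
are portable across runs and machines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: salt fixed forever; bump only with a sketch-format version change
HASH_VERSION_SALT = np.uint64(0x9E3779B97F4A7C15)

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of a sequence set's canonical k-mers."""

    k: int
    s: int
    hashes: tuple[int, ...]  # sorted ascending, length <= s

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise ValueError("sketch larger than its capacity")
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + HASH_VERSION_SALT).astype(np.uint64)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """2-bit-packed canonical k-mer codes of one sequence (N-containing
    windows are dropped)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    windows = windows[valid].astype(np.uint64)
    if windows.size == 0:
        return np.empty(0, dtype=np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    with np.errstate(over="ignore"):
        fwd = windows @ powers
        rc = (np.uint64(3) - windows)[:, ::-1] @ powers
    return np.minimum(fwd, rc)


def sketch_sequences(
    sequences: Iterable[str], k: int = 21, s: int = 1000
) -> Sketch:
    """Bottom-s sketch over the union of canonical k-mers of ``sequences``.

    ``k`` must be odd so no k-mer equals its own reverse complement and
    canonicalisation is unambiguous.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    all_hashes = []
    n_usable = 0
    for seq in sequences:
        codes = canonical_kmer_codes(seq, k)
        if codes.size:
            n_usable += 1
            all_hashes.append(_splitmix64(codes))
    if not all_hashes:
        raise ValueError(f"no sequence of length >= k={k} to sketch")
    hashes = np.unique(np.concatenate(all_hashes))
    return Sketch(k=k, s=s, hashes=tuple(int(h) for h in hashes[:s]))


def sketch_sequence(sequence: str, k: int = 21, s: int = 1000) -> Sketch:
    return sketch_sequences([sequence], k=k, s=s)


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance d = -(1/k) ln(2j / (1+j)) from the merged-bottom-s
    Jaccard estimate j; disjoint sketches give the defined cap of 1.0."""
    if a.k != b.k:
        raise ValueError(f"k-mer size mismatch: {a.k} != {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(np.asarray(a.hashes, dtype=np.uint64),
                       np.asarray(b.hashes, dtype=np.uint64))
    merged = union[:s]
    inter = np.intersect1d(merged, np.asarray(a.hashes, dtype=np.uint64))
    inter = np.intersect1d(inter, np.asarray(b.hashes, dtype=np.uint64))
    denom = len(merged)
    if denom == 0:
        return 1.0
    j = len(inter) / denom
    if j == 0.0:
        return 1.0
    d = -math.log(2.0 * j / (1.0 + j)) / a.k
    return min(max(d, 0.0), 1.0)


def exact_jaccard_distance(seq_a: str, seq_b: str, k: int = 21) -> float:
    """Mash-formula distance from the exact Jaccard index of the full
    canonical k-mer sets (no sketching) — the sketch-free reference."""
    set_a = set(canonical_kmer_codes(seq_a, k).tolist())
    set_b = set(canonical_kmer_codes(seq_b, k).tolist())
    if not set_a and not set_b:
        return 0.0
    j = len(set_a & set_b) / len(set_a | set_b)
    if j == 0.0:
        return 1.0
    return min(-math.log(2.0 * j / (1.0 + j)) / k, 1.0)


def select_references(
    genome_sketches: dict[str, Sketch],
    sample_sketch: Sketch,
    max_distance: float = 0.10,
) -> list[tuple[str, float]]:
    """Catalogue genomes within ``max_distance`` of the sample, in
    catalogue order, as (genome_id, distance) pairs."""
    if not genome_sketches:
        logger.warning("empty genome catalogue: nothing to prefilter")
        return []
    retained = []
    for gid, sk in genome_sketches.items():
        d = mash_distance(sk, sample_sketch)
        if d <= max_distance:
            retained.append((gid, d))
    return retained
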