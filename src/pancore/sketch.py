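"""Bottom-s MinHash sketching of genomes and Mash-style distance estimation.

A genome is reduced to the ``s`` smallest 64-bit hash values of its canonical
k-mers (the lexicographically smaller of each k-mer and its reverse
complement).  Two sketches estimate the Jaccard index of the underlying k-mer
sets with the merged bottom-s estimator, which the Mash distance

    D = -(1/k) * ln(2j / (1 + j))

converts into an estimate of per-base divergence: for closely related genomes
D approximates 1 - ANI.  A pair sharing no k-mers is assigned the capped
distance 1.0.

Hashing uses a fixed splitmix64-style mixer over 2-bit-packed k-mers, so
sketches are deterministic across runs and platforms for a given
``hash_seed``.  Only A/C/G/T participate; any window containing another
character is skipped, matching Mash's behaviour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .distances import DistanceMatrix

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10_000
DEFAULT_HASH_SEED = 42

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


@dataclass
class Sketch:
    """Bottom-s MinHash signature of one genome's canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray = field(repr=False)  # sorted uint64, len <= s

    def __len__(self) -> int:
        return len(self.hashes)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit-packed codes of all valid k-mer windows (k <= 32)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 32:
        raise ValueError("k must be <= 32 to fit a 64-bit packing")
    b = _encode(seq)
    n = len(b)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    invalid = (b == 255).astype(np.int64)
    bad = np.cumsum(np.concatenate(([0], invalid)))
    valid = (bad[k:] - bad[:-k]) == 0
    b64 = np.where(b == 255, 0, b).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        win = b64[j : j + m]
        fwd = (fwd << np.uint64(2)) | win
        rev |= (np.uint64(3) - win) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[valid]


def canonical_kmers(seq: str, k: int):
    """Yield the canonical form of each valid k-mer window of ``seq``.

    The canonical form is the lexicographically smaller of the k-mer and its
    reverse complement; windows containing characters other than A/C/G/T are
    skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    su = seq.upper()
    for i in range(len(su) - k + 1):
        kmer = su[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = kmer.translate(_COMPLEMENT)[::-1]
        yield min(kmer, rc)


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Vectorised 64-bit finaliser (splitmix64), keyed by ``seed``."""
    z = x + np.uint64(seed * 0x9E3779B97F4A7C15 & 0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _sorted_unique(x: np.ndarray) -> np.ndarray:
    if len(x) == 0:
        return x
    x = np.sort(x)
    return x[np.concatenate(([True], x[1:] != x[:-1]))]


def make_sketch(
    seq: str,
    genome_id: str = "",
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch a genome: the ``s`` smallest distinct hashes of its canonical k-mers."""
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    if len(seq) < k:
        warnings.warn(
            f"sequence of genome {genome_id!r} is shorter than k={k}; empty sketch",
            stacklevel=2,
        )
        return Sketch(genome_id, k, s, hash_seed, np.empty(0, dtype=np.uint64))
    codes = _sorted_unique(_kmer_codes(seq, k))
    with np.errstate(over="ignore"):
        hashes = _sorted_unique(_splitmix64(codes, hash_seed))
    return Sketch(genome_id, k, s, hash_seed, hashes[:s])


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s Jaccard estimate: shared fraction of the s smallest
    hashes of the union of the two sketches."""
    if a.k != b.k or a.s != b.s:
        raise ValueError(
            f"sketch parameters differ: (k={a.k}, s={a.s}) vs (k={b.k}, s={b.s})"
        )
    union = np.union1d(a.hashes, b.hashes)[: a.s]
    if len(union) == 0:
        return 0.0
    shared = np.intersect1d(union, np.intersect1d(a.hashes, b.hashes))
    return len(shared) / len(union)


def mash_distance(j: float, k: int) -> float:
    """Mash distance D = -(1/k) ln(2j/(1+j)); j=0 is capped at 1."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate {j} outside [0, 1]")
    if j == 0.0:
        return 1.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(max(d, 0.0), 1.0)


def pairwise_distances(sketches: list[Sketch]) -> DistanceMatrix:
    """All-vs-all Mash distances between sketches sharing (k, s)."""
    if not sketches:
        raise ValueError("no sketches given")
    k, s = sketches[0].k, sketches[0].s
    for sk in sketches:
        if sk.k != k or sk.s != s:
            raise ValueError("all sketches must share k and sketch size")
    n = len(sketches)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = mash_distance(jaccard_estimate(sketches[i], sketches[j]), k)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=[sk.genome_id for sk in sketches], values=values)
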