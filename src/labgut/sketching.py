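"""Canonical k-mer MinHash sketching and Mash-style genome distances.

A genome is reduced to the set of its canonical k-mers (the lexicographic
minimum of each k-mer and its reverse complement), each k-mer is mapped to a
64-bit hash, and the sketch keeps the ``s`` smallest hash values ("bottom-s"
MinHash).  The Jaccard index of two k-mer sets is estimated from the merged
bottom-s sketch and converted to an approximate per-base divergence with the
Mash formula

    D = -(1/k) * ln( 2j / (1+j) ),

capped at 1 (a Jaccard of 0 saturates to distance 1).  For closely related
genomes D approximates 1 - ANI.

k-mers are packed into 64-bit integers with 2 bits per base (A=0, C=1, G=2,
T=3), which limits k to 32 — the same ceiling Mash itself uses.  Hashing is a
seeded splitmix64-style finalizer applied to the packed code, so sketches are
reproducible across platforms for a fixed ``hash_seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MAX_K",
    "Sketch",
    "DistanceMatrix",
    "canonical_kmers",
    "hash_kmers",
    "sketch",
    "sketch_sequences",
    "jaccard_estimate",
    "mash_distance",
    "pairwise_distances",
]

MAX_K = 32

# base -> 2-bit code; anything outside ACGT (case-insensitive) -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit finalizer (splitmix64) applied elementwise."""
    with np.errstate(over="ignore"):
        z = x + (np.uint64(seed % (1 << 64)) * _GOLDEN + _GOLDEN)
        z = (z ^ (z >> np.uint64(30))) * _MIX1
        z = (z ^ (z >> np.uint64(27))) * _MIX2
        return z ^ (z >> np.uint64(31))


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K} (2-bit packed codes), got {k}")


def _canonical_codes(sequence: str, k: int) -> np.ndarray:
    """Packed canonical k-mer codes of every valid window of one contig.

    Windows containing any non-ACGT symbol are skipped; contigs shorter than
    k contribute nothing.  Returns a (possibly empty) uint64 array with one
    entry per valid window (not deduplicated).
    """
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid8 = (codes != 255)
    # window is valid iff all k positions are valid
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        ok &= valid8[i : n + i]
    c = codes.astype(np.uint64)
    comp = np.uint64(3) - c  # complement; garbage at invalid positions (masked)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd |= c[i : n + i] << np.uint64(2 * (k - 1 - i))
        rev |= comp[i : n + i] << np.uint64(2 * i)
    canon = np.minimum(fwd, rev)
    return canon[ok]


def _decode(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _encode_kmer(kmer: str) -> int:
    codes = _CODE[np.frombuffer(kmer.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer!r}")
    out = 0
    for c in codes:
        out = (out << 2) | int(c)
    return out


def _as_sequences(sequences: str | Iterable[str]) -> list[str]:
    if isinstance(sequences, str):
        return [sequences]
    return list(sequences)


def canonical_kmers(sequences: str | Iterable[str], k: int) -> set[str]:
    """Set of canonical k-mers of one or more contigs.

    The canonical form of a k-mer is the lexicographic minimum of the k-mer
    and its reverse complement.  Windows containing any non-ACGT symbol are
    skipped.
    """
    _check_k(k)
    out: set[str] = set()
    for seq in _as_sequences(sequences):
        for code in np.unique(_canonical_codes(seq, k)):
            out.add(_decode(int(code), k))
    return out


def hash_kmers(kmers: Iterable[str], k: int, hash_seed: int = 42) -> np.ndarray:
    """Sorted unique 64-bit hashes of (canonicalized) k-mers."""
    _check_k(k)
    enc = []
    for kmer in kmers:
        if len(kmer) != k:
            raise ValueError(f"k-mer {kmer!r} has length {len(kmer)}, expected {k}")
        code = _encode_kmer(kmer)
        rc = _encode_kmer(_revcomp(kmer))
        enc.append(min(code, rc))
    if not enc:
        return np.empty(0, dtype=np.uint64)
    return np.unique(_splitmix64(np.asarray(enc, dtype=np.uint64), hash_seed))


def _revcomp(kmer: str) -> str:
    return kmer.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of one genome's canonical k-mer set."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted, unique, uint64, len <= s
    n_distinct_kmers: int
    hash_seed: int = 42

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        object.__setattr__(self, "hashes", h)
        if h.size > self.s:
            raise ValueError("sketch holds more hashes than its capacity s")
        if h.size > 1 and not (h[1:] > h[:-1]).all():
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size < min(self.s, self.n_distinct_kmers):
            raise ValueError("sketch is under-filled relative to n_distinct_kmers")

    @property
    def is_empty(self) -> bool:
        return self.hashes.size == 0


def sketch(kmer_set: Iterable[str], s: int, hash_seed: int = 42,
           *, k: int | None = None, genome_id: str = "") -> Sketch:
    """Bottom-s sketch of an explicit canonical k-mer set.

    ``k`` is inferred from the first k-mer when not given.  An empty k-mer
    set yields an empty sketch, which is flagged unusable for distances.
    """
    if s < 1:
        raise ValueError(f"sketch size s must be >= 1, got {s}")
    kmers = list(kmer_set)
    if k is None:
        if not kmers:
            raise ValueError("cannot infer k from an empty k-mer set; pass k=")
        k = len(kmers[0])
    _check_k(k)
    hashes = hash_kmers(kmers, k, hash_seed)
    n_distinct = hashes.size
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=hashes[:s],
                  n_distinct_kmers=n_distinct, hash_seed=hash_seed)


def sketch_sequences(sequences: str | Iterable[str], k: int = 21, s: int = 10000,
                     hash_seed: int = 42, genome_id: str = "") -> Sketch:
    """Sketch a genome given as one or more contig sequences.

    Equivalent to ``sketch(canonical_kmers(sequences, k), s, hash_seed)`` but
    avoids materializing k-mer strings.
    """
    _check_k(k)
    if s < 1:
        raise ValueError(f"sketch size s must be >= 1, got {s}")
    parts = [_canonical_codes(seq, k) for seq in _as_sequences(sequences)]
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if codes.size == 0:
        return Sketch(genome_id=genome_id, k=k, s=s,
                      hashes=np.empty(0, dtype=np.uint64),
                      n_distinct_kmers=0, hash_seed=hash_seed)
    hashes = np.unique(_splitmix64(np.unique(codes), hash_seed))
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=hashes[:s],
                  n_distinct_kmers=hashes.size, hash_seed=hash_seed)


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k:
        raise ValueError(f"incompatible sketches: k={a.k} vs k={b.k}")
    if a.s != b.s:
        raise ValueError(f"incompatible sketches: s={a.s} vs s={b.s}")
    if a.hash_seed != b.hash_seed:
        raise ValueError(
            f"incompatible sketches: hash_seed={a.hash_seed} vs {b.hash_seed}")


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s MinHash estimate of the Jaccard index.

    Let U be the s smallest values of the merged hash sets; the estimate is
    |U ∩ A ∩ B| / |U|.  Exact whenever s >= |union of both k-mer sets|.
    """
    _check_compatible(a, b)
    if a.is_empty or b.is_empty:
        raise ValueError("cannot estimate Jaccard with an empty sketch")
    merged = np.union1d(a.hashes, b.hashes)  # sorted unique
    u = merged[: a.s]
    shared = int(np.count_nonzero(np.isin(u, a.hashes) & np.isin(u, b.hashes)))
    return shared / u.size


def mash_distance(j: float, k: int) -> float:
    """Mash distance D = -(1/k) ln(2j/(1+j)), capped at 1; j=0 maps to 1."""
    _check_k(k)
    if not (0.0 <= j <= 1.0):
        raise ValueError(f"Jaccard index must be in [0, 1], got {j}")
    if j == 0.0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return float(min(max(d, 0.0), 1.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genome distance matrix with labelled rows."""

    ids: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any() or (v > 1.0 + 1e-12).any():
            raise ValueError("distance entries must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_distances(genomes: Mapping[str, str | Sequence[str]] | Iterable[tuple[str, str | Sequence[str]]],
                       k: int = 21, s: int = 10000, hash_seed: int = 42) -> DistanceMatrix:
    """All-vs-all Mash distances for a collection of genomes.

    ``genomes`` maps genome id -> sequence (or list of contig sequences).
    Genomes with no valid k-mer (empty sketch) are excluded with a warning
    and listed in ``DistanceMatrix.excluded``.
    """
    items = list(genomes.items()) if isinstance(genomes, Mapping) else list(genomes)
    sketches: list[Sketch] = []
    excluded: list[str] = []
    for gid, seqs in items:
        sk = sketch_sequences(seqs, k=k, s=s, hash_seed=hash_seed, genome_id=gid)
        if sk.is_empty:
            warnings.warn(f"genome {gid!r} has no valid k-mers; excluded from distances")
            excluded.append(gid)
        else:
            sketches.append(sk)
    if len(sketches) < 2:
        raise ValueError("need at least 2 usable genomes for pairwise distances")
    n = len(sketches)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dist = mash_distance(jaccard_estimate(sketches[i], sketches[j]), k)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=[sk.genome_id for sk in sketches], values=d,
                          excluded=excluded)
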