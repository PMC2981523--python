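"""Stage 1: k-mer occurrence envelopes.

For every k-mer K of length 1..5 (1,364 in total) and every training TSS
window, count the overlapping occurrences ``u`` of K in the upstream half
[-100,-1] and ``d`` in the downstream half [+1,+100]; both lie in
[0, 100+1-k].  Training records, per k-mer, the observed envelope
min(d)/max(d) conditional on each observed u, and min(u)/max(u) conditional
on each observed d.  A window passes the stage only if, for all 1,364
k-mers, its (u, d) pair satisfies both conditional bounds; a u (or d) value
never observed in training fails the constraint outright.  By construction
every training window passes (100% training sensitivity), and envelopes only
widen as positives are added.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .seq_windows import TssWindow

ALPHABET = "ACGT"
K_MAX = 5
#: number of k-mer indices that precede length-k k-mers in enumeration order
KMER_OFFSET = {1: 0, 2: 4, 3: 20, 4: 84, 5: 340}
N_KMERS = 1364
HALF_LEN = 100

# sentinels for unobserved keys: the interval is empty, so any value fails
_UNSEEN_MIN = np.int16(HALF_LEN + 1)
_UNSEEN_MAX = np.int16(-1)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes A,C,G,T -> 0..3; anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return bytes(_DECODE[codes]).decode()


def enumerate_kmers(k_max: int = K_MAX) -> list[str]:
    """All k-mers of lengths 1..k_max, shorter first, lexicographic within."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    out = []
    for k in range(1, k_max + 1):
        out.extend("".join(p) for p in itertools.product(ALPHABET, repeat=k))
    return out


def kmer_index(kmer: str) -> int:
    """Index of a k-mer in :func:`enumerate_kmers` order."""
    k = len(kmer)
    idx = 0
    for c in kmer:
        idx = idx * 4 + ALPHABET.index(c)
    return KMER_OFFSET[k] + idx


def count_overlapping(segment: str, kmer: str) -> int:
    """Number of (overlapping) occurrences of ``kmer`` in ``segment``."""
    k = len(kmer)
    if k == 0 or k > len(segment):
        return 0
    return sum(1 for i in range(len(segment) - k + 1) if segment[i : i + k] == kmer)


def kmer_count_matrix(codes: np.ndarray) -> np.ndarray:
    """Per-row counts of all 1,364 k-mers for a (n, L) code matrix.

    Rows must contain only codes 0..3.  Returns an (n, 1364) int32 matrix in
    enumeration order; overlapping occurrences are counted.
    """
    codes = np.ascontiguousarray(codes)
    n, length = codes.shape
    ids = []
    for k in range(1, K_MAX + 1):
        width = length - k + 1
        if width <= 0:
            continue
        v = np.zeros((n, width), dtype=np.int32)
        for t in range(k):
            v = v * 4 + codes[:, t : t + width]
        ids.append(v + KMER_OFFSET[k])
    flat = np.concatenate(ids, axis=1)
    flat = flat + (np.arange(n, dtype=np.int64)[:, None] * N_KMERS)
    counts = np.bincount(flat.ravel(), minlength=n * N_KMERS)
    return counts.reshape(n, N_KMERS).astype(np.int32)


@dataclass
class KmerEnvelope:
    """Observed (u, d) occurrence envelope for one k-mer."""

    kmer: str
    d_bounds: Dict[int, Tuple[int, int]]  # u -> (min_d, max_d)
    u_bounds: Dict[int, Tuple[int, int]]  # d -> (min_u, max_u)


@dataclass
class KmerEnvelopeSet:
    """Envelopes for all 1,364 k-mers, plus dense lookup tables.

    The dense tables are shaped (1364, 101), indexed by [k-mer, count];
    unobserved counts hold an empty interval (min > max) so lookups there
    always fail the constraint.
    """

    min_d: np.ndarray
    max_d: np.ndarray
    min_u: np.ndarray
    max_u: np.ndarray
    kmers: list[str] = field(default_factory=enumerate_kmers)

    def envelope(self, kmer: str) -> KmerEnvelope:
        """Sparse view of one k-mer's envelope (observed keys only)."""
        j = kmer_index(kmer)
        d_bounds = {
            int(u): (int(self.min_d[j, u]), int(self.max_d[j, u]))
            for u in np.flatnonzero(self.max_d[j] >= 0)
        }
        u_bounds = {
            int(d): (int(self.min_u[j, d]), int(self.max_u[j, d]))
            for d in np.flatnonzero(self.max_u[j] >= 0)
        }
        return KmerEnvelope(kmer, d_bounds, u_bounds)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        entries = []
        for kmer in self.kmers:
            env = self.envelope(kmer)
            entries.append(
                {
                    "kmer": kmer,
                    "d_bounds": {str(u): list(v) for u, v in sorted(env.d_bounds.items())},
                    "u_bounds": {str(d): list(v) for d, v in sorted(env.u_bounds.items())},
                }
            )
        return {"kmers": entries}

    @classmethod
    def from_dict(cls, data: dict) -> "KmerEnvelopeSet":
        kmers = enumerate_kmers()
        shape = (N_KMERS, HALF_LEN + 1)
        min_d = np.full(shape, _UNSEEN_MIN, dtype=np.int16)
        max_d = np.full(shape, _UNSEEN_MAX, dtype=np.int16)
        min_u = np.full(shape, _UNSEEN_MIN, dtype=np.int16)
        max_u = np.full(shape, _UNSEEN_MAX, dtype=np.int16)
        entries = data["kmers"]
        if len(entries) != N_KMERS:
            raise ValueError(f"expected {N_KMERS} envelopes, got {len(entries)}")
        for entry in entries:
            j = kmer_index(entry["kmer"])
            for u, (lo, hi) in entry["d_bounds"].items():
                min_d[j, int(u)] = lo
                max_d[j, int(u)] = hi
            for d, (lo, hi) in entry["u_bounds"].items():
                min_u[j, int(d)] = lo
                max_u[j, int(d)] = hi
        return cls(min_d, max_d, min_u, max_u, kmers)


def _scatter_minmax(keys: np.ndarray, values: np.ndarray, size: int):
    """Grouped min/max of ``values`` by integer ``keys`` (sort + reduceat)."""
    order = np.argsort(keys, kind="stable")
    k = keys[order]
    v = values[order]
    starts = np.flatnonzero(np.r_[True, k[1:] != k[:-1]])
    mins = np.minimum.reduceat(v, starts)
    maxs = np.maximum.reduceat(v, starts)
    out_min = np.full(size, _UNSEEN_MIN, dtype=np.int16)
    out_max = np.full(size, _UNSEEN_MAX, dtype=np.int16)
    out_min[k[starts]] = mins
    out_max[k[starts]] = maxs
    return out_min, out_max


def windows_to_counts(windows: Sequence[TssWindow]) -> Tuple[np.ndarray, np.ndarray]:
    """(upstream, downstream) k-mer count matrices for a window list."""
    codes = np.stack([encode(w.seq) for w in windows])
    return kmer_count_matrix(codes[:, :HALF_LEN]), kmer_count_matrix(codes[:, HALF_LEN:])


def train_envelopes(positives: Sequence[TssWindow]) -> KmerEnvelopeSet:
    """Learn per-k-mer (u, d) envelopes from positive windows."""
    if len(positives) == 0:
        raise ValueError("cannot train envelopes on an empty positive set")
    up, down = windows_to_counts(positives)
    return envelopes_from_counts(up, down)


def envelopes_from_counts(up: np.ndarray, down: np.ndarray) -> KmerEnvelopeSet:
    width = HALF_LEN + 1
    base = np.arange(N_KMERS, dtype=np.int64) * width
    keys_u = (base[None, :] + up).ravel()
    keys_d = (base[None, :] + down).ravel()
    vals_d = down.ravel().astype(np.int16)
    vals_u = up.ravel().astype(np.int16)
    min_d, max_d = _scatter_minmax(keys_u, vals_d, N_KMERS * width)
    min_u, max_u = _scatter_minmax(keys_d, vals_u, N_KMERS * width)
    shape = (N_KMERS, width)
    return KmerEnvelopeSet(
        min_d.reshape(shape), max_d.reshape(shape),
        min_u.reshape(shape), max_u.reshape(shape),
    )


def classify_counts(up: np.ndarray, down: np.ndarray, env: KmerEnvelopeSet) -> np.ndarray:
    """Vectorized stage-1 decision for (n, 1364) count matrices."""
    cols = np.arange(N_KMERS)
    ok = (
        (env.min_d[cols, up] <= down)
        & (down <= env.max_d[cols, up])
        & (env.min_u[cols, down] <= up)
        & (up <= env.max_u[cols, down])
    )
    return ok.all(axis=1)


def classify_kmer_stage(window: TssWindow, env: KmerEnvelopeSet) -> bool:
    """True iff the window satisfies all 1,364 k-mer envelope constraints."""
    up, down = windows_to_counts([window])
    return bool(classify_counts(up, down, env)[0])
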