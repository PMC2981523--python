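"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the package's vectorized paths:
they count k-mers by substring slicing, score PWMs by per-position python
sums, and check envelope constraints against the sparse per-k-mer maps.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

import tssmask as tm
from tssmask.pipeline import TrainConfig, train_masker
from tssmask.synth import SynthConfig, generate_corpus


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_corpus() -> tm.TrainingCorpus:
    return generate_corpus(SynthConfig(n_pos=400, n_neg=400, seed=11))


@pytest.fixture(scope="session")
def small_model(small_corpus) -> tm.MaskerModel:
    return train_masker(small_corpus, TrainConfig(seed=11))


@pytest.fixture(scope="session")
def random_windows() -> list:
    """600 background windows, independent of any training corpus."""
    corpus = generate_corpus(SynthConfig(n_pos=0, n_neg=600, gc_background=0.5, seed=77))
    return corpus.negatives


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_count(segment: str, kmer: str) -> int:
    """Position-scan occurrence count (overlaps allowed)."""
    k = len(kmer)
    return sum(1 for i in range(len(segment) - k + 1) if segment[i : i + k] == kmer)


def oracle_kmer_counts(half: str) -> Counter:
    """Counter of all 1..5-mer substrings of a window half."""
    c: Counter = Counter()
    for k in range(1, 6):
        for i in range(len(half) - k + 1):
            c[half[i : i + k]] += 1
    return c


def oracle_envelope_pass(window: tm.TssWindow, env: tm.KmerEnvelopeSet) -> bool:
    """All-1,364-constraints check via the sparse envelope maps."""
    up = oracle_kmer_counts(window.seq[:100])
    down = oracle_kmer_counts(window.seq[100:])
    for kmer in tm.enumerate_kmers(5):
        u, d = up[kmer], down[kmer]
        e = env.envelope(kmer)
        if u not in e.d_bounds or d not in e.u_bounds:
            return False
        lo_d, hi_d = e.d_bounds[u]
        lo_u, hi_u = e.u_bounds[d]
        if not (lo_d <= d <= hi_d and lo_u <= u <= hi_u):
            return False
    return True


def oracle_pwm_score(seq: str, pwm: tm.Pwm) -> float:
    """Per-position summation of matrix entries."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(pwm.weights[idx[b], j] for j, b in enumerate(seq))
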