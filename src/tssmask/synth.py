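"""Synthetic corpora and genomes with TSS-like compositional structure.

Real mammalian TSS neighbourhoods differ from bulk genomic DNA in exactly
the axes the four-stage chain reads: locally elevated GC around the start
site, a pyrimidine-purine initiator bias at [-1,+1], and (for a fraction of
promoters) a fixed upstream box motif.  The generator plants those three
signals on an i.i.d. background so that every stage, and the end-to-end
scanner, can be exercised without any genome download.  Negatives are pure
background composition, mirroring the random-DNA reference sets used to
train the discriminative stages.

Defaults: background GC 0.42 (mammalian genome-scale composition), +0.15 GC
inside [-40,+40] of positives, initiator probability 0.8, "TATAAA" planted
at position -30 in 30% of positives.  All draws flow from one seeded
generator, so corpora and genomes are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kmer_stage import decode, encode
from .seq_windows import (
    CoordinateRecord,
    TrainingCorpus,
    TssWindow,
    window_pos_to_index,
)

WINDOW_LEN = 200
#: 0-based index span of the GC-boosted core [-40,+40] inside a window
CORE_START, CORE_END = 60, 140

_PYRIMIDINE = np.array([1, 3])  # C, T
_PURINE = np.array([0, 2])      # A, G


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; probabilities are per-window Bernoulli rates."""

    n_pos: int
    n_neg: int
    gc_background: float = 0.42
    core_gc_boost: float = 0.15
    inr_strength: float = 0.8
    box_motif: Optional[str] = "TATAAA"
    box_offset: int = -30
    box_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.gc_background, self.inr_strength, self.box_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.gc_background + self.core_gc_boost < 1.0:
            raise ValueError("core GC probability must lie in (0, 1)")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _draw_positive_codes(rng: np.random.Generator, cfg: SynthConfig, n: int) -> np.ndarray:
    """n positive windows as an (n, 200) code matrix."""
    probs = np.tile(_base_probs(cfg.gc_background), (WINDOW_LEN, 1))
    probs[CORE_START:CORE_END] = _base_probs(cfg.gc_background + cfg.core_gc_boost)
    cum = np.cumsum(probs, axis=1)[:, :3]
    u = rng.random((n, WINDOW_LEN))
    codes = (u[:, :, None] >= cum[None, :, :]).sum(axis=2).astype(np.uint8)

    has_inr = rng.random(n) < cfg.inr_strength
    codes[has_inr, 99] = rng.choice(_PYRIMIDINE, size=int(has_inr.sum()))
    codes[has_inr, 100] = rng.choice(_PURINE, size=int(has_inr.sum()))

    if cfg.box_motif:
        has_box = rng.random(n) < cfg.box_fraction
        start = window_pos_to_index(cfg.box_offset)
        codes[has_box, start : start + len(cfg.box_motif)] = encode(cfg.box_motif)
    return codes


def _draw_background_codes(rng: np.random.Generator, gc: float, n: int, length: int) -> np.ndarray:
    cum = np.cumsum(_base_probs(gc))[:3]
    u = rng.random((n, length))
    return (u[:, :, None] >= cum[None, None, :]).sum(axis=2).astype(np.uint8)


def generate_corpus(cfg: SynthConfig) -> TrainingCorpus:
    """Positive and negative training windows under the configured model."""
    rng = np.random.default_rng(cfg.seed)
    pos_codes = _draw_positive_codes(rng, cfg, cfg.n_pos)
    neg_codes = _draw_background_codes(rng, cfg.gc_background, cfg.n_neg, WINDOW_LEN)
    positives = [TssWindow(decode(c), label="positive") for c in pos_codes]
    negatives = [TssWindow(decode(c), label="negative") for c in neg_codes]
    return TrainingCorpus(positives, negatives)


def generate_genome(
    length: int,
    gc: float,
    planted_tss: Sequence[Tuple[int, str]],
    cfg: SynthConfig,
    seed: int,
) -> Tuple[str, List[CoordinateRecord]]:
    """A background sequence with positive-model patches at planted TSSs.

    Each planted (pos, strand) receives a full 200-nt positive window
    embedded strand-aware (the minus-strand patch is the reverse complement
    of the drawn window).  Patches must not overlap and must sit at least
    100 nt from either end.  Returns the sequence and the ground truth as
    coordinate records.
    """
    rng = np.random.default_rng(seed)
    genome = _draw_background_codes(rng, gc, 1, length)[0]
    spans = []
    for pos, strand in planted_tss:
        if strand == "+":
            span = (pos - 100, pos + 100)
        elif strand == "-":
            span = (pos - 99, pos + 101)
        else:
            raise ValueError(f"bad strand {strand!r}")
        if span[0] < 0 or span[1] > length:
            raise ValueError(f"planted TSS at {pos}{strand} too close to an end")
        spans.append(span)
    for (s1, e1), (s2, e2) in zip(sorted(spans), sorted(spans)[1:]):
        if s2 < e1:
            raise ValueError("planted patches overlap")

    truth = []
    for (pos, strand), (start, end) in zip(planted_tss, spans):
        wcodes = _draw_positive_codes(rng, cfg, 1)[0]
        if strand == "-":
            wcodes = (3 - wcodes)[::-1]
        genome[start:end] = wcodes
        truth.append(CoordinateRecord("synth", pos, strand, "planted"))
    return decode(genome), truth
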