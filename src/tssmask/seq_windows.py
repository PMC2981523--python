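"""Sequence windows, coordinates and training-set assembly.

The classifier operates on single-stranded 200-nt windows read 5'->3' on the
transcribed strand, with the putative TSS as window character 101 (the first
downstream nucleotide).  Window coordinates follow the promoter-analysis
convention: upstream positions -100..-1 map to characters 1..100, downstream
positions +1..+100 map to characters 101..200; there is no position 0.

Genomic coordinates are 0-based, half-open throughout (BED convention); any
1-based table dialect must be converted at the reader boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

WINDOW_LEN = 200
#: 0-based index of the TSS nucleotide inside a window (window character 101).
TSS_INDEX = 100

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


class AmbiguousSequenceError(ValueError):
    """A window or slice contains a character outside {A,C,G,T}."""


class WindowBoundsError(ValueError):
    """A requested window would overrun the sequence boundary."""


class SamplingExhaustedError(RuntimeError):
    """Negative-window sampling could not satisfy the request."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def window_pos_to_index(pos: int) -> int:
    """Map a window coordinate in -100..-1, +1..+100 to a 0-based index."""
    if pos == 0 or not -100 <= pos <= 100:
        raise ValueError(f"window coordinate out of range: {pos}")
    return 100 + pos if pos < 0 else 99 + pos


@dataclass(frozen=True)
class TssWindow:
    """A 200-nt single-stranded window with the putative TSS at character 101.

    ``origin`` when present is ``(sequence_id, genomic 0-based TSS position,
    strand)``; ``label`` is ``"positive"``, ``"negative"`` or ``None``.
    Lowercase (soft-masked) input is uppercased before validation; non-ACGT
    characters are rejected.
    """

    seq: str
    origin: Optional[Tuple[str, int, str]] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if len(seq) != WINDOW_LEN:
            raise ValueError(f"window must be {WINDOW_LEN} nt, got {len(seq)}")
        if not _VALID.issuperset(seq):
            raise AmbiguousSequenceError("window contains non-ACGT characters")
        if self.origin is not None and self.origin[2] not in ("+", "-"):
            raise ValueError(f"bad strand {self.origin[2]!r}")
        object.__setattr__(self, "seq", seq)

    @property
    def upstream(self) -> str:
        """Characters 1..100 (positions -100..-1)."""
        return self.seq[:100]

    @property
    def downstream(self) -> str:
        """Characters 101..200 (positions +1..+100)."""
        return self.seq[100:]


class CoordinateRecord(NamedTuple):
    """A strand-specific transcript 5'-end (0-based single-nucleotide)."""

    sequence_id: str
    pos: int
    strand: str
    source_tag: str = ""

    @property
    def triple(self) -> Tuple[str, int, str]:
        return (self.sequence_id, self.pos, self.strand)


@dataclass
class TrainingCorpus:
    """Positive (TSS-centered) and negative (random) training windows."""

    positives: list[TssWindow] = field(default_factory=list)
    negatives: list[TssWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def extract_window(
    genome_seq: str,
    pos: int,
    strand: str,
    sequence_id: Optional[str] = None,
    label: Optional[str] = None,
) -> TssWindow:
    """Extract the 200-nt window whose TSS nucleotide is ``genome_seq[pos]``.

    On the plus strand the window is ``genome_seq[pos-100 : pos+100)``; on the
    minus strand it is the reverse complement of ``genome_seq[pos-99 : pos+101)``
    so that the TSS base is again window character 101 on the transcribed
    strand.
    """
    n = len(genome_seq)
    if strand == "+":
        start, end = pos - 100, pos + 100
    elif strand == "-":
        start, end = pos - 99, pos + 101
    else:
        raise ValueError(f"bad strand {strand!r}")
    if start < 0 or end > n:
        raise WindowBoundsError(
            f"window [{start},{end}) exceeds sequence of length {n}"
        )
    piece = genome_seq[start:end]
    if strand == "-":
        piece = revcomp(piece)
    origin = (sequence_id, pos, strand) if sequence_id is not None else None
    return TssWindow(piece, origin=origin, label=label)


def compile_tss_set(
    cage: Sequence[CoordinateRecord],
    evidence: Sequence[CoordinateRecord],
) -> list[CoordinateRecord]:
    """CAGE 5' ends exactly confirmed by independent transcript evidence.

    A CAGE record is kept when its ``(sequence_id, pos, strand)`` triple
    exactly equals at least one evidence triple (no mismatch, no positional
    slack, strand-specific).  Duplicates collapse to unique triples; no
    minimum spacing between neighbouring TSSs is enforced.
    """
    confirmed = {r.triple for r in evidence}
    seen: dict[Tuple[str, int, str], CoordinateRecord] = {}
    for rec in cage:
        if rec.triple in confirmed and rec.triple not in seen:
            seen[rec.triple] = rec
    return [seen[t] for t in sorted(seen)]


def sample_negative_windows(
    genome: Sequence[Tuple[str, str]],
    cage: Sequence[CoordinateRecord],
    n: int,
    rng_seed: int,
    max_tries: Optional[int] = None,
) -> list[TssWindow]:
    """Draw ``n`` random 200-nt windows for the negative reference set.

    Sequences are chosen with probability proportional to their length,
    strand uniformly.  A draw is rejected and retried when the window
    contains a non-ACGT character or when any CAGE 5' end (either strand)
    lies within +-10 nt of the window center.  Reproducible given
    ``rng_seed``; raises :class:`SamplingExhaustedError` once the retry
    budget is spent.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not genome:
        raise ValueError("genome must be non-empty")
    rng = np.random.default_rng(rng_seed)
    lengths = np.array([len(s) for _, s in genome], dtype=float)
    if lengths.sum() == 0:
        raise SamplingExhaustedError("genome has no sequence")
    weights = lengths / lengths.sum()

    exclusion: dict[str, np.ndarray] = {}
    for rec in cage:
        exclusion.setdefault(rec.sequence_id, [])  # type: ignore[arg-type]
    for rec in cage:
        exclusion[rec.sequence_id].append(rec.pos)  # type: ignore[union-attr]
    exclusion = {k: np.sort(np.asarray(v)) for k, v in exclusion.items()}

    budget = max_tries if max_tries is not None else 1000 + 200 * n
    out: list[TssWindow] = []
    tries = 0
    while len(out) < n:
        if tries >= budget:
            raise SamplingExhaustedError(
                f"drew {len(out)}/{n} windows in {tries} tries"
            )
        tries += 1
        idx = int(rng.choice(len(genome), p=weights))
        seq_id, seq = genome[idx]
        strand = "+" if rng.integers(2) == 0 else "-"
        lo, hi = (100, len(seq) - 100) if strand == "+" else (99, len(seq) - 101)
        if hi < lo:
            continue
        center = int(rng.integers(lo, hi + 1))
        near = exclusion.get(seq_id)
        if near is not None and near.size:
            j = int(np.searchsorted(near, center))
            if (j < near.size and near[j] - center <= 10) or (
                j > 0 and center - near[j - 1] <= 10
            ):
                continue
        try:
            out.append(
                extract_window(seq, center, strand, sequence_id=seq_id, label="negative")
            )
        except AmbiguousSequenceError:
            continue
    return out


# ---------------------------------------------------------------------------
# FASTA / BED I/O (gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Iterator[Tuple[str, str, str]]:
    """Yield ``(id, description, sequence)`` from a (possibly gzipped) FASTA."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, rec.description, str(rec.seq)


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            handle,
            "fasta",
        )


def write_windows_fasta(windows: Sequence[TssWindow], path) -> None:
    """Serialize windows with origin/label metadata in the FASTA header."""
    def _records():
        for i, w in enumerate(windows):
            sid, pos, strand = w.origin if w.origin else (".", ".", ".")
            desc = f"id={sid} pos={pos} strand={strand} label={w.label or '.'}"
            yield SeqRecord(Seq(w.seq), id=f"w{i}", description=desc)

    with _open_text(path, "wt") as handle:
        SeqIO.write(_records(), handle, "fasta")


def read_windows_fasta(path, label: Optional[str] = None) -> list[TssWindow]:
    """Parse windows written by :func:`write_windows_fasta` (or plain FASTA)."""
    out = []
    for _rid, desc, seq in read_fasta(path):
        meta = dict(
            tok.split("=", 1) for tok in desc.split()[1:] if "=" in tok
        )
        origin = None
        if meta.get("id", ".") != "." and meta.get("pos", ".") != ".":
            origin = (meta["id"], int(meta["pos"]), meta["strand"])
        lab = meta.get("label", ".")
        out.append(TssWindow(seq, origin=origin, label=label or (None if lab == "." else lab)))
    return out


def read_coordinate_bed(path) -> list[CoordinateRecord]:
    """Read transcript 5' ends from a BED6/TSV table (0-based half-open).

    For a plus-strand interval the 5' end is ``start``; for minus strand it
    is ``end - 1``.  The name column becomes the source tag.
    """
    out = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand == "+" else end - 1
            out.append(CoordinateRecord(chrom, pos, strand, name))
    return out


def write_coordinate_bed(records: Sequence[CoordinateRecord], path) -> None:
    with _open_text(path, "wt") as handle:
        for r in records:
            handle.write(
                f"{r.sequence_id}\t{r.pos}\t{r.pos + 1}\t{r.source_tag or '.'}\t0\t{r.strand}\n"
            )
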