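"""Stage 2: dinucleotide-conditioned PWMs over the 20-nt core [-10,+10].

Training positives are split into 16 subsets by the dinucleotide at window
positions [-1,+1] (characters 100 and 101).  Each present subset gets a
length-20 position weight matrix built from its members' core sequences and
a threshold s_min equal to the minimum training score, so every training
member passes its own subset (100% training sensitivity).  Windows whose
central dinucleotide never occurred in training are rejected.

The PWM here is a log2 likelihood-ratio matrix with an additive pseudocount:

    w[b, j] = log2( (count(b at j) + pc) / (N + 4 pc) / background[b] )

Because each subset threshold is the minimum of the members' scores under
the same matrix, any strictly monotone transform of the scoring yields
identical stage decisions; the particular normalization is therefore a free
choice for stages 2-3 (it matters only for the stage-4 feature scale).
The same builder/scorer is reused by the later stages at length 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .kmer_stage import encode
from .seq_windows import TssWindow

#: additive score assigned to a zero-probability base (pseudocount 0)
NEG_SENTINEL = -1.0e9

DEFAULT_PSEUDOCOUNT = 0.25
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

#: the 16 dinucleotide subset keys, in enumeration order
DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]

#: 0-based slice of the [-10,+10] core inside a window (characters 91..110)
CORE_SLICE = slice(90, 110)
CORE_LEN = 20


@dataclass
class Pwm:
    """A 4 x L additive scoring matrix (rows indexed A,C,G,T)."""

    weights: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: Tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("weights must be a 4 x L matrix")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "pseudocount": self.pseudocount,
            "background": list(self.background),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pwm":
        return cls(np.array(d["weights"]), d["pseudocount"], tuple(d["background"]))


def build_pwm(
    aligned_seqs: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> Pwm:
    """Build a PWM from equal-length aligned DNA strings."""
    if not aligned_seqs:
        raise ValueError("cannot build a PWM from an empty set")
    length = len(aligned_seqs[0])
    if any(len(s) != length for s in aligned_seqs):
        raise ValueError("aligned sequences must have uniform length")
    codes = np.stack([encode(s) for s in aligned_seqs])
    if codes.max() > 3:
        raise ValueError("aligned sequences must be ACGT only")
    n = len(aligned_seqs)
    counts = np.zeros((4, length), dtype=np.float64)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    bg = np.asarray(background, dtype=np.float64)[:, None]
    with np.errstate(divide="ignore"):
        weights = np.where(probs > 0.0, np.log2(np.maximum(probs, 1e-300) / bg), NEG_SENTINEL)
    return Pwm(weights, float(pseudocount), tuple(background))


def pwm_score(seq: str, pwm: Pwm) -> float:
    """Additive PWM score: sum over positions of w[base, position]."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.length}")
    codes = encode(seq)
    if codes.max() > 3:
        raise ValueError("sequence must be ACGT only")
    return float(pwm.weights[codes, np.arange(pwm.length)].sum())


def score_matrix(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Vectorized :func:`pwm_score` for an (n, L) code matrix."""
    return pwm.weights[codes, np.arange(pwm.length)].sum(axis=1)


def central_dinucleotide(window: TssWindow) -> str:
    """The dinucleotide at window positions [-1,+1] (characters 100, 101)."""
    return window.seq[99:101]


@dataclass
class PwmStageModel:
    """16 subset PWMs (length 20) with per-subset minimum-score thresholds."""

    pwms: Dict[str, Pwm] = field(default_factory=dict)
    s_min: Dict[str, float] = field(default_factory=dict)

    @property
    def subset_present(self) -> frozenset:
        return frozenset(self.pwms)

    def to_dict(self) -> dict:
        return {
            "pwms": {k: self.pwms[k].to_dict() for k in sorted(self.pwms)},
            "s_min": {k: self.s_min[k] for k in sorted(self.s_min)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PwmStageModel":
        return cls(
            {k: Pwm.from_dict(v) for k, v in d["pwms"].items()},
            {k: float(v) for k, v in d["s_min"].items()},
        )


def group_by_dinucleotide(windows: Sequence[TssWindow]) -> Dict[str, list]:
    """Partition window indices by central dinucleotide."""
    groups: Dict[str, list] = {}
    for i, w in enumerate(windows):
        groups.setdefault(central_dinucleotide(w), []).append(i)
    return groups


def train_pwm_stage(
    positives: Sequence[TssWindow],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> PwmStageModel:
    """Fit the 16 core PWMs and their 100%-sensitivity thresholds."""
    if not positives:
        raise ValueError("cannot train the PWM stage on an empty positive set")
    model = PwmStageModel()
    for dinuc, idx in group_by_dinucleotide(positives).items():
        cores = [positives[i].seq[CORE_SLICE] for i in idx]
        pwm = build_pwm(cores, pseudocount, background)
        scores = [pwm_score(c, pwm) for c in cores]
        model.pwms[dinuc] = pwm
        model.s_min[dinuc] = min(scores)
    return model


def classify_pwm_stage(window: TssWindow, model: PwmStageModel) -> bool:
    """True iff the core scores at least s_min of the window's subset.

    Windows in a subset that had no training members are rejected.  Ties
    pass (the threshold comparison is >=).
    """
    dinuc = central_dinucleotide(window)
    if dinuc not in model.pwms:
        return False
    s = pwm_score(window.seq[CORE_SLICE], model.pwms[dinuc])
    return s >= model.s_min[dinuc]
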