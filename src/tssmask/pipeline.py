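"""Daisy-chain orchestration, genome scanning and model persistence.

A window is a potential TSS only if it passes all four stages in
conjunction: (1) k-mer occurrence envelopes, (2) core [-10,+10] PWM
threshold, (3) 40-section linear discriminant, (4) RBF SVM decision above
t_SVM.  A scanned genomic position failing any stage is demarcated NTL
(non-TSS location) on that strand; surviving positions are TIAR
(transcription-initiation active region).  Positions whose 200-nt window
would overrun a sequence end, or whose window contains non-ACGT characters,
are UNSCORED: "cannot evaluate" is deliberately kept distinct from "cannot
initiate transcription" so NTL fractions are reported over scored positions
only.

Models persist as a versioned JSON document; floating-point values
round-trip exactly, so a reloaded model reproduces decision values
bit-for-bit and retraining under an identical corpus and configuration
yields a byte-identical file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import kmer_stage, ldf_stage, pwm_stage, svm_stage
from .kmer_stage import KmerEnvelopeSet, encode, kmer_count_matrix
from .ldf_stage import LdfSubsetModel
from .pwm_stage import DINUCLEOTIDES, PwmStageModel
from .seq_windows import TrainingCorpus, TssWindow, revcomp
from .svm_stage import SvmStageModel

MODEL_FORMAT = "tssmask-model"
MODEL_FORMAT_VERSION = 1

#: scan labels (uint8 codes)
NTL, TIAR, UNSCORED = 0, 1, 2
LABEL_NAMES = {NTL: "NTL", TIAR: "TIAR", UNSCORED: "UNSCORED"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

#: default SVM threshold: the 100%-training-sensitivity operating point
DEFAULT_T_SVM = -2.5

_SCAN_CHUNK = 4096


class ModelFormatError(ValueError):
    """The model file is corrupt or has an unsupported format/version."""


class TrainingError(RuntimeError):
    """A stage failed to train; the message names the stage."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (all stages are otherwise data-determined)."""

    pseudocount: float = pwm_stage.DEFAULT_PSEUDOCOUNT
    background: Tuple[float, float, float, float] = pwm_stage.UNIFORM_BACKGROUND
    gamma: float = svm_stage.DEFAULT_GAMMA
    C: float = svm_stage.DEFAULT_C
    scale_features: bool = False
    default_t_svm: float = DEFAULT_T_SVM
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MaskerModel:
    """The persisted four-stage bundle."""

    envelopes: KmerEnvelopeSet
    pwm_model: PwmStageModel
    ldf_models: Dict[str, LdfSubsetModel]
    svm_model: SvmStageModel
    default_t_svm: float = DEFAULT_T_SVM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.svm_model.feature_router = self.ldf_models


@dataclass
class ScanTrack:
    """Per-position, per-strand labels over a scanned sequence."""

    sequence_id: str
    strand: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> Dict[str, int]:
        return {
            name: int((self.labels == code).sum()) for code, name in LABEL_NAMES.items()
        }


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_masker(corpus: TrainingCorpus, config: TrainConfig = TrainConfig()) -> MaskerModel:
    """Train stages 1-4 in chain order on the same corpus."""
    if not corpus.positives or not corpus.negatives:
        raise ValueError("corpus needs non-empty positive and negative sets")
    try:
        envelopes = kmer_stage.train_envelopes(corpus.positives)
    except Exception as exc:  # pragma: no cover - defensive
        raise TrainingError(f"k-mer envelope stage: {exc}") from exc
    try:
        pwm_model = pwm_stage.train_pwm_stage(
            corpus.positives, config.pseudocount, config.background
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise TrainingError(f"core PWM stage: {exc}") from exc
    try:
        ldf_models = ldf_stage.train_ldf_stage(
            corpus.positives, corpus.negatives, config.pseudocount, config.background
        )
    except Exception as exc:
        raise TrainingError(f"LDF stage: {exc}") from exc

    # stage-4 features via each window's own subset routing; negatives whose
    # subset has no positives cannot be featurized (they are rejected by
    # stage 2 anyway) and are excluded from SVM training
    pos_x = _route_features(corpus.positives, ldf_models)
    neg_x = _route_features(corpus.negatives, ldf_models)
    pos_x = pos_x[~np.isnan(pos_x[:, 0])]
    neg_x = neg_x[~np.isnan(neg_x[:, 0])]
    if len(neg_x) == 0:
        raise TrainingError("SVM stage: no routable negatives")
    try:
        svm_model = svm_stage.train_svm(
            pos_x,
            neg_x,
            gamma=config.gamma,
            C=config.C,
            scale=config.scale_features,
            feature_router=ldf_models,
        )
    except Exception as exc:
        raise TrainingError(f"SVM stage: {exc}") from exc

    provenance = {
        "n_positives": len(corpus.positives),
        "n_negatives": len(corpus.negatives),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "format_version": MODEL_FORMAT_VERSION,
    }
    return MaskerModel(
        envelopes, pwm_model, ldf_models, svm_model,
        default_t_svm=config.default_t_svm, provenance=provenance,
    )


def _route_features(windows: Sequence[TssWindow], models: Dict[str, LdfSubsetModel]) -> np.ndarray:
    codes = np.stack([encode(w.seq) for w in windows])
    return _route_features_codes(codes, models)


def _route_features_codes(codes: np.ndarray, models: Dict[str, LdfSubsetModel]) -> np.ndarray:
    """Per-window 40-feature vectors via subset routing; NaN rows when absent."""
    n = codes.shape[0]
    x = np.full((n, ldf_stage.N_SECTIONS), np.nan)
    dinuc_code = codes[:, 99] * 4 + codes[:, 100]
    for key, m in models.items():
        kc = "ACGT".index(key[0]) * 4 + "ACGT".index(key[1])
        rows = np.flatnonzero(dinuc_code == kc)
        if rows.size:
            x[rows] = ldf_stage.section_features_matrix(codes[rows], m.section_pwms)
    return x


# ---------------------------------------------------------------------------
# Batch evaluation of the chain
# ---------------------------------------------------------------------------

@dataclass
class ChainEvaluation:
    """Per-window stage decisions and cached SVM decision values.

    ``svm_scores`` is NaN for windows that cannot be routed (absent subset);
    such windows fail stages 2-4 regardless of threshold.
    """

    pass_kmer: np.ndarray
    pass_pwm: np.ndarray
    pass_ldf: np.ndarray
    svm_scores: np.ndarray

    @property
    def pass_pre_svm(self) -> np.ndarray:
        return self.pass_kmer & self.pass_pwm & self.pass_ldf

    def pass_svm(self, t_svm: float) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.svm_scores, nan=-np.inf) > t_svm

    def labels(self, t_svm: float) -> np.ndarray:
        """NTL/TIAR codes at a threshold (chain conjunction)."""
        tiar = self.pass_pre_svm & self.pass_svm(t_svm)
        return np.where(tiar, TIAR, NTL).astype(np.uint8)

    def survivors(self, t_svm: float) -> list[int]:
        """Cumulative survivor counts after stages 1, 2, 3, 4."""
        m1 = self.pass_kmer
        m2 = m1 & self.pass_pwm
        m3 = m2 & self.pass_ldf
        m4 = m3 & self.pass_svm(t_svm)
        return [int(m.sum()) for m in (m1, m2, m3, m4)]


def evaluate_codes(codes: np.ndarray, model: MaskerModel) -> ChainEvaluation:
    """Run all four stages on an (n, 200) code matrix (codes 0..3 only)."""
    n = codes.shape[0]
    up = kmer_count_matrix(codes[:, :100])
    down = kmer_count_matrix(codes[:, 100:])
    pass1 = kmer_stage.classify_counts(up, down, model.envelopes)

    dinuc_code = codes[:, 99] * 4 + codes[:, 100]
    pass2 = np.zeros(n, dtype=bool)
    cols20 = np.arange(pwm_stage.CORE_LEN)
    for key, pwm in model.pwm_model.pwms.items():
        kc = "ACGT".index(key[0]) * 4 + "ACGT".index(key[1])
        rows = np.flatnonzero(dinuc_code == kc)
        if rows.size:
            s = pwm.weights[codes[rows][:, pwm_stage.CORE_SLICE], cols20].sum(axis=1)
            pass2[rows] = s >= model.pwm_model.s_min[key]

    pass3 = np.zeros(n, dtype=bool)
    scores = np.full(n, np.nan)
    x = _route_features_codes(codes, model.ldf_models)
    for key, m in model.ldf_models.items():
        kc = "ACGT".index(key[0]) * 4 + "ACGT".index(key[1])
        rows = np.flatnonzero(dinuc_code == kc)
        if rows.size:
            pass3[rows] = m.score(x[rows]) >= m.ldf_min
    routable = ~np.isnan(x[:, 0])
    if routable.any():
        scores[routable] = model.svm_model.decision_values(x[routable])
    return ChainEvaluation(pass1, pass2, pass3, scores)


def evaluate_windows(windows: Sequence[TssWindow], model: MaskerModel) -> ChainEvaluation:
    codes = np.stack([encode(w.seq) for w in windows])
    return evaluate_codes(codes, model)


def classify_window(
    window: TssWindow, model: MaskerModel, t_svm: Optional[float] = None
) -> str:
    """Label a single window "TIAR" iff all four stages pass, else "NTL"."""
    t = model.default_t_svm if t_svm is None else t_svm
    ev = evaluate_windows([window], model)
    return LABEL_NAMES[int(ev.labels(t)[0])]


# ---------------------------------------------------------------------------
# Whole-sequence scanning
# ---------------------------------------------------------------------------

def _scan_forward_labels(seq: str, model: MaskerModel, t_svm: float) -> np.ndarray:
    """Plus-strand labels for every position of ``seq``."""
    n = len(seq)
    labels = np.full(n, UNSCORED, dtype=np.uint8)
    if n < 200:
        return labels
    codes = encode(seq)
    bad = (codes > 3).astype(np.int32)
    cum = np.r_[0, np.cumsum(bad)]
    starts_bad = cum[200:] - cum[:-200]  # per window start 0..n-200
    windows = np.lib.stride_tricks.sliding_window_view(codes, 200)
    ok = np.flatnonzero(starts_bad == 0)
    # window starting at s has its TSS nucleotide at position s + 100
    for lo in range(0, ok.size, _SCAN_CHUNK):
        sel = ok[lo : lo + _SCAN_CHUNK]
        ev = evaluate_codes(np.ascontiguousarray(windows[sel]), model)
        labels[sel + 100] = ev.labels(t_svm)
    return labels


def scan_sequence(
    seq: str,
    model: MaskerModel,
    t_svm: Optional[float] = None,
    sequence_id: str = "seq",
) -> Tuple[ScanTrack, ScanTrack]:
    """Strand-specific single-nucleotide NTL/TIAR tracks for a sequence.

    For each position p and strand, the 200-nt window with p as the TSS
    nucleotide (read 5'->3' on that strand) is classified.  Positions whose
    window would overrun either end, or whose window contains non-ACGT
    characters, are UNSCORED.  The minus-strand track equals the
    position-mirrored plus-strand track of the reverse complement.
    """
    t = model.default_t_svm if t_svm is None else t_svm
    plus = _scan_forward_labels(seq, model, t)
    minus = _scan_forward_labels(revcomp(seq), model, t)[::-1].copy()
    return (
        ScanTrack(sequence_id, "+", plus),
        ScanTrack(sequence_id, "-", minus),
    )


# ---------------------------------------------------------------------------
# Track reporting
# ---------------------------------------------------------------------------

def track_to_bed(track: ScanTrack) -> list[Tuple[str, int, int, str, int, str]]:
    """Maximal same-label runs as BED6 records (0-based half-open)."""
    labels = track.labels
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, labels.size]
    return [
        (track.sequence_id, int(s), int(e), LABEL_NAMES[int(labels[s])], 0, track.strand)
        for s, e in zip(starts, ends)
    ]


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def track_from_bed(records, length: int, sequence_id: str, strand: str) -> ScanTrack:
    """Rebuild a track from BED records (inverse of :func:`track_to_bed`)."""
    labels = np.full(length, UNSCORED, dtype=np.uint8)
    for chrom, start, end, name, _score, rec_strand in records:
        if chrom == sequence_id and rec_strand == strand:
            labels[start:end] = LABEL_CODES[name]
    return ScanTrack(sequence_id, strand, labels)


def ntl_fraction(tracks: Sequence[ScanTrack]) -> Dict[str, float]:
    """Pooled per-label fractions over all given tracks.

    NTL and TIAR fractions are over scored positions and sum to 1; the
    UNSCORED fraction (over all positions) is reported separately.
    """
    if not tracks:
        raise ValueError("need at least one track")
    all_labels = np.concatenate([t.labels for t in tracks])
    total = all_labels.size
    n_unscored = int((all_labels == UNSCORED).sum())
    scored = total - n_unscored
    n_ntl = int((all_labels == NTL).sum())
    n_tiar = int((all_labels == TIAR).sum())
    return {
        "NTL": n_ntl / scored if scored else float("nan"),
        "TIAR": n_tiar / scored if scored else float("nan"),
        "UNSCORED": n_unscored / total if total else float("nan"),
        "scored_positions": scored,
        "total_positions": total,
    }


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def model_to_dict(model: MaskerModel) -> dict:
    return {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "default_t_svm": model.default_t_svm,
        "provenance": model.provenance,
        "envelopes": model.envelopes.to_dict(),
        "pwm_stage": model.pwm_model.to_dict(),
        "ldf_stage": {k: model.ldf_models[k].to_dict() for k in sorted(model.ldf_models)},
        "svm_stage": model.svm_model.to_dict(),
    }


def model_from_dict(data: dict) -> MaskerModel:
    if data.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"not a {MODEL_FORMAT} document")
    if data.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported format version {data.get('format_version')!r}"
        )
    try:
        model = MaskerModel(
            envelopes=KmerEnvelopeSet.from_dict(data["envelopes"]),
            pwm_model=PwmStageModel.from_dict(data["pwm_stage"]),
            ldf_models={
                k: LdfSubsetModel.from_dict(v) for k, v in data["ldf_stage"].items()
            },
            svm_model=SvmStageModel.from_dict(data["svm_stage"]),
            default_t_svm=float(data["default_t_svm"]),
            provenance=data.get("provenance", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupt model document: {exc}") from exc
    return model


def save_model(model: MaskerModel, path) -> None:
    text = json.dumps(model_to_dict(model), sort_keys=True, separators=(",", ":"))
    with open(path, "w") as fh:
        fh.write(text)
        fh.write("\n")


def load_model(path) -> MaskerModel:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelFormatError("model file does not contain a JSON object")
    return model_from_dict(data)
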