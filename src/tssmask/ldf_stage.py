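"""Stage 3: per-subset 40-feature linear discriminant functions.

The 200-nt window is divided into 40 consecutive non-overlapping 5-nt
sections.  For each of the 16 dinucleotide subsets, a length-5 PWM is built
per section from the subset's positive windows; a window's feature vector is
the 40 section scores under those PWMs.  Negative windows are featurized
with the same PWMs, routed to subsets by their own central dinucleotide
(classification-time routing must match training-time routing).  A Fisher
linear discriminant (pooled within-class covariance, ridge fallback for
ill-conditioned covariance) separates the classes; the subset threshold
LDF_min is the minimum discriminant score over the subset's positives, so
training sensitivity is 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .kmer_stage import encode
from .pwm_stage import (
    DEFAULT_PSEUDOCOUNT,
    UNIFORM_BACKGROUND,
    Pwm,
    build_pwm,
    central_dinucleotide,
    group_by_dinucleotide,
    pwm_score,
)
from .seq_windows import TssWindow

N_SECTIONS = 40
SECTION_LEN = 5

#: relative ridge added to the pooled covariance diagonal when ill-conditioned
RIDGE_REL = 1e-6
COND_THRESHOLD = 1e8


class LdfTrainingError(ValueError):
    """A subset cannot be fitted (missing class or too few samples)."""


def section_features(window: TssWindow, section_pwms: Sequence[Pwm]) -> np.ndarray:
    """x_i = score of window characters [5(i-1)+1 .. 5i] under PWM i."""
    if len(section_pwms) != N_SECTIONS:
        raise ValueError(f"expected {N_SECTIONS} section PWMs")
    return np.array(
        [
            pwm_score(window.seq[SECTION_LEN * i : SECTION_LEN * (i + 1)], section_pwms[i])
            for i in range(N_SECTIONS)
        ]
    )


def section_features_matrix(codes: np.ndarray, section_pwms: Sequence[Pwm]) -> np.ndarray:
    """Vectorized :func:`section_features` for an (n, 200) code matrix."""
    n = codes.shape[0]
    x = np.empty((n, N_SECTIONS), dtype=np.float64)
    cols = np.arange(SECTION_LEN)
    for i in range(N_SECTIONS):
        w = section_pwms[i].weights
        x[:, i] = w[codes[:, SECTION_LEN * i : SECTION_LEN * (i + 1)], cols].sum(axis=1)
    return x


def fit_ldf(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    ridge_rel: float = RIDGE_REL,
    cond_threshold: float = COND_THRESHOLD,
) -> Tuple[np.ndarray, float]:
    """Fisher linear discriminant with pooled within-class covariance.

    Returns coefficients ``c`` (oriented so positives score higher on
    average) and intercept ``c_const`` placed at the midpoint of the class
    mean projections.  When the pooled covariance is ill-conditioned, a
    ridge term ``ridge_rel * trace / p`` is added to its diagonal.
    """
    Xp = np.asarray(pos_features, dtype=np.float64)
    Xn = np.asarray(neg_features, dtype=np.float64)
    if Xp.ndim != 2 or Xn.ndim != 2 or Xp.shape[1] != Xn.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal width")
    if len(Xp) < 2 or len(Xn) < 2:
        raise LdfTrainingError("each class needs at least 2 samples")
    p = Xp.shape[1]
    mu_p = Xp.mean(axis=0)
    mu_n = Xn.mean(axis=0)
    sw = ((len(Xp) - 1) * np.cov(Xp, rowvar=False) + (len(Xn) - 1) * np.cov(Xn, rowvar=False))
    sw /= len(Xp) + len(Xn) - 2
    sw = np.atleast_2d(sw)
    eps = ridge_rel * np.trace(sw) / p
    if not np.isfinite(np.linalg.cond(sw)) or np.linalg.cond(sw) > cond_threshold:
        sw = sw + eps * np.eye(p)
    try:
        c = np.linalg.solve(sw, mu_p - mu_n)
    except np.linalg.LinAlgError:
        c = np.linalg.solve(sw + eps * np.eye(p), mu_p - mu_n)
    if float(c @ (mu_p - mu_n)) < 0.0:
        c = -c
    c_const = -0.5 * float(c @ (mu_p + mu_n))
    return c, c_const


@dataclass
class LdfSubsetModel:
    """Section PWMs, discriminant coefficients and threshold for one subset."""

    dinucleotide: str
    section_pwms: list
    coef: np.ndarray
    intercept: float
    ldf_min: float

    def score(self, features: np.ndarray) -> np.ndarray:
        # elementwise multiply + pairwise sum: bitwise identical whether the
        # input is one row or a batch (a BLAS dot may differ across shapes,
        # which matters because ldf_min is compared with exact >=)
        x = np.asarray(features, dtype=np.float64)
        return (x * self.coef).sum(axis=-1) + self.intercept

    def to_dict(self) -> dict:
        return {
            "dinucleotide": self.dinucleotide,
            "section_pwms": [p.to_dict() for p in self.section_pwms],
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "ldf_min": self.ldf_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LdfSubsetModel":
        return cls(
            d["dinucleotide"],
            [Pwm.from_dict(p) for p in d["section_pwms"]],
            np.array(d["coef"]),
            float(d["intercept"]),
            float(d["ldf_min"]),
        )


def train_ldf_stage(
    positives: Sequence[TssWindow],
    negatives: Sequence[TssWindow],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> Dict[str, LdfSubsetModel]:
    """Fit one LDF per present dinucleotide subset."""
    if not positives:
        raise ValueError("cannot train the LDF stage on an empty positive set")
    pos_groups = group_by_dinucleotide(positives)
    neg_groups = group_by_dinucleotide(negatives)
    models: Dict[str, LdfSubsetModel] = {}
    for dinuc, pos_idx in pos_groups.items():
        subset_pos = [positives[i] for i in pos_idx]
        pwms = [
            build_pwm(
                [w.seq[SECTION_LEN * i : SECTION_LEN * (i + 1)] for w in subset_pos],
                pseudocount,
                background,
            )
            for i in range(N_SECTIONS)
        ]
        neg_idx = neg_groups.get(dinuc, [])
        if len(neg_idx) == 0:
            raise LdfTrainingError(
                f"subset {dinuc!r} has {len(subset_pos)} positives but no negatives"
            )
        if len(pos_idx) < 2 or len(neg_idx) < 2:
            # too few members to estimate a within-class covariance: use a
            # degenerate pass-through discriminant (no discrimination, but
            # the subset's training members still pass, preserving the
            # 100%-training-sensitivity contract)
            models[dinuc] = LdfSubsetModel(dinuc, pwms, np.zeros(N_SECTIONS), 0.0, 0.0)
            continue
        codes_p = np.stack([encode(w.seq) for w in subset_pos])
        codes_n = np.stack([encode(negatives[i].seq) for i in neg_idx])
        Xp = section_features_matrix(codes_p, pwms)
        Xn = section_features_matrix(codes_n, pwms)
        coef, intercept = fit_ldf(Xp, Xn)
        model = LdfSubsetModel(dinuc, pwms, coef, intercept, 0.0)
        model.ldf_min = float(model.score(Xp).min())
        models[dinuc] = model
    return models


def classify_ldf_stage(window: TssWindow, models: Dict[str, LdfSubsetModel]) -> bool:
    """True iff s_LDF >= LDF_min in the window's subset (absent subset fails)."""
    dinuc = central_dinucleotide(window)
    m = models.get(dinuc)
    if m is None:
        return False
    s = float(m.score(section_features(window, m.section_pwms)))
    return s >= m.ldf_min
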