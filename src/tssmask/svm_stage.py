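"""Stage 4: RBF support vector machine over the 40 section-PWM features.

A single SVM (radial basis kernel, gamma default 1.28, soft margin C default
1) is trained on the pooled 40-dimensional feature vectors of all subsets;
genuine-TSS windows are labeled +1, random windows -1.  Its decision value
s_SVM, compared against the adjustable threshold t_SVM with a STRICT
inequality (s_SVM > t_SVM), is the only user-tunable dial of the chain.

The SVM sits last in the daisy chain: it is the most expensive stage and
the one whose threshold gives the most useful sensitivity/specificity
trade-off.  After fitting, the support vectors, dual coefficients and
intercept are extracted and all decision values are computed by an explicit
kernel expansion sum_i alpha_i y_i K(x_i, x) + b, so persisted models
reproduce decision values bit-for-bit on reload.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from sklearn.svm import SVC

from .kmer_stage import encode
from .ldf_stage import LdfSubsetModel, section_features_matrix
from .pwm_stage import central_dinucleotide
from .seq_windows import TssWindow

DEFAULT_GAMMA = 1.28
DEFAULT_C = 1.0


@dataclass
class SvmStageModel:
    """Kernel expansion state for the trained RBF machine.

    ``dual_coef`` holds alpha_i * y_i for each support vector; decision
    values are ``dual_coef @ K(sv, x) + intercept`` with
    ``K(a, b) = exp(-gamma ||a-b||^2)``.  ``feature_router`` references the
    stage-3 subset models whose section PWMs featurize incoming windows.
    When ``scale`` is on, features are standardized with the stored training
    mean/sd before entering the kernel.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float = DEFAULT_GAMMA
    C: float = DEFAULT_C
    scale: bool = False
    feature_mean: Optional[np.ndarray] = None
    feature_sd: Optional[np.ndarray] = None
    min_pos_score: float = float("nan")
    model_name: str = ""
    feature_router: Optional[Dict[str, LdfSubsetModel]] = field(
        default=None, repr=False, compare=False
    )

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """s_SVM for an (n, 40) feature matrix."""
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if self.scale:
            x = (x - self.feature_mean) / self.feature_sd
        sv = self.support_vectors
        sq = ((x * x).sum(axis=1)[:, None] + (sv * sv).sum(axis=1)[None, :]
              - 2.0 * (x @ sv.T))
        k = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return k @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "scale": self.scale,
            "feature_mean": None if self.feature_mean is None else self.feature_mean.tolist(),
            "feature_sd": None if self.feature_sd is None else self.feature_sd.tolist(),
            "min_pos_score": self.min_pos_score,
            "model_name": self.model_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmStageModel":
        return cls(
            np.array(d["support_vectors"]),
            np.array(d["dual_coef"]),
            float(d["intercept"]),
            float(d["gamma"]),
            float(d["C"]),
            bool(d["scale"]),
            None if d["feature_mean"] is None else np.array(d["feature_mean"]),
            None if d["feature_sd"] is None else np.array(d["feature_sd"]),
            float(d["min_pos_score"]),
            d.get("model_name", ""),
        )


def train_svm(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    C: float = DEFAULT_C,
    scale: bool = False,
    model_name: str = "",
    feature_router: Optional[Dict[str, LdfSubsetModel]] = None,
) -> SvmStageModel:
    """Fit the RBF machine on labeled feature vectors (+1 TSS / -1 random)."""
    Xp = np.asarray(pos_features, dtype=np.float64)
    Xn = np.asarray(neg_features, dtype=np.float64)
    if len(Xp) == 0 or len(Xn) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([Xp, Xn])
    y = np.r_[np.ones(len(Xp)), -np.ones(len(Xn))]
    mean = sd = None
    if scale:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd
    svc = SVC(kernel="rbf", gamma=gamma, C=C)
    svc.fit(X, y)
    # sklearn orders classes [-1, +1]; decision_function is positive on +1 side
    model = SvmStageModel(
        support_vectors=np.asarray(svc.support_vectors_, dtype=np.float64),
        dual_coef=np.asarray(svc.dual_coef_[0], dtype=np.float64),
        intercept=float(svc.intercept_[0]),
        gamma=float(gamma),
        C=float(C),
        scale=scale,
        feature_mean=mean,
        feature_sd=sd,
        model_name=model_name,
        feature_router=feature_router,
    )
    model.min_pos_score = float(model.decision_values(Xp).min())
    return model


def window_features(window: TssWindow, router: Dict[str, LdfSubsetModel]) -> np.ndarray:
    """Featurize a window via its subset's section PWMs."""
    dinuc = central_dinucleotide(window)
    m = router.get(dinuc)
    if m is None:
        raise ValueError(f"no section PWMs for subset {dinuc!r}")
    return section_features_matrix(encode(window.seq)[None, :], m.section_pwms)[0]


def svm_decision(window: TssWindow, model: SvmStageModel) -> float:
    """Decision value s_SVM of a window (features via stage-3 routing)."""
    if model.feature_router is None:
        raise RuntimeError("model has no feature router attached")
    x = window_features(window, model.feature_router)
    return float(model.decision_values(x[None, :])[0])


def classify_svm_stage(window: TssWindow, model: SvmStageModel, t_svm: float) -> bool:
    """True iff s_SVM > t_SVM (strict; a tie is rejected)."""
    return svm_decision(window, model) > t_svm
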