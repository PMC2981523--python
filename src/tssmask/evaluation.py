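"""Sensitivity/specificity sweeps, trade-off curves and cross-validation.

Sensitivity is the fraction of positive windows labeled TIAR; specificity is
the fraction of negative windows correctly demarcated NTL (true-negative
rate).  A sweep evaluates stages 1-3 and the SVM decision value once per
window and re-thresholds the cached decision, which is exactly equivalent to
re-running the full chain at every threshold.  The default threshold grid
spans -2.50 .. 1.25, the range over which the chain moves from its
100%-training-sensitivity operating point to a highly specific one.

Cross-validation (4-fold by default) retrains all four stages - including
every 100%-sensitivity threshold - on each training fold and sweeps the
held-out quarter; folds are drawn per class without stratification by
dinucleotide subset (a stratified option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import MaskerModel, TrainConfig, evaluate_windows, train_masker
from .pwm_stage import central_dinucleotide
from .seq_windows import TrainingCorpus, TssWindow

DEFAULT_THRESHOLDS = (
    -2.50, -2.00, -1.50, -1.00, -0.50, -0.25, 0.00, 0.25, 0.50, 0.75, 1.00, 1.25,
)


class SweepRow(NamedTuple):
    t_svm: float
    sensitivity: float
    specificity: float


@dataclass
class CvReport:
    """Per-fold and mean sweep rows from a k-fold cross-validation."""

    k: int
    seed: int
    fold_rows: list
    fold_assignments: dict = field(default_factory=dict)

    @property
    def mean_rows(self) -> list[SweepRow]:
        by_t: dict[float, list[SweepRow]] = {}
        for rows in self.fold_rows:
            for r in rows:
                by_t.setdefault(r.t_svm, []).append(r)
        return [
            SweepRow(
                t,
                float(np.mean([r.sensitivity for r in rs])),
                float(np.mean([r.specificity for r in rs])),
            )
            for t, rs in sorted(by_t.items())
        ]


def sweep(
    model: MaskerModel,
    positives: Sequence[TssWindow],
    negatives: Sequence[TssWindow],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[SweepRow]:
    """One sensitivity/specificity row per threshold."""
    if not positives or not negatives:
        raise ValueError("sweep needs non-empty positive and negative sets")
    ev_pos = evaluate_windows(positives, model)
    ev_neg = evaluate_windows(negatives, model)
    rows = []
    for t in thresholds:
        sens = float((ev_pos.labels(t) == 1).mean())
        spec = float((ev_neg.labels(t) == 0).mean())
        rows.append(SweepRow(float(t), sens, spec))
    return rows


def cross_validate(
    corpus: TrainingCorpus,
    config: TrainConfig = TrainConfig(),
    k: int = 4,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    stratify_by_subset: bool = False,
) -> CvReport:
    """k-fold CV with full per-fold retraining of all four stages."""
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    if len(corpus.positives) < k or len(corpus.negatives) < k:
        raise ValueError(f"each class needs at least {k} members")
    rng = np.random.default_rng(seed)
    pos_folds = _make_folds(corpus.positives, k, rng, stratify_by_subset)
    neg_folds = _make_folds(corpus.negatives, k, rng, stratify_by_subset)

    fold_rows = []
    assignments = {"positives": pos_folds, "negatives": neg_folds}
    for fold in range(k):
        train = TrainingCorpus(
            [w for i, w in enumerate(corpus.positives) if pos_folds[i] != fold],
            [w for i, w in enumerate(corpus.negatives) if neg_folds[i] != fold],
        )
        test_pos = [w for i, w in enumerate(corpus.positives) if pos_folds[i] == fold]
        test_neg = [w for i, w in enumerate(corpus.negatives) if neg_folds[i] == fold]
        model = train_masker(train, config)
        fold_rows.append(sweep(model, test_pos, test_neg, thresholds))
    return CvReport(k, seed, fold_rows, assignments)


def _make_folds(windows, k: int, rng: np.random.Generator, stratify: bool) -> np.ndarray:
    n = len(windows)
    folds = np.empty(n, dtype=np.int64)
    if stratify:
        groups: dict[str, list[int]] = {}
        for i, w in enumerate(windows):
            groups.setdefault(central_dinucleotide(w), []).append(i)
        for idx in groups.values():
            order = rng.permutation(len(idx))
            for slot, j in enumerate(order):
                folds[idx[j]] = slot % k
    else:
        order = rng.permutation(n)
        for slot, j in enumerate(order):
            folds[j] = slot % k
    return folds


def sweep_table(rows: Sequence[SweepRow]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["t_svm", "sensitivity", "specificity"])
    return df.sort_values("t_svm", kind="stable").reset_index(drop=True)


def tradeoff_curve(
    rows: Sequence[SweepRow],
    table_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Threshold-sorted trade-off table; optionally written as TSV and PNG."""
    if len(rows) < 2:
        raise ValueError("a trade-off curve needs at least 2 rows")
    df = sweep_table(rows)
    if table_path is not None:
        df.to_csv(table_path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(df["specificity"], df["sensitivity"], "o-")
        ax.set_xlabel("specificity (NTL rate on random DNA)")
        ax.set_ylabel("sensitivity (TIAR rate on TSS windows)")
        ax.set_title("sensitivity / specificity trade-off")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df


def read_sweep_table(path) -> list[SweepRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        SweepRow(float(r.t_svm), float(r.sensitivity), float(r.specificity))
        for r in df.itertuples()
    ]
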