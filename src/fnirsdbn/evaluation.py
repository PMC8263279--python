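"""Scoring and aggregation.

Accuracy is reported at two granularities: per-sample (each time point is a
sample, the granularity implied by the 19200x16 / 9600x16 train/test
matrices) and per-trial (majority vote over the 160 time points of a trial,
ties toward class 0). Per-subject accuracies are summarized as mean and
population standard deviation, and cross-subject generalization is laid out
as a subject x subject transfer matrix whose diagonal holds each subject's
own held-out-session accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dbn import DbnModel, forward
from .preprocessing import SampleMatrix

__all__ = [
    "AccuracyReport",
    "TransferMatrix",
    "score",
    "summarize",
    "transfer_evaluate",
    "REFERENCE_MOVEMENT_ACC",
    "REFERENCE_IMAGERY_ACC",
]

#: Published per-subject two-class accuracies (%) from the 10-subject arm
#: flexion/extension fNIRS study this pipeline models; used as reference
#: inputs for summary statistics, never as outputs of this package.
REFERENCE_MOVEMENT_ACC = (
    86.90, 82.32, 81.47, 85.79, 76.23, 89.21, 84.79, 82.29, 78.04, 86.45,
)
REFERENCE_IMAGERY_ACC = (
    81.79, 79.23, 70.94, 79.29, 73.97, 82.93, 78.56, 81.47, 73.96, 79.79,
)


@dataclass
class AccuracyReport:
    sample_accuracy: float  # percent
    trial_accuracy: float  # percent, majority vote per trial
    n_samples: int
    n_trials: int
    confusion: np.ndarray  # c x c counts, rows = true class


def score(model: DbnModel, samples: SampleMatrix) -> AccuracyReport:
    """Argmax-class predictions scored per sample and per trial."""
    x, y, trial_index = samples.x, samples.y, samples.trial_index
    if not (len(x) == len(y) == len(trial_index)):
        raise ValueError("samples, labels and trial_index lengths differ")
    pred = forward(x, model).argmax(axis=1)
    n = len(y)
    sample_acc = float((pred == y).mean()) * 100.0

    trials = np.unique(trial_index)
    correct = 0
    for t in trials:
        mask = trial_index == t
        votes = np.bincount(pred[mask], minlength=2)
        majority = int(votes.argmax())  # argmax breaks ties toward class 0
        correct += majority == y[mask][0]
    trial_acc = correct / len(trials) * 100.0

    c = len(model.class_labels)
    confusion = np.zeros((c, c), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    return AccuracyReport(
        sample_accuracy=sample_acc,
        trial_accuracy=trial_acc,
        n_samples=n,
        n_trials=len(trials),
        confusion=confusion,
    )


def summarize(per_subject_accuracies) -> tuple[float, float]:
    """Arithmetic mean and population (divide-by-N) standard deviation."""
    vals = np.asarray(list(per_subject_accuracies), dtype=float)
    if vals.size == 0:
        raise ValueError("no accuracies to summarize")
    return float(vals.mean()), float(vals.std(ddof=0))


@dataclass
class TransferMatrix:
    """accuracy[i, j]: model trained on subject i, scored on subject j's
    held-out session (sample accuracy, percent)."""

    subjects: list[str]
    accuracy: np.ndarray
    arch_by_subject: dict[str, tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.accuracy, index=self.subjects, columns=self.subjects
        )

    def diagonal_dominant_rows(self) -> int:
        """Rows whose diagonal entry is the row maximum."""
        a = self.accuracy
        return int(
            sum(a[i, i] >= a[i].max() for i in range(len(self.subjects)))
        )


def transfer_evaluate(
    models_by_subject: dict[str, DbnModel],
    test_sets_by_subject: dict[str, SampleMatrix],
) -> TransferMatrix:
    """Full cross-subject grid of sample accuracies."""
    subjects = list(models_by_subject)
    missing = [s for s in subjects if s not in test_sets_by_subject]
    if missing:
        raise ValueError(f"missing test sets for subjects {missing}")
    acc = np.zeros((len(subjects), len(subjects)))
    for i, si in enumerate(subjects):
        for j, sj in enumerate(subjects):
            acc[i, j] = score(
                models_by_subject[si], test_sets_by_subject[sj]
            ).sample_accuracy
    arch = {
        s: models_by_subject[s].hidden_sizes for s in subjects
    }
    return TransferMatrix(subjects=subjects, accuracy=acc, arch_by_subject=arch)
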