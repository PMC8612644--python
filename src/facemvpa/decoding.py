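"""Classification-method MVPA: pairwise linear SVM with
leave-one-run-out cross-validation.

For each pair of familiar categories a linear soft-margin support-vector
classifier is trained on the per-run patterns of all runs but one and
tested on the left-out run; the mean accuracy over folds is the decoding
score.  Group significance vs the 50% chance level is a one-sample t-test
across subjects with BH-FDR over the six category pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .core import BetaPatternSet, FAMILIAR_CATEGORIES
from .rsa import GroupInferenceResult, group_inference


@dataclass
class DecodingResult:
    pair: tuple[str, str]
    fold_accuracies: np.ndarray  # one per left-out run
    mean_accuracy: float


def category_pairs(categories: tuple[str, ...] = FAMILIAR_CATEGORIES) -> list[tuple[str, str]]:
    """All unordered category pairs (six for the four familiar categories)."""
    return list(combinations(categories, 2))


def pairwise_svm_cv(
    patterns: BetaPatternSet,
    pair: tuple[str, str],
    cost: float = 1.0,
    standardize: bool = False,
) -> DecodingResult:
    """Leave-one-run-out linear SVM for one category pair.

    A decision score of exactly 0 (a tie on the boundary) counts as an
    error: conservative and deterministic.  With ``standardize`` the
    per-voxel mean/SD are estimated on the training folds only.
    """
    if patterns.n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    for cond in pair:
        if cond not in patterns.condition_labels:
            raise ValueError(f"condition {cond!r} missing from patterns")
    sub = patterns.select_conditions(tuple(pair))
    x = sub.betas  # (runs, 2, voxels)
    n_runs = sub.n_runs
    fold_acc = np.empty(n_runs)
    for test_run in range(n_runs):
        train_runs = [r for r in range(n_runs) if r != test_run]
        x_train = x[train_runs].reshape(-1, x.shape[2])
        y_train = np.tile([0, 1], len(train_runs))
        x_test = x[test_run]
        y_test = np.array([0, 1])
        if standardize:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        clf = SVC(kernel="linear", C=cost)
        clf.fit(x_train, y_train)
        scores = clf.decision_function(x_test)
        pred_correct = ((scores > 0) & (y_test == 1)) | ((scores < 0) & (y_test == 0))
        fold_acc[test_run] = pred_correct.mean()
    return DecodingResult(tuple(pair), fold_acc, float(fold_acc.mean()))


def decode_all_pairs(
    patterns: BetaPatternSet,
    categories: tuple[str, ...] = FAMILIAR_CATEGORIES,
    cost: float = 1.0,
    standardize: bool = False,
) -> list[DecodingResult]:
    return [
        pairwise_svm_cv(patterns, pair, cost=cost, standardize=standardize)
        for pair in category_pairs(categories)
    ]


def decoding_significance(
    accuracies_by_subject: np.ndarray,
    chance: float = 0.5,
    alpha: float = 0.05,
) -> GroupInferenceResult:
    """t-test of per-subject accuracies vs chance, BH-FDR across pairs.

    ``accuracies_by_subject`` is (n_subjects, n_pairs).
    """
    return group_inference(accuracies_by_subject, null_value=chance, alpha=alpha)
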