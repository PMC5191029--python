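"""End-to-end recognition runs: features -> split -> train -> score.

Glue over the feature, classifier and evaluation modules so examples,
the CLI and the tests share one code path for the two protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bpnet, evaluation, features
from .features import FeatureMatrix

__all__ = ["ProtocolResult", "run_dependent", "run_independent"]


@dataclass
class ProtocolResult:
    measures: evaluation.PerformanceMeasures
    matrix: evaluation.ConfusionMatrix
    model: bpnet.TrainedModel
    n_train: int
    n_test: int


def _fit_and_score(
    train: FeatureMatrix, test: FeatureMatrix, config: bpnet.TrainConfig,
) -> ProtocolResult:
    train_n, stats = features.normalize_features(train, train)
    test_n, _ = features.normalize_features(train, test)
    classes = sorted(int(c) for c in np.unique(train.activity))
    model = bpnet.fit_classifier(
        train_n.features.to_numpy(), train_n.activity, config, classes=classes
    )
    model.norm_mean = stats.mean.to_numpy()
    model.norm_sd = stats.sd.to_numpy()
    pred = bpnet.predict_labels(model, test_n.features.to_numpy())
    matrix = evaluation.confusion(test_n.activity, pred, classes)
    return ProtocolResult(
        measures=evaluation.measures(matrix),
        matrix=matrix,
        model=model,
        n_train=len(train),
        n_test=len(test),
    )


def run_dependent(
    matrix: FeatureMatrix,
    config: bpnet.TrainConfig | None = None,
    fraction: float = 0.5,
) -> ProtocolResult:
    """Pooled-subject chronological split, one model."""
    config = config or bpnet.TrainConfig()
    tr_mask, te_mask = evaluation.split_masks(
        matrix.subject, matrix.activity, matrix.start_time, fraction
    )
    return _fit_and_score(matrix.take(tr_mask), matrix.take(te_mask), config)


def run_independent(
    matrix: FeatureMatrix,
    config: bpnet.TrainConfig | None = None,
    fraction: float = 0.5,
) -> tuple[evaluation.PerformanceMeasures, dict[int, ProtocolResult]]:
    """One model per subject; measures aggregated by test-sample weight."""
    config = config or bpnet.TrainConfig()
    per_subject: dict[int, ProtocolResult] = {}
    weighted: list[tuple[evaluation.PerformanceMeasures, int]] = []
    for s in sorted(int(v) for v in np.unique(matrix.subject)):
        sub = matrix.take(matrix.subject == s)
        tr_mask, te_mask = evaluation.split_masks(
            sub.subject, sub.activity, sub.start_time, fraction
        )
        res = _fit_and_score(sub.take(tr_mask), sub.take(te_mask), config)
        per_subject[s] = res
        weighted.append((res.measures, res.n_test))
    return evaluation.overall_pm(weighted), per_subject
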