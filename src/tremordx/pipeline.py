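"""End-to-end two-stage pipeline glue: train both stages, predict, explain."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig, config_hash, stage_seed
from .data import Group, TremorAssessment
from .stage1 import SignalDataset, Stage1Model, build_signal_dataset, train_stage1
from .stage2 import (
    AssessmentDecision,
    QdaModel,
    classify_assessment,
    features_from_dataset,
    fit_naive_bayes,
    fit_qda,
)

__all__ = ["TrainedPipeline", "train_pipeline", "predict_dataset", "prepare_dataset"]


@dataclass
class TrainedPipeline:
    stage1: Stage1Model
    stage2: QdaModel
    config: PipelineConfig

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)


def prepare_dataset(assessments: list[TremorAssessment], config: PipelineConfig) -> SignalDataset:
    return build_signal_dataset(assessments, config.spectrogram)


def train_pipeline(
    train_ds: SignalDataset, config: PipelineConfig, seed: int | None = None
) -> TrainedPipeline:
    """Train stage 1 on the per-signal dataset, then fit stage 2 on the
    per-assessment feature vectors it produces."""
    cnn_seed = stage_seed(config.seed, "stage1") if seed is None else seed
    model = train_stage1(train_ds, replace(config.cnn, seed=cnn_seed))
    features = features_from_dataset(train_ds, model, mode=config.feature_mode)
    if config.classifier == "nb":
        stage2 = fit_naive_bayes(features)
    else:
        stage2 = fit_qda(features, shrinkage=config.shrinkage)
    return TrainedPipeline(stage1=model, stage2=stage2, config=config)


def predict_dataset(
    pipeline: TrainedPipeline, dataset: SignalDataset
) -> list[AssessmentDecision]:
    """Per-assessment decisions (with log likelihood ratios) for a dataset."""
    features = features_from_dataset(
        dataset, pipeline.stage1, mode=pipeline.config.feature_mode
    )
    return [
        classify_assessment(pipeline.stage2, f, threshold=pipeline.config.threshold)
        for f in features
    ]
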