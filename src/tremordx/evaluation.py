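"""Patient-wise splitting, Monte-Carlo accuracy estimation, ROC/AUC,
first-visit evaluation and wrapper feature ranking.

Splits are always by patient: every assessment of a patient (all visits,
both hands) lands on one side, so no recording of a test patient is ever
seen during stage-1 training or stage-2 fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import PipelineConfig, stage_seed
from .data import Group
from .pipeline import TrainedPipeline, predict_dataset, train_pipeline
from .stage1 import SignalDataset
from .stage2 import (
    FEATURE_DIM,
    AssessmentDecision,
    FeatureVector,
    all_feature_labels,
    classify_assessment,
    fit_qda,
    patient_prediction,
)

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "split_patients",
    "roc_auc",
    "monte_carlo_evaluate",
    "first_visit_evaluate",
    "rank_features_wrapper",
]


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float
    seed: int = 0
    first_visit_only_test: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_patients(patient_groups: dict, spec: SplitSpec) -> tuple[set, set]:
    """Stratified patient-level split into (train, test) id sets.

    Per-class test counts follow largest-remainder rounding of the overall
    rounded test total, with a floor of one test patient per class; a
    fraction that would empty a class on the training side is an error.
    """
    by_class: dict[Group, list] = {Group.PD: [], Group.ET: []}
    for pid, group in patient_groups.items():
        if group in by_class:
            by_class[group].append(pid)
    for group, pids in by_class.items():
        if len(pids) < 2:
            raise ValueError(f"need >= 2 patients in class {group.value} to split")

    n_total = sum(len(p) for p in by_class.values())
    n_test_total = _round_half_up(n_total * spec.test_fraction)
    quotas = {g: len(p) * spec.test_fraction for g, p in by_class.items()}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    leftover = n_test_total - sum(counts.values())
    # distribute by largest fractional remainder; ties favor PD (class order)
    order = sorted(
        by_class, key=lambda g: (-(quotas[g] - np.floor(quotas[g])), g is not Group.PD)
    )
    for g in order:
        if leftover <= 0:
            break
        counts[g] += 1
        leftover -= 1
    for g in by_class:
        counts[g] = max(counts[g], 1)  # both classes must appear in the test set
        if counts[g] >= len(by_class[g]):
            raise ValueError(
                f"test_fraction {spec.test_fraction} leaves class {g.value} "
                "empty on the training side"
            )

    rng = np.random.default_rng(spec.seed)
    test: set = set()
    for g in (Group.PD, Group.ET):
        pids = sorted(by_class[g])
        picked = rng.permutation(len(pids))[: counts[g]]
        test.update(pids[i] for i in picked)
    train = set(patient_groups) - test
    return train, test


def roc_auc(scored: Sequence[tuple]) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from (score, truth) pairs.

    ``score`` is the assessment log likelihood ratio (higher favors PD) and
    ``truth`` the true Group; PD is the positive class.  Thresholds sweep all
    observed scores, so tied scores produce diagonal segments and the
    trapezoid AUC equals the pairwise-concordance (Mann-Whitney) statistic.
    """
    scores = np.array([s for s, _ in scored], dtype=float)
    truths = np.array([t is Group.PD for _, t in scored], dtype=bool)
    n_pos = int(truths.sum())
    n_neg = truths.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truths[order]
    tp = np.cumsum(sorted_truth)
    fp = np.cumsum(~sorted_truth)
    # keep only the last index of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class EvaluationReport:
    patient_accuracy: float
    assessment_accuracy: float
    confusion: dict  # patient-level counts: tp, fn, fp, tn (PD positive)
    sensitivity: float
    specificity: float
    roc: np.ndarray
    auc: float
    n_repeats: int
    per_repeat_patient_accuracy: list
    per_repeat_assessment_accuracy: list
    test_fraction: float
    first_visit_only: bool = False
    epochs: int = 0
    excluded_patients: list = field(default_factory=list)


def _evaluate_repeat(
    dataset: SignalDataset, config: PipelineConfig, repeat: int, first_visit_only: bool
):
    pid_groups = {
        str(pid): Group.PD if label == 0 else Group.ET
        for pid, label in zip(dataset.patient_ids, dataset.labels)
    }
    train_ids, test_ids = split_patients(
        pid_groups,
        SplitSpec(config.test_fraction, seed=stage_seed(config.seed, "split", repeat)),
    )
    in_test = np.isin(dataset.patient_ids.astype(str), sorted(test_ids))
    train_ds = dataset.subset(~in_test)
    test_ds = dataset.subset(in_test)

    pipeline = train_pipeline(
        train_ds, config, seed=stage_seed(config.seed, "stage1", repeat)
    )
    decisions = predict_dataset(pipeline, test_ds)

    excluded: list = []
    if first_visit_only:
        with_v1 = {d.patient_id for d in decisions if d.visit == 1}
        excluded = sorted(set(d.patient_id for d in decisions) - with_v1)
        if excluded:
            warnings.warn(
                f"excluding test patients without a visit-1 assessment: {excluded}",
                RuntimeWarning,
                stacklevel=2,
            )
        decisions = [d for d in decisions if d.visit == 1]

    by_patient: dict[str, list] = {}
    for d in decisions:
        by_patient.setdefault(d.patient_id, []).append(d)

    confusion = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    n_correct_patients = 0
    for pid, ds in by_patient.items():
        truth = pid_groups[pid]
        correct, predicted = patient_prediction(ds, truth)
        n_correct_patients += correct
        if truth is Group.PD:
            confusion["tp" if predicted is Group.PD else "fn"] += 1
        else:
            confusion["tn" if predicted is Group.ET else "fp"] += 1

    patient_acc = n_correct_patients / len(by_patient) if by_patient else float("nan")
    assessment_acc = (
        float(np.mean([d.correct for d in decisions])) if decisions else float("nan")
    )
    scored = [(d.log_likelihood_ratio, d.group) for d in decisions]
    return patient_acc, assessment_acc, confusion, scored, excluded


def monte_carlo_evaluate(
    dataset: SignalDataset,
    config: PipelineConfig,
    test_fraction: float | None = None,
    n_repeats: int | None = None,
    first_visit_only: bool = False,
) -> EvaluationReport:
    """Repeatedly split/train/evaluate and average patient-level accuracy.

    Per-repeat split and training seeds derive from the master seed, so a
    report is bit-identically reproducible from (config, dataset).
    """
    if test_fraction is not None or n_repeats is not None:
        from dataclasses import replace

        config = replace(
            config,
            test_fraction=config.test_fraction if test_fraction is None else test_fraction,
            n_repeats=config.n_repeats if n_repeats is None else n_repeats,
        )
    patient_accs, assessment_accs = [], []
    confusion = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    scored_all: list = []
    excluded_all: list = []
    for repeat in range(config.n_repeats):
        p_acc, a_acc, conf, scored, excluded = _evaluate_repeat(
            dataset, config, repeat, first_visit_only
        )
        patient_accs.append(p_acc)
        assessment_accs.append(a_acc)
        for k in confusion:
            confusion[k] += conf[k]
        scored_all.extend(scored)
        excluded_all.extend(excluded)

    roc, auc = roc_auc(scored_all)
    tp, fn, fp, tn = (confusion[k] for k in ("tp", "fn", "fp", "tn"))
    return EvaluationReport(
        patient_accuracy=float(np.mean(patient_accs)),
        assessment_accuracy=float(np.mean(assessment_accs)),
        confusion=confusion,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        roc=roc,
        auc=auc,
        n_repeats=config.n_repeats,
        per_repeat_patient_accuracy=patient_accs,
        per_repeat_assessment_accuracy=assessment_accs,
        test_fraction=config.test_fraction,
        first_visit_only=first_visit_only,
        epochs=config.cnn.epochs,
        excluded_patients=excluded_all,
    )


def first_visit_evaluate(
    dataset: SignalDataset,
    config: PipelineConfig,
    test_fraction: float | None = None,
    n_repeats: int | None = None,
) -> EvaluationReport:
    """Monte-Carlo evaluation scoring only visit-1 assessments of test patients.

    Training still uses all visits of the training patients.
    """
    return monte_carlo_evaluate(
        dataset, config, test_fraction, n_repeats, first_visit_only=True
    )


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def rank_features_wrapper(
    features,
    labels=None,
    classifier_factory: Callable | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Rank features by single-feature k-fold CV accuracy, descending.

    Each feature alone is used to fit the second-stage classifier; ties are
    broken by canonical feature index.  Labels are 0=PD / 1=ET; feature lists
    of FeatureVector carry their own labels.
    """
    if len(features) and isinstance(features[0], FeatureVector):
        mat = np.stack([f.values for f in features])
        labels = np.array([0 if f.group is Group.PD else 1 for f in features])
    else:
        mat = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=int)
    if mat.shape[1] != FEATURE_DIM:
        raise ValueError(f"expected {FEATURE_DIM}-dimensional features")

    if classifier_factory is None:
        classifier_factory = lambda x, y: fit_qda(x, y, shrinkage=0.0)

    folds = _stratified_folds(labels, k, seed)
    feature_labels = all_feature_labels()
    results = []
    for j in range(mat.shape[1]):
        col = mat[:, [j]]
        correct = 0
        for fold in folds:
            mask = np.zeros(mat.shape[0], dtype=bool)
            mask[fold] = True
            model = classifier_factory(col[~mask], labels[~mask])
            for row, y in zip(col[mask], labels[mask]):
                d = classify_assessment(model, row)
                correct += (d.predicted is Group.PD) == (y == 0)
        results.append(
            {
                "index": j,
                "label": feature_labels[j],
                "cv_accuracy": correct / mat.shape[0],
            }
        )
    return sorted(results, key=lambda r: (-r["cv_accuracy"], r["index"]))
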