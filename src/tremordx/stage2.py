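"""Second-stage classifier: QDA likelihood ratio over 54 per-assessment votes.

Feature order is canonical: index = (trial-1)*18 + task_hint_index*3 +
axis_index, i.e. trial-major, then task, then axis (x, y, z).  The likelihood
ratio N(f; mu_PD, Sigma_PD) / N(f; mu_ET, Sigma_ET) is evaluated in log space;
values above the threshold (default 1) vote PD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import AXES, INCLUDED_TASKS, TRIALS, Axis, Group, TaskLabel, TremorAssessment
from .stage1 import Stage1Model, SignalDataset, encode_task_hint

__all__ = [
    "FEATURE_DIM",
    "FeatureVector",
    "QdaModel",
    "AssessmentDecision",
    "feature_index",
    "feature_label",
    "all_feature_labels",
    "assemble_features",
    "features_from_dataset",
    "fit_qda",
    "fit_naive_bayes",
    "qda_log_likelihood_ratio",
    "qda_likelihood_ratio",
    "classify_assessment",
    "decide_patient",
    "patient_prediction",
]

FEATURE_DIM = 54


def feature_index(trial: int, task: TaskLabel, axis: Axis) -> int:
    """Canonical position of (trial, task, axis) in the 54-vector."""
    if trial not in TRIALS:
        raise ValueError(f"trial must be in {TRIALS}")
    return (trial - 1) * 18 + task.hint_index * 3 + axis.index


def feature_label(trial: int, task: TaskLabel, axis: Axis) -> str:
    """Human-readable label: [TrialNumber-TaskName-RecordingChannel]."""
    return f"{trial}-{task.value}-{axis.value}"


def all_feature_labels() -> list[str]:
    labels = [""] * FEATURE_DIM
    for trial in TRIALS:
        for task in INCLUDED_TASKS:
            for axis in AXES:
                labels[feature_index(trial, task, axis)] = feature_label(trial, task, axis)
    return labels


@dataclass
class FeatureVector:
    values: np.ndarray  # (54,)
    mode: str  # probabilistic | binary
    patient_id: str
    group: Group
    visit: int
    hand: object

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FEATURE_DIM,):
            raise ValueError(f"feature vector must have shape ({FEATURE_DIM},)")

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.visit, self.hand)


def _binarize(p_pd: np.ndarray) -> np.ndarray:
    # ties (p == 0.5) map to 0
    return (p_pd > 0.5).astype(float)


def assemble_features(
    assessment: TremorAssessment,
    model: Stage1Model,
    mode: str = "probabilistic",
    spectrogram_params=None,
) -> FeatureVector:
    """Run every signal of one assessment through stage 1 and order the votes."""
    from .preprocessing import SpectrogramParams, preprocess_signal

    if mode not in ("probabilistic", "binary"):
        raise ValueError(f"unknown feature mode: {mode!r}")
    params = spectrogram_params or SpectrogramParams()
    values = np.empty(FEATURE_DIM)
    X, hints, slots = [], [], []
    for (task, trial, axis), sig in assessment.signals.items():
        X.append(preprocess_signal(sig, params).power)
        hints.append(encode_task_hint(task))
        slots.append(feature_index(trial, task, axis))
    probs = model.forward_batch(np.asarray(X), np.asarray(hints))
    values[np.asarray(slots)] = probs[:, 0]  # p_PD
    if mode == "binary":
        values = _binarize(values)
    return FeatureVector(
        values=values,
        mode=mode,
        patient_id=assessment.patient_id,
        group=assessment.group,
        visit=assessment.visit,
        hand=assessment.hand,
    )


def features_from_dataset(
    dataset: SignalDataset, model: Stage1Model, mode: str = "probabilistic"
) -> list[FeatureVector]:
    """Assemble per-assessment feature vectors from a preprocessed dataset.

    Avoids recomputing spectrograms when they are already in a SignalDataset.
    """
    if mode not in ("probabilistic", "binary"):
        raise ValueError(f"unknown feature mode: {mode!r}")
    p_pd = model.predict_proba_pd(dataset.X, dataset.hints)
    buckets: dict[tuple, dict] = {}
    for i, akey in enumerate(dataset.assessment_keys):
        b = buckets.setdefault(
            akey, {"values": np.full(FEATURE_DIM, np.nan), "label": dataset.labels[i]}
        )
        task, trial, axis = dataset.signal_keys[i]
        b["values"][feature_index(trial, task, axis)] = p_pd[i]
    out = []
    for akey in sorted(buckets, key=lambda k: (k[0], k[1], k[2].value)):
        b = buckets[akey]
        if np.isnan(b["values"]).any():
            raise ValueError(f"incomplete assessment in dataset: {akey}")
        values = _binarize(b["values"]) if mode == "binary" else b["values"]
        out.append(
            FeatureVector(
                values=values,
                mode=mode,
                patient_id=akey[0],
                group=Group.PD if b["label"] == 0 else Group.ET,
                visit=akey[1],
                hand=akey[2],
            )
        )
    return out


@dataclass
class QdaModel:
    mu_pd: np.ndarray
    mu_et: np.ndarray
    sigma_pd: np.ndarray
    sigma_et: np.ndarray
    shrinkage: float
    priors: tuple = (0.5, 0.5)

    def __post_init__(self) -> None:
        d = self.mu_pd.shape[0]
        for sigma in (self.sigma_pd, self.sigma_et):
            if sigma.shape != (d, d):
                raise ValueError("covariance shape mismatch")
            if not np.allclose(sigma, sigma.T):
                raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mu_pd.shape[0]

    def swapped(self) -> "QdaModel":
        return QdaModel(
            mu_pd=self.mu_et,
            mu_et=self.mu_pd,
            sigma_pd=self.sigma_et,
            sigma_et=self.sigma_pd,
            shrinkage=self.shrinkage,
            priors=(self.priors[1], self.priors[0]),
        )


def _regularized_cov(samples: np.ndarray, shrinkage: float) -> np.ndarray:
    """(1-s) * S + s * diag(S) + eps*I with eps = 1e-6 * mean diagonal."""
    s_mat = np.cov(samples, rowvar=False, ddof=1)
    s_mat = np.atleast_2d(s_mat)
    sigma = (1.0 - shrinkage) * s_mat + shrinkage * np.diag(np.diag(s_mat))
    mean_diag = float(np.diag(s_mat).mean())
    eps = 1e-6 * (mean_diag if mean_diag > 0 else 1.0)
    return sigma + eps * np.eye(s_mat.shape[0])


def _as_matrix(features) -> tuple[np.ndarray, np.ndarray | None]:
    if len(features) and isinstance(features[0], FeatureVector):
        mat = np.stack([f.values for f in features])
        labels = np.array([0 if f.group is Group.PD else 1 for f in features])
        return mat, labels
    return np.atleast_2d(np.asarray(features, dtype=float)), None


def fit_qda(
    features, labels=None, shrinkage: float = 0.1, priors: tuple = (0.5, 0.5)
) -> QdaModel:
    """Fit class means and regularized covariances.

    ``features`` may be a list of FeatureVector (labels taken from their
    groups) or an (n, d) array with an explicit 0/1 label vector (0=PD).
    """
    mat, inferred = _as_matrix(features)
    labels = np.asarray(inferred if labels is None else labels, dtype=int)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    pd_rows = mat[labels == 0]
    et_rows = mat[labels == 1]
    if pd_rows.shape[0] < 2 or et_rows.shape[0] < 2:
        raise ValueError("each class needs at least 2 training assessments")
    return QdaModel(
        mu_pd=pd_rows.mean(axis=0),
        mu_et=et_rows.mean(axis=0),
        sigma_pd=_regularized_cov(pd_rows, shrinkage),
        sigma_et=_regularized_cov(et_rows, shrinkage),
        shrinkage=shrinkage,
        priors=priors,
    )


def fit_naive_bayes(features, labels=None, priors: tuple = (0.5, 0.5)) -> QdaModel:
    """Diagonal-Gaussian per-feature class conditionals (same interface as QDA).

    Structurally a QdaModel whose covariances are diagonal; fitted feature by
    feature with per-feature sample variances.
    """
    mat, inferred = _as_matrix(features)
    labels = np.asarray(inferred if labels is None else labels, dtype=int)
    pd_rows = mat[labels == 0]
    et_rows = mat[labels == 1]
    if pd_rows.shape[0] < 2 or et_rows.shape[0] < 2:
        raise ValueError("each class needs at least 2 training assessments")

    def diag_cov(rows: np.ndarray) -> np.ndarray:
        var = rows.var(axis=0, ddof=1)
        mean_diag = float(var.mean())
        eps = 1e-6 * (mean_diag if mean_diag > 0 else 1.0)
        return np.diag(var + eps)

    return QdaModel(
        mu_pd=pd_rows.mean(axis=0),
        mu_et=et_rows.mean(axis=0),
        sigma_pd=diag_cov(pd_rows),
        sigma_et=diag_cov(et_rows),
        shrinkage=1.0,
        priors=priors,
    )


def _log_gaussian(f: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    d = mu.shape[0]
    chol = np.linalg.cholesky(sigma)
    diff = f - mu
    solved = np.linalg.solve(chol, diff)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(
        -0.5 * (d * np.log(2.0 * np.pi) + logdet + solved @ solved)
    )


def qda_log_likelihood_ratio(model: QdaModel, f) -> float:
    """log [ N(f; mu_PD, Sigma_PD) / N(f; mu_ET, Sigma_ET) ]."""
    f = np.asarray(f.values if isinstance(f, FeatureVector) else f, dtype=float)
    if f.shape != (model.dim,):
        raise ValueError(f"feature dimension {f.shape} != ({model.dim},)")
    return _log_gaussian(f, model.mu_pd, model.sigma_pd) - _log_gaussian(
        f, model.mu_et, model.sigma_et
    )


def qda_likelihood_ratio(model: QdaModel, f) -> float:
    """Positive likelihood ratio; values > 1 favor PD."""
    with np.errstate(over="ignore"):
        return float(np.exp(qda_log_likelihood_ratio(model, f)))


@dataclass
class AssessmentDecision:
    predicted: Group
    log_likelihood_ratio: float
    threshold_used: float
    patient_id: str = ""
    group: Group = Group.UNKNOWN  # ground truth when known
    visit: int = 1
    hand: object = None

    @property
    def correct(self) -> bool:
        return self.group is not Group.UNKNOWN and self.predicted is self.group

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.visit, self.hand)


def classify_assessment(
    model: QdaModel, f, threshold: float = 1.0
) -> AssessmentDecision:
    """PD iff likelihood ratio strictly exceeds the threshold (ties -> ET)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    llr = qda_log_likelihood_ratio(model, f)
    predicted = Group.PD if llr > np.log(threshold) else Group.ET
    kwargs = {}
    if isinstance(f, FeatureVector):
        kwargs = dict(
            patient_id=f.patient_id, group=f.group, visit=f.visit, hand=f.hand
        )
    return AssessmentDecision(
        predicted=predicted,
        log_likelihood_ratio=llr,
        threshold_used=threshold,
        **kwargs,
    )


def decide_patient(decisions: Sequence[AssessmentDecision], truth: Group) -> bool:
    """Logical-AND fusion: the patient is correct iff every test-set
    assessment decision equals the true label."""
    if not decisions:
        raise ValueError("patient has no assessment decisions")
    return all(d.predicted is truth for d in decisions)


def patient_prediction(
    decisions: Sequence[AssessmentDecision], truth: Group
) -> tuple[bool, Group]:
    """(correct, predicted label) for confusion-matrix bookkeeping.

    Under the AND rule a patient with disagreeing assessments is incorrect;
    for the confusion matrix they get the majority label, with ties broken
    *against* the truth so the matrix stays consistent with incorrectness.
    """
    correct = decide_patient(decisions, truth)
    votes = [d.predicted for d in decisions]
    n_pd = sum(v is Group.PD for v in votes)
    n_et = len(votes) - n_pd
    if n_pd > n_et:
        predicted = Group.PD
    elif n_et > n_pd:
        predicted = Group.ET
    else:
        predicted = Group.ET if truth is Group.PD else Group.PD
    return correct, predicted
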