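"""First-stage classifier: spectrogram CNN with 6-bit task-hint injection.

The network votes PD vs ET on every single-axis recording; the second stage
aggregates the 54 votes of one assessment.  Class index 0 is PD, 1 is ET.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .data import INCLUDED_TASKS, Group, TaskLabel, TremorAssessment, ExcludedTaskError
from .nn import Adam, ConvSpec, Network, softmax_cross_entropy
from .preprocessing import SpectrogramParams, preprocess_signal

__all__ = [
    "PD_CLASS",
    "ET_CLASS",
    "CnnConfig",
    "Stage1Model",
    "SignalDataset",
    "ModelIOError",
    "encode_task_hint",
    "build_signal_dataset",
    "train_stage1",
    "crossvalidate_stage1",
    "save_model",
    "load_model",
]

PD_CLASS = 0
ET_CLASS = 1
_CHECKPOINT_VERSION = 1

GROUP_TO_CLASS = {Group.PD: PD_CLASS, Group.ET: ET_CLASS}
CLASS_TO_GROUP = {PD_CLASS: Group.PD, ET_CLASS: Group.ET}


class ModelIOError(ValueError):
    """Checkpoint cannot be read or has an incompatible version."""


@dataclass(frozen=True)
class CnnConfig:
    """Architecture + optimization settings for the first-stage classifier."""

    conv_specs: tuple = (
        ConvSpec(filters=8, kernel=5, stride=1, pool=2),
        ConvSpec(filters=16, kernel=3, stride=1, pool=2),
    )
    dense_widths: tuple = (128, 64, 2)
    leaky_slope: float = 0.1
    learning_rate: float = 0.0001
    epochs: int = 44
    batch_size: int = 32
    seed: int = 0
    use_hints: bool = True
    input_shape: tuple = (129, 191)

    def __post_init__(self) -> None:
        if len(self.conv_specs) != 2:
            raise ValueError("exactly 2 convolutional layers are required")
        if len(self.dense_widths) != 3 or self.dense_widths[-1] != 2:
            raise ValueError("exactly 3 dense layers, last of width 2, are required")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_specs"] = [asdict(cs) for cs in self.conv_specs]
        d["dense_widths"] = list(self.dense_widths)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CnnConfig":
        d = dict(d)
        d["conv_specs"] = tuple(ConvSpec(**cs) for cs in d["conv_specs"])
        d["dense_widths"] = tuple(d["dense_widths"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


def encode_task_hint(task: TaskLabel) -> np.ndarray:
    """One-hot 6-bit hint vector at the task's fixed index."""
    if task.excluded_from_pipeline:
        raise ExcludedTaskError(f"{task.value} is excluded from the pipeline")
    bits = np.zeros(6)
    bits[task.hint_index] = 1.0
    return bits


@dataclass
class SignalDataset:
    """Per-signal training matrix with provenance for patient-wise splits."""

    X: np.ndarray  # (N, 129, 191) scaled spectrograms
    hints: np.ndarray  # (N, 6)
    labels: np.ndarray  # (N,) class indices (0=PD, 1=ET)
    patient_ids: np.ndarray  # (N,) str
    assessment_keys: list  # (patient_id, visit, hand) per signal
    signal_keys: list  # (task, trial, axis) per signal

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "SignalDataset":
        idx = np.flatnonzero(mask)
        return SignalDataset(
            X=self.X[idx],
            hints=self.hints[idx],
            labels=self.labels[idx],
            patient_ids=self.patient_ids[idx],
            assessment_keys=[self.assessment_keys[i] for i in idx],
            signal_keys=[self.signal_keys[i] for i in idx],
        )


def build_signal_dataset(
    assessments: list[TremorAssessment],
    params: SpectrogramParams | None = None,
) -> SignalDataset:
    """Preprocess every signal of every assessment into network inputs."""
    params = params or SpectrogramParams()
    X, hints, labels, pids, akeys, skeys = [], [], [], [], [], []
    for a in assessments:
        if a.group not in GROUP_TO_CLASS:
            raise ValueError(f"assessment {a.key} has no PD/ET ground truth")
        for task in INCLUDED_TASKS:
            for trial in (1, 2, 3):
                for axis_key in sorted(
                    (k for k in a.signals if k[0] == task and k[1] == trial),
                    key=lambda k: k[2].value,
                ):
                    sig = a.signals[axis_key]
                    spec = preprocess_signal(sig, params)
                    X.append(spec.power)
                    hints.append(encode_task_hint(task))
                    labels.append(GROUP_TO_CLASS[a.group])
                    pids.append(a.patient_id)
                    akeys.append(a.key)
                    skeys.append(axis_key)
    return SignalDataset(
        X=np.asarray(X),
        hints=np.asarray(hints),
        labels=np.asarray(labels, dtype=int),
        patient_ids=np.asarray(pids, dtype=object),
        assessment_keys=akeys,
        signal_keys=skeys,
    )


@dataclass
class Stage1Model:
    params: dict
    config: CnnConfig
    training_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._net = Network(
            conv_specs=self.config.conv_specs,
            dense_widths=self.config.dense_widths,
            input_shape=self.config.input_shape,
            leaky_slope=self.config.leaky_slope,
            use_hints=self.config.use_hints,
        )

    @property
    def network(self) -> Network:
        return self._net

    def forward_batch(self, X: np.ndarray, hints: np.ndarray) -> np.ndarray:
        probs, _ = self._net.forward(self.params, X, hints)
        return probs

    def forward(self, spec_grid: np.ndarray, hint: np.ndarray) -> tuple:
        """Single-signal forward pass -> (p_PD, p_ET)."""
        probs = self.forward_batch(
            np.asarray(spec_grid)[None, ...], np.asarray(hint)[None, :]
        )
        return float(probs[0, PD_CLASS]), float(probs[0, ET_CLASS])

    def predict_proba_pd(self, X: np.ndarray, hints: np.ndarray) -> np.ndarray:
        return self.forward_batch(X, hints)[:, PD_CLASS]


def _mean_loss(net: Network, params: dict, X, hints, labels, batch: int) -> float:
    total, n = 0.0, X.shape[0]
    for s in range(0, n, batch):
        probs, cache = net.forward(params, X[s : s + batch], hints[s : s + batch])
        loss, _ = softmax_cross_entropy(cache["logits"], labels[s : s + batch])
        total += loss * (min(s + batch, n) - s)
    return total / n


def train_stage1(
    dataset: SignalDataset,
    config: CnnConfig,
    val: SignalDataset | None = None,
    verbose: bool = False,
) -> Stage1Model:
    """Train the CNN for exactly ``config.epochs`` epochs with Adam.

    The training log records per-epoch mean cross-entropy (computed over the
    minibatch losses of the epoch) and, if ``val`` is given, the per-signal
    validation accuracy.
    """
    classes = np.unique(dataset.labels)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")

    net = Network(
        conv_specs=config.conv_specs,
        dense_widths=config.dense_widths,
        input_shape=config.input_shape,
        leaky_slope=config.leaky_slope,
        use_hints=config.use_hints,
    )
    rng = np.random.default_rng(config.seed)
    params = net.init_params(rng)
    opt = Adam(params, lr=config.learning_rate)
    n = len(dataset)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            probs, cache = net.forward(params, dataset.X[idx], dataset.hints[idx])
            loss, dlogits = softmax_cross_entropy(cache["logits"], dataset.labels[idx])
            grads, _, _ = net.backward(params, cache, dlogits)
            opt.step(params, grads)
            epoch_loss += loss * idx.size
            seen += idx.size
        entry = {"epoch": epoch + 1, "train_loss": epoch_loss / seen}
        if val is not None and len(val):
            vp = net.forward(params, val.X, val.hints)[0]
            entry["val_accuracy"] = float((vp.argmax(axis=1) == val.labels).mean())
        log.append(entry)
        if verbose:
            print(f"epoch {entry['epoch']}: {entry}")
    return Stage1Model(params=params, config=config, training_log=log)


def partition_patients(
    patient_ids: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Shuffle unique patients and deal them round-robin into k folds."""
    patients = np.asarray(sorted(set(patient_ids)))
    if k > patients.size:
        raise ValueError(f"k={k} folds but only {patients.size} patients")
    rng = np.random.default_rng(seed)
    shuffled = patients[rng.permutation(patients.size)]
    return [shuffled[i::k] for i in range(k)]


def crossvalidate_stage1(
    dataset: SignalDataset, config: CnnConfig, k: int = 5
) -> tuple[list[float], float]:
    """Patient-wise k-fold cross-validation of per-signal accuracy.

    Folds partition patients, never signals: all recordings of a validation
    patient are unseen during that fold's training.
    """
    folds = partition_patients(dataset.patient_ids, k, config.seed)
    accuracies = []
    for i, fold_patients in enumerate(folds):
        val_mask = np.isin(dataset.patient_ids.astype(str), fold_patients.astype(str))
        train = dataset.subset(~val_mask)
        valset = dataset.subset(val_mask)
        model = train_stage1(train, replace(config, seed=config.seed + i), val=None)
        probs = model.forward_batch(valset.X, valset.hints)
        accuracies.append(float((probs.argmax(axis=1) == valset.labels).mean()))
    return accuracies, float(np.mean(accuracies))


def save_model(model: Stage1Model, path: str | Path) -> None:
    meta = {
        "version": _CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "training_log": model.training_log,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path: str | Path) -> Stage1Model:
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    except Exception as exc:
        raise ModelIOError(f"cannot load model checkpoint {path}: {exc}") from exc
    if meta.get("version") != _CHECKPOINT_VERSION:
        raise ModelIOError(
            f"checkpoint version {meta.get('version')} != {_CHECKPOINT_VERSION}"
        )
    return Stage1Model(
        params=params,
        config=CnnConfig.from_dict(meta["config"]),
        training_log=meta["training_log"],
    )
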