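"""Cohort data model: tasks, signals, assessments, and the manifest I/O layer.

A cohort is described by a CSV manifest (one row per single-axis recording)
plus one plain-text signal file per row.  Assessments -- the 54-signal unit
consumed by the second-stage classifier -- are derived views, never
serialized directly.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TaskLabel",
    "Group",
    "Hand",
    "Axis",
    "TremorSignal",
    "TremorAssessment",
    "ManifestEntry",
    "CohortManifest",
    "AssessmentKey",
    "AssessmentIndex",
    "ManifestSchemaError",
    "ManifestIntegrityError",
    "SignalParseError",
    "SignalIntegrityError",
    "ExcludedTaskError",
    "IncompleteAssessmentError",
    "INCLUDED_TASKS",
    "TRIALS",
    "AXES",
    "RECORDING_DURATION_S",
    "SIGNALS_PER_ASSESSMENT",
    "load_manifest",
    "write_manifest",
    "read_signal",
    "write_signal",
    "index_assessments",
    "assemble_assessments",
    "load_assessment",
]

RECORDING_DURATION_S = 20.0
SIGNALS_PER_ASSESSMENT = 54  # 6 tasks x 3 trials x 3 axes
TRIALS = (1, 2, 3)

MANIFEST_COLUMNS = (
    "patient_id",
    "group",
    "visit",
    "hand",
    "task",
    "trial",
    "axis",
    "fs",
    "file_path",
)


class ManifestSchemaError(ValueError):
    """Manifest header/columns do not match the expected schema."""


class ManifestIntegrityError(ValueError):
    """Manifest rows are individually parseable but collectively invalid."""


class SignalParseError(ValueError):
    """A signal file contains non-numeric or non-finite rows."""


class SignalIntegrityError(ValueError):
    """A signal file's length is inconsistent with its declared metadata."""


class ExcludedTaskError(ValueError):
    """The finger-to-nose task is excluded from the classification pipeline."""


class IncompleteAssessmentError(ValueError):
    """An operation requiring a complete 54-signal assessment got less."""


class TaskLabel(enum.Enum):
    """The 7 scripted recording tasks; the kinetic one is pipeline-excluded."""

    REST1 = "Rest1"
    REST2 = "Rest2"
    POSTURE1 = "Posture1"
    POSTURE2 = "Posture2"
    LOAD1 = "Load1"
    LOAD2 = "Load2"
    FINGER_TO_NOSE = "FingerToNose"

    @property
    def excluded_from_pipeline(self) -> bool:
        return self is TaskLabel.FINGER_TO_NOSE

    @property
    def hint_index(self) -> int:
        """Fixed position of this task in the 6-bit hint vector."""
        if self.excluded_from_pipeline:
            raise ExcludedTaskError(
                f"{self.value} has no hint index: it is excluded from the pipeline"
            )
        return INCLUDED_TASKS.index(self)

    @classmethod
    def parse(cls, text: str) -> "TaskLabel":
        key = text.strip().lower()
        try:
            return _TASK_BY_NAME[key]
        except KeyError:
            raise ManifestIntegrityError(f"unknown task label: {text!r}") from None


INCLUDED_TASKS = (
    TaskLabel.REST1,
    TaskLabel.REST2,
    TaskLabel.POSTURE1,
    TaskLabel.POSTURE2,
    TaskLabel.LOAD1,
    TaskLabel.LOAD2,
)

_TASK_BY_NAME = {t.value.lower(): t for t in TaskLabel}
# tolerate hyphenated spellings in hand-edited manifests
_TASK_BY_NAME.update({t.value.lower().replace("finger", "finger-"): t for t in TaskLabel})
for _t in TaskLabel:
    _TASK_BY_NAME[_t.name.lower()] = _t


class Group(enum.Enum):
    PD = "PD"
    ET = "ET"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Group":
        key = text.strip().lower()
        for g in cls:
            if g.value.lower() == key:
                return g
        raise ManifestIntegrityError(f"unknown group label: {text!r}")


class Hand(enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def parse(cls, text: str) -> "Hand":
        key = text.strip().lower()
        for h in cls:
            if h.value == key:
                return h
        raise ManifestIntegrityError(f"unknown hand label: {text!r}")


class Axis(enum.Enum):
    X = "x"
    Y = "y"
    Z = "z"

    @property
    def index(self) -> int:
        return AXES.index(self)

    @classmethod
    def parse(cls, text: str) -> "Axis":
        key = text.strip().lower()
        for a in cls:
            if a.value == key:
                return a
        raise ManifestIntegrityError(f"unknown axis label: {text!r}")


AXES = (Axis.X, Axis.Y, Axis.Z)


@dataclass
class TremorSignal:
    """One single-axis acceleration recording with full provenance."""

    samples: np.ndarray
    fs: float
    patient_id: str
    group: Group
    visit: int
    hand: Hand
    task: TaskLabel
    trial: int
    axis: Axis

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.trial not in TRIALS:
            raise ValueError(f"trial must be one of {TRIALS}")
        if self.visit < 1:
            raise ValueError("visit must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace_samples(self, samples: np.ndarray, fs: float | None = None) -> "TremorSignal":
        return TremorSignal(
            samples=samples,
            fs=self.fs if fs is None else fs,
            patient_id=self.patient_id,
            group=self.group,
            visit=self.visit,
            hand=self.hand,
            task=self.task,
            trial=self.trial,
            axis=self.axis,
        )


AssessmentKey = tuple  # (patient_id, visit, hand)


@dataclass
class TremorAssessment:
    """The 54-signal bundle for one patient-visit-hand."""

    patient_id: str
    group: Group
    visit: int
    hand: Hand
    signals: Mapping[tuple, TremorSignal]  # (task, trial, axis) -> signal

    def __post_init__(self) -> None:
        expected = {
            (task, trial, axis)
            for task in INCLUDED_TASKS
            for trial in TRIALS
            for axis in AXES
        }
        got = set(self.signals.keys())
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise IncompleteAssessmentError(
                f"assessment {self.key} needs exactly {SIGNALS_PER_ASSESSMENT} "
                f"signals; missing={sorted(str(m) for m in missing)[:5]} "
                f"extra={sorted(str(e) for e in extra)[:5]}"
            )
        for sig in self.signals.values():
            if (sig.patient_id, sig.visit, sig.hand) != self.key:
                raise IncompleteAssessmentError(
                    f"signal {sig.patient_id}/{sig.visit}/{sig.hand} does not "
                    f"belong to assessment {self.key}"
                )
            if sig.group != self.group:
                raise IncompleteAssessmentError("inconsistent group label within assessment")

    @property
    def key(self) -> AssessmentKey:
        return (self.patient_id, self.visit, self.hand)

    def __len__(self) -> int:
        return len(self.signals)


@dataclass(frozen=True)
class ManifestEntry:
    patient_id: str
    group: Group
    visit: int
    hand: Hand
    task: TaskLabel
    trial: int
    axis: Axis
    fs: float
    file_path: str

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.visit, self.hand, self.task, self.trial, self.axis)


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]
    root: Path = field(default_factory=Path)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        seen: set[tuple] = set()
        for e in self.entries:
            if e.key in seen:
                raise ManifestIntegrityError(f"duplicate manifest key: {e.key}")
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def included_entries(self) -> list[ManifestEntry]:
        return [e for e in self.entries if not e.task.excluded_from_pipeline]

    @property
    def patient_ids(self) -> list[str]:
        return sorted({e.patient_id for e in self.entries})

    def patient_groups(self) -> dict[str, Group]:
        groups: dict[str, Group] = {}
        for e in self.entries:
            prev = groups.setdefault(e.patient_id, e.group)
            if prev != e.group:
                raise ManifestIntegrityError(
                    f"patient {e.patient_id} appears with conflicting group labels"
                )
        return groups

    def resolve(self, entry: ManifestEntry) -> Path:
        p = Path(entry.file_path)
        return p if p.is_absolute() else self.root / p


def _parse_row(row: dict, line_no: int) -> ManifestEntry:
    try:
        visit = int(row["visit"])
        trial = int(row["trial"])
        fs = float(row["fs"])
    except ValueError as exc:
        raise ManifestIntegrityError(f"manifest line {line_no}: {exc}") from None
    if fs <= 0:
        raise ManifestIntegrityError(f"manifest line {line_no}: fs must be > 0")
    if trial not in TRIALS:
        raise ManifestIntegrityError(f"manifest line {line_no}: trial must be in {TRIALS}")
    return ManifestEntry(
        patient_id=row["patient_id"].strip(),
        group=Group.parse(row["group"]),
        visit=visit,
        hand=Hand.parse(row["hand"]),
        task=TaskLabel.parse(row["task"]),
        trial=trial,
        axis=Axis.parse(row["axis"]),
        fs=fs,
        file_path=row["file_path"].strip(),
    )


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Parameters
    ----------
    path
        Manifest file; signal paths are resolved relative to its directory.
    check_files
        When true (default) every referenced signal file must exist.
    """
    path = Path(path)
    try:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ManifestSchemaError(f"{path}: empty manifest (no header row)")
            header = tuple(name.strip() for name in reader.fieldnames)
            if set(header) != set(MANIFEST_COLUMNS):
                missing = set(MANIFEST_COLUMNS) - set(header)
                extra = set(header) - set(MANIFEST_COLUMNS)
                raise ManifestSchemaError(
                    f"{path}: bad manifest header; missing={sorted(missing)} "
                    f"extra={sorted(extra)}"
                )
            entries = [_parse_row(row, i + 2) for i, row in enumerate(reader)]
    except OSError as exc:
        raise OSError(f"cannot read manifest {path}: {exc}") from exc

    manifest = CohortManifest(entries=entries, root=path.parent)
    if check_files:
        for e in entries:
            if not manifest.resolve(e).is_file():
                raise ManifestIntegrityError(
                    f"manifest references missing file: {e.file_path}"
                )
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for e in manifest.entries:
            writer.writerow(
                [
                    e.patient_id,
                    e.group.value,
                    e.visit,
                    e.hand.value,
                    e.task.value,
                    e.trial,
                    e.axis.value,
                    _fmt_fs(e.fs),
                    e.file_path,
                ]
            )


def _fmt_fs(fs: float) -> str:
    return str(int(fs)) if float(fs).is_integer() else repr(fs)


def write_signal(samples: np.ndarray, path: str | Path) -> None:
    """Write one sample per line, LF-terminated plain text."""
    samples = np.asarray(samples, dtype=float)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(f"{v:.8g}" for v in samples))
        fh.write("\n")


def read_signal(
    entry: ManifestEntry,
    root: str | Path = ".",
    duration_s: float = RECORDING_DURATION_S,
) -> TremorSignal:
    """Read a single-column signal file and attach the entry's metadata.

    The file length must equal round(duration_s * fs) within one sample.
    """
    p = Path(entry.file_path)
    if not p.is_absolute():
        p = Path(root) / p
    try:
        samples = np.loadtxt(p, dtype=float, ndmin=1)
    except ValueError as exc:
        raise SignalParseError(f"{p}: non-numeric sample row ({exc})") from None
    if samples.ndim != 1:
        raise SignalParseError(f"{p}: expected a single column of samples")
    if not np.all(np.isfinite(samples)):
        raise SignalParseError(f"{p}: contains NaN/inf sample rows")
    expected = round(duration_s * entry.fs)
    if abs(samples.shape[0] - expected) > 1:
        raise SignalIntegrityError(
            f"{p}: {samples.shape[0]} samples, expected {expected} "
            f"({duration_s} s at {entry.fs} Hz)"
        )
    return TremorSignal(
        samples=samples,
        fs=entry.fs,
        patient_id=entry.patient_id,
        group=entry.group,
        visit=entry.visit,
        hand=entry.hand,
        task=entry.task,
        trial=entry.trial,
        axis=entry.axis,
    )


@dataclass
class AssessmentIndex:
    """Bookkeeping view of one complete assessment (entries, not samples)."""

    patient_id: str
    group: Group
    visit: int
    hand: Hand
    entries: dict  # (task, trial, axis) -> ManifestEntry

    @property
    def key(self) -> AssessmentKey:
        return (self.patient_id, self.visit, self.hand)


def index_assessments(
    manifest: CohortManifest,
) -> tuple[list[AssessmentIndex], list[dict]]:
    """Group included manifest entries into complete 54-signal assessments.

    Finger-to-nose rows are dropped.  Returns (complete, incomplete_reports);
    incompleteness is reported, never fatal.
    """
    buckets: dict[AssessmentKey, dict] = {}
    groups: dict[AssessmentKey, Group] = {}
    for e in manifest.entries:
        if e.task.excluded_from_pipeline:
            continue
        key = (e.patient_id, e.visit, e.hand)
        buckets.setdefault(key, {})[(e.task, e.trial, e.axis)] = e
        groups[key] = e.group

    expected = {
        (task, trial, axis)
        for task in INCLUDED_TASKS
        for trial in TRIALS
        for axis in AXES
    }
    complete: list[AssessmentIndex] = []
    incomplete: list[dict] = []
    for key in sorted(buckets, key=lambda k: (k[0], k[1], k[2].value)):
        entries = buckets[key]
        if set(entries.keys()) == expected:
            complete.append(
                AssessmentIndex(
                    patient_id=key[0],
                    group=groups[key],
                    visit=key[1],
                    hand=key[2],
                    entries=entries,
                )
            )
        else:
            missing = expected - set(entries.keys())
            incomplete.append(
                {
                    "key": key,
                    "n_present": len(entries),
                    "n_missing": len(missing),
                    "missing": sorted(
                        (t.value, trial, a.value) for (t, trial, a) in missing
                    ),
                }
            )
    return complete, incomplete


def load_assessment(index: AssessmentIndex, root: str | Path) -> TremorAssessment:
    signals = {
        key: read_signal(entry, root=root) for key, entry in index.entries.items()
    }
    return TremorAssessment(
        patient_id=index.patient_id,
        group=index.group,
        visit=index.visit,
        hand=index.hand,
        signals=signals,
    )


def assemble_assessments(
    manifest: CohortManifest,
) -> tuple[list[TremorAssessment], list[dict]]:
    """Read all complete assessments from disk; report incomplete ones."""
    complete, incomplete = index_assessments(manifest)
    return [load_assessment(ix, manifest.root) for ix in complete], incomplete
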