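"""Synthetic tremor cohort generator.

Emulates the statistical structure the classifier assumes: two diagnostic
classes with overlapping tremor bands, pseudo-rhythmic oscillation (reflected
random walk on instantaneous frequency) with a 2f harmonic, class-dependent
task-amplitude profiles across the 6 static tasks, slow postural drift, a
sensor noise floor, unilateral/bilateral patients, and optional second visits.

Noise is an absolute floor calibrated against a unit-amplitude tone, so tasks
with small amplitude have genuinely lower effective SNR -- this is what makes
the task-amplitude profile informative downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import (
    AXES,
    INCLUDED_TASKS,
    RECORDING_DURATION_S,
    TRIALS,
    Axis,
    CohortManifest,
    Group,
    Hand,
    ManifestEntry,
    TaskLabel,
    TremorSignal,
    write_manifest,
    write_signal,
)

__all__ = [
    "ClassProfile",
    "CohortSpec",
    "PatientEffects",
    "default_profiles",
    "simulate_signal",
    "simulate_cohort",
    "build_cohort_layout",
]


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one diagnostic class."""

    tremor_band: tuple  # (f_low, f_high) Hz
    freq_jitter_sd: float  # Hz per sqrt(s); random-walk scale, reflected at band edges
    harmonic_ratio: float  # relative amplitude of the 2f component
    task_amplitude: dict  # TaskLabel -> relative RMS amplitude
    axis_weights: tuple = (1.0, 0.7, 0.4)
    bilateral_prob: float = 1.0
    amplitude_cv: float = 0.2  # between-patient coefficient of variation

    def __post_init__(self) -> None:
        lo, hi = self.tremor_band
        if not lo < hi and not lo == hi:
            raise ValueError("tremor_band must satisfy f_low <= f_high")
        if any(a < 0 for a in self.task_amplitude.values()):
            raise ValueError("task amplitudes must be >= 0")
        if not 0.0 <= self.bilateral_prob <= 1.0:
            raise ValueError("bilateral_prob must be in [0, 1]")
        if any(w < 0 for w in self.axis_weights):
            raise ValueError("axis weights must be >= 0")


def default_profiles(separation: str = "paper_like") -> dict:
    """Return {PD, ET} class profiles.

    ``paper_like``: overlapping bands (PD 4-6 Hz rest-dominant and mostly
    unilateral; ET 4-8 Hz posture/load-dominant and always bilateral).
    ``easy``: disjoint bands and a strong task contrast, guaranteeing the
    pipeline has learnable signal for acceptance testing.
    """
    if separation == "paper_like":
        pd = ClassProfile(
            tremor_band=(4.0, 6.0),
            freq_jitter_sd=0.3,
            harmonic_ratio=0.3,
            task_amplitude={
                TaskLabel.REST1: 1.0,
                TaskLabel.REST2: 1.0,
                TaskLabel.POSTURE1: 0.4,
                TaskLabel.POSTURE2: 0.4,
                TaskLabel.LOAD1: 0.45,
                TaskLabel.LOAD2: 0.45,
                TaskLabel.FINGER_TO_NOSE: 0.4,
            },
            bilateral_prob=0.3,
            amplitude_cv=0.3,
        )
        et = ClassProfile(
            tremor_band=(4.0, 8.0),
            freq_jitter_sd=0.4,
            harmonic_ratio=0.2,
            task_amplitude={
                TaskLabel.REST1: 0.5,  # a fraction of ET patients tremble at rest
                TaskLabel.REST2: 0.5,
                TaskLabel.POSTURE1: 1.0,
                TaskLabel.POSTURE2: 1.0,
                TaskLabel.LOAD1: 0.9,
                TaskLabel.LOAD2: 0.9,
                TaskLabel.FINGER_TO_NOSE: 1.0,
            },
            bilateral_prob=1.0,
            amplitude_cv=0.3,
        )
    elif separation == "easy":
        # strong task contrast: rest tasks carry a loud tone, the other
        # tasks a weak one near the detection floor, so rest features are
        # reliably the informative ones without saturating the others
        pd = ClassProfile(
            tremor_band=(4.0, 5.5),
            freq_jitter_sd=0.1,
            harmonic_ratio=0.2,
            task_amplitude={
                TaskLabel.REST1: 1.0,
                TaskLabel.REST2: 1.0,
                TaskLabel.POSTURE1: 0.12,
                TaskLabel.POSTURE2: 0.12,
                TaskLabel.LOAD1: 0.12,
                TaskLabel.LOAD2: 0.12,
                TaskLabel.FINGER_TO_NOSE: 0.12,
            },
            bilateral_prob=0.0,
            amplitude_cv=0.1,
        )
        et = ClassProfile(
            tremor_band=(6.5, 8.0),
            freq_jitter_sd=0.1,
            harmonic_ratio=0.2,
            task_amplitude={
                TaskLabel.REST1: 0.8,
                TaskLabel.REST2: 0.8,
                TaskLabel.POSTURE1: 0.12,
                TaskLabel.POSTURE2: 0.12,
                TaskLabel.LOAD1: 0.12,
                TaskLabel.LOAD2: 0.12,
                TaskLabel.FINGER_TO_NOSE: 0.12,
            },
            bilateral_prob=0.0,
            amplitude_cv=0.1,
        )
    else:
        raise ValueError(f"unknown separation preset: {separation!r}")
    return {Group.PD: pd, Group.ET: et}


@dataclass(frozen=True)
class CohortSpec:
    n_pd: int = 8
    n_et: int = 8
    visits: int = 1
    raw_fs: float = 1500.0
    duration_s: float = RECORDING_DURATION_S
    snr_db: float = 20.0
    drift_amp: float = 0.05  # < 0.5 Hz postural drift amplitude
    seed: int = 0
    profiles: dict = field(default_factory=lambda: default_profiles("paper_like"))
    include_finger_to_nose: bool = False
    calibration_offset_sd: float = 0.3  # DC offset removed later by demeaning

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_et < 0:
            raise ValueError("patient counts must be >= 0")
        if self.visits not in (1, 2):
            raise ValueError("visits must be 1 or 2")


@dataclass(frozen=True)
class PatientEffects:
    """Per-patient latent draws shared by all of that patient's recordings."""

    base_freq: float
    amp_scale: float
    bilateral: bool
    affected_hand: Hand
    axis_weights: tuple


def _draw_patient_effects(
    profile: ClassProfile, rng: np.random.Generator
) -> PatientEffects:
    lo, hi = profile.tremor_band
    base = lo if lo == hi else rng.uniform(lo, hi)
    cv = profile.amplitude_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    amp = float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
    bilateral = bool(rng.random() < profile.bilateral_prob)
    affected = Hand.LEFT if rng.random() < 0.5 else Hand.RIGHT
    weights = np.asarray(profile.axis_weights, dtype=float)
    weights = np.clip(weights * (1.0 + 0.1 * rng.normal(size=3)), 0.0, None)
    return PatientEffects(
        base_freq=float(base),
        amp_scale=amp,
        bilateral=bilateral,
        affected_hand=affected,
        axis_weights=tuple(weights),
    )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the edges."""
    if hi <= lo:
        return np.full_like(x, lo)
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    return lo + np.where(y > width, 2.0 * width - y, y)


def simulate_signal(
    profile: ClassProfile,
    task: TaskLabel,
    effects: PatientEffects,
    rng: np.random.Generator,
    axis: Axis = Axis.X,
    fs: float = 1500.0,
    duration_s: float = RECORDING_DURATION_S,
    snr_db: float = 20.0,
    drift_amp: float = 0.05,
    amplitude_gain: float = 1.0,
    calibration_offset_sd: float = 0.0,
) -> np.ndarray:
    """One raw single-axis recording (samples only; metadata lives elsewhere).

    samples = A * [sin(phi) + h * sin(2 phi)] + drift + noise (+ DC offset)
    with dphi/dt = 2 pi f(t), f(t) a reflected random walk in the tremor band.
    """
    n = round(duration_s * fs)
    dt = 1.0 / fs
    lo, hi = profile.tremor_band

    if profile.freq_jitter_sd > 0 and hi > lo:
        steps = rng.normal(0.0, profile.freq_jitter_sd * np.sqrt(dt), size=n)
        freq = _reflect(effects.base_freq + np.cumsum(steps), lo, hi)
    else:
        freq = np.full(n, effects.base_freq)

    phase = 2.0 * np.pi * np.cumsum(freq) * dt + rng.uniform(0.0, 2.0 * np.pi)
    tone = np.sin(phase) + profile.harmonic_ratio * np.sin(2.0 * phase)

    amp = (
        profile.task_amplitude[task]
        * effects.amp_scale
        * effects.axis_weights[axis.index]
        * amplitude_gain
    )
    out = amp * tone

    if drift_amp > 0:
        f_drift = rng.uniform(0.05, 0.45)
        out = out + drift_amp * np.sin(
            2.0 * np.pi * f_drift * np.arange(n) * dt + rng.uniform(0, 2 * np.pi)
        )

    # noise floor calibrated to a unit-amplitude tone (RMS 1/sqrt(2))
    if np.isfinite(snr_db):
        sigma = (1.0 / np.sqrt(2.0)) * 10.0 ** (-snr_db / 20.0)
        out = out + rng.normal(0.0, sigma, size=n)

    if calibration_offset_sd > 0:
        out = out + rng.normal(0.0, calibration_offset_sd)

    return out


def _iter_cohort(spec: CohortSpec):
    """Yield (entry_meta, seed_tuple) for every recording in the cohort.

    Deterministic: each recording's RNG seed is derived from the cohort seed
    and the recording's coordinates, independent of iteration order.
    """
    patients = [(Group.PD, i) for i in range(spec.n_pd)] + [
        (Group.ET, i) for i in range(spec.n_et)
    ]
    tasks = list(INCLUDED_TASKS) + (
        [TaskLabel.FINGER_TO_NOSE] if spec.include_finger_to_nose else []
    )
    for group, idx in patients:
        pid = f"{group.value}{idx + 1:03d}"
        profile = spec.profiles[group]
        eff_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0 if group is Group.PD else 1, idx])
        )
        effects = _draw_patient_effects(profile, eff_rng)
        hands = (
            [Hand.LEFT, Hand.RIGHT] if effects.bilateral else [effects.affected_hand]
        )
        for visit in range(1, spec.visits + 1):
            v_effects = effects
            if visit > 1:
                # redraw small perturbations of the same patient effects
                pr = np.random.default_rng(
                    np.random.SeedSequence(
                        [spec.seed, 0 if group is Group.PD else 1, idx, 7 + visit]
                    )
                )
                lo, hi = profile.tremor_band
                v_effects = replace(
                    effects,
                    base_freq=float(
                        _reflect(
                            np.array([effects.base_freq + pr.normal(0.0, 0.1)]), lo, hi
                        )[0]
                    ),
                    amp_scale=effects.amp_scale * float(np.exp(pr.normal(0.0, 0.05))),
                )
            for hand in hands:
                for task in tasks:
                    # asymmetry: a bilateral patient's less-affected hand is
                    # attenuated (mildly for ET, strongly for PD phenotype)
                    hand_gain = 1.0
                    if effects.bilateral and hand != effects.affected_hand:
                        hand_gain = 0.5 if group is Group.PD else 0.85
                    for trial in TRIALS:
                        for axis in AXES:
                            seed_tuple = (
                                spec.seed,
                                0 if group is Group.PD else 1,
                                idx,
                                visit,
                                0 if hand is Hand.LEFT else 1,
                                list(TaskLabel).index(task),
                                trial,
                                axis.index,
                            )
                            yield (
                                {
                                    "patient_id": pid,
                                    "group": group,
                                    "visit": visit,
                                    "hand": hand,
                                    "task": task,
                                    "trial": trial,
                                    "axis": axis,
                                    "profile": profile,
                                    "effects": v_effects,
                                    "hand_gain": hand_gain,
                                },
                                seed_tuple,
                            )


def _entry_filename(meta: dict) -> str:
    return (
        f"signals/{meta['patient_id']}_v{meta['visit']}_{meta['hand'].value}_"
        f"{meta['task'].value}_t{meta['trial']}_{meta['axis'].value}.txt"
    )


def build_cohort_layout(spec: CohortSpec) -> CohortManifest:
    """Manifest entries for the cohort without generating/writing any samples.

    Useful for bookkeeping (counts, splits); files referenced do not exist
    until :func:`simulate_cohort` writes them.
    """
    entries = [
        ManifestEntry(
            patient_id=meta["patient_id"],
            group=meta["group"],
            visit=meta["visit"],
            hand=meta["hand"],
            task=meta["task"],
            trial=meta["trial"],
            axis=meta["axis"],
            fs=spec.raw_fs,
            file_path=_entry_filename(meta),
        )
        for meta, _ in _iter_cohort(spec)
    ]
    return CohortManifest(entries=entries, provenance=f"synthetic seed={spec.seed}")


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Generate the cohort, write signal files + manifest, return the manifest.

    Fully deterministic given ``spec.seed``: re-running with the same spec
    produces byte-identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "signals").mkdir(parents=True, exist_ok=True)
    entries = []
    for meta, seed_tuple in _iter_cohort(spec):
        rng = np.random.default_rng(np.random.SeedSequence(list(seed_tuple)))
        samples = simulate_signal(
            meta["profile"],
            meta["task"],
            meta["effects"],
            rng,
            axis=meta["axis"],
            fs=spec.raw_fs,
            duration_s=spec.duration_s,
            snr_db=spec.snr_db,
            drift_amp=spec.drift_amp,
            amplitude_gain=meta["hand_gain"],
            calibration_offset_sd=spec.calibration_offset_sd,
        )
        rel = _entry_filename(meta)
        write_signal(samples, out_dir / rel)
        entries.append(
            ManifestEntry(
                patient_id=meta["patient_id"],
                group=meta["group"],
                visit=meta["visit"],
                hand=meta["hand"],
                task=meta["task"],
                trial=meta["trial"],
                axis=meta["axis"],
                fs=spec.raw_fs,
                file_path=rel,
            )
        )
    manifest = CohortManifest(
        entries=entries, root=out_dir, provenance=f"synthetic seed={spec.seed}"
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
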