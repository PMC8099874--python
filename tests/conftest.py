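import numpy as np
import pytest

from tremordx.data import (
    Axis,
    Group,
    Hand,
    TaskLabel,
    TremorSignal,
    assemble_assessments,
    load_manifest,
)
from tremordx.nn import ConvSpec
from tremordx.stage1 import CnnConfig, build_signal_dataset, train_stage1
from tremordx.synthetic import CohortSpec, default_profiles, simulate_cohort


def make_signal(
    samples,
    fs=100.0,
    patient_id="P1",
    group=Group.PD,
    visit=1,
    hand=Hand.LEFT,
    task=TaskLabel.REST1,
    trial=1,
    axis=Axis.X,
):
    return TremorSignal(
        samples=np.asarray(samples, dtype=float),
        fs=fs,
        patient_id=patient_id,
        group=group,
        visit=visit,
        hand=hand,
        task=task,
        trial=trial,
        axis=axis,
    )


def tone_signal(freq_hz, fs=100.0, duration_s=20.0, amplitude=1.0, **kwargs):
    t = np.arange(round(duration_s * fs)) / fs
    return make_signal(amplitude * np.sin(2 * np.pi * freq_hz * t), fs=fs, **kwargs)


@pytest.fixture(scope="session")
def tiny_cnn():
    """Smallest trainable architecture; for mechanics tests, not accuracy."""
    return CnnConfig(
        conv_specs=(ConvSpec(2, 5, 4, 2), ConvSpec(3, 3, 1, 2)),
        dense_widths=(16, 8, 2),
        learning_rate=1e-3,
        epochs=2,
        batch_size=32,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cnn():
    """Small but capable architecture used for accuracy-bearing tests."""
    return CnnConfig(
        conv_specs=(ConvSpec(4, 5, 2, 2), ConvSpec(8, 3, 1, 2)),
        dense_widths=(64, 32, 2),
        learning_rate=1e-3,
        epochs=8,
        batch_size=32,
        seed=0,
    )


@pytest.fixture(scope="session")
def easy_cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("easy_cohort")
    spec = CohortSpec(
        n_pd=3,
        n_et=3,
        raw_fs=100.0,
        seed=5,
        snr_db=10.0,
        profiles=default_profiles("easy"),
    )
    simulate_cohort(spec, out)
    return out


@pytest.fixture(scope="session")
def easy_manifest(easy_cohort_dir):
    return load_manifest(easy_cohort_dir / "manifest.csv")


@pytest.fixture(scope="session")
def easy_assessments(easy_manifest):
    assessments, incomplete = assemble_assessments(easy_manifest)
    assert not incomplete
    return assessments


@pytest.fixture(scope="session")
def easy_dataset(easy_assessments):
    return build_signal_dataset(easy_assessments)


@pytest.fixture(scope="session")
def trained_tiny_model(easy_dataset, tiny_cnn):
    from dataclasses import replace

    return train_stage1(easy_dataset, replace(tiny_cnn, epochs=3))


# -- acceptance-scale artifacts (shared so training happens once) -----------

ACCEPTANCE_CNN = CnnConfig(
    conv_specs=(ConvSpec(4, 5, 2, 2), ConvSpec(8, 3, 1, 2)),
    dense_widths=(64, 32, 2),
    learning_rate=1e-3,
    epochs=8,  # <= 10 per the desk-scale budget
    batch_size=32,
    seed=0,
)


def _easy_cohort(tmp_path_factory, n_per_class, seed):
    out = tmp_path_factory.mktemp(f"easy_{n_per_class}_{seed}")
    spec = CohortSpec(
        n_pd=n_per_class,
        n_et=n_per_class,
        raw_fs=100.0,
        seed=seed,
        snr_db=10.0,
        profiles=default_profiles("easy"),
    )
    simulate_cohort(spec, out)
    assessments, incomplete = assemble_assessments(load_manifest(out / "manifest.csv"))
    assert not incomplete
    return assessments


@pytest.fixture(scope="session")
def acceptance_cohort(tmp_path_factory):
    return _easy_cohort(tmp_path_factory, n_per_class=8, seed=11)


@pytest.fixture(scope="session")
def acceptance_dataset(acceptance_cohort):
    from tremordx.config import PipelineConfig
    from tremordx.pipeline import prepare_dataset

    return prepare_dataset(acceptance_cohort, PipelineConfig(cnn=ACCEPTANCE_CNN))


@pytest.fixture(scope="session")
def acceptance_pipeline(acceptance_dataset):
    from tremordx.config import PipelineConfig
    from tremordx.pipeline import train_pipeline

    config = PipelineConfig(cnn=ACCEPTANCE_CNN, seed=1)
    return train_pipeline(acceptance_dataset, config, seed=7)


@pytest.fixture(scope="session")
def holdout_dataset(tmp_path_factory):
    """Same distribution as the acceptance cohort, disjoint seed: features
    computed on it are genuinely out-of-sample for the trained pipeline."""
    from tremordx.config import PipelineConfig
    from tremordx.pipeline import prepare_dataset

    assessments = _easy_cohort(tmp_path_factory, n_per_class=12, seed=12)
    return prepare_dataset(assessments, PipelineConfig(cnn=ACCEPTANCE_CNN))
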