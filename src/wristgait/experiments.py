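"""Canned experiment configurations for the evaluation studies.

A full-scale study of this kind (18 subjects, two wrists, five regular and
five impaired walks each, GPU-trained networks) is too large for a
laptop-scale CPU run, so the stock experiments here use a reduced cohort
while keeping every other element of the design: both wrists, 5+5 trials per subject,
the full preprocessing chain, the default network hyperparameters and
training recipe, and leave-one-subject-out evaluation.  Cohort sizes and
epoch counts are the package's standard desk-scale choices; they can be
raised freely through the same dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic_gait import GaitSimConfig
from .preprocessing import PreprocessConfig
from .models import ArchitectureConfig, TrainingConfig


@dataclass(frozen=True)
class StudyConfig:
    """One end-to-end LOSO study: cohort + preprocessing + model + training."""

    sim: GaitSimConfig
    pre: PreprocessConfig
    arch: ArchitectureConfig
    train: TrainingConfig
    sensors: str = "AGR"


def accuracy_study(seed: int) -> StudyConfig:
    """Single-seed LOSO benchmark of the feature-fusion network.

    5 subjects x 2 wrists x (5+5) trials of 16-20 s walks; training uses
    the standard recipe (Adam 0.001, batch 256, early stopping) with the
    epoch cap reduced to 6 for CPU-scale turnaround.
    """
    return StudyConfig(
        sim=GaitSimConfig(n_subjects=5, trials_per_condition=5,
                          duration_range=(16.0, 20.0), rng_seed=seed),
        pre=PreprocessConfig(),
        arch=ArchitectureConfig(sensors="AGR"),
        train=TrainingConfig(max_epochs=6, patience=3, seed=seed),
    )


def ablation_study(seed: int) -> StudyConfig:
    """Architecture-comparison runs (proposed vs CNN-only vs BiLSTM-only).

    A leaner 4-subject cohort, repeated over seeds: the comparison is
    relative, so per-run cost matters more than per-run precision.  Training
    runs a fixed number of epochs with no early stopping — at this cohort
    size a held-out validation split is a handful of windows and restoring
    the "best" epoch measured on it is noise, which penalizes the
    slower-converging fusion model unevenly.
    """
    return StudyConfig(
        sim=GaitSimConfig(n_subjects=4, trials_per_condition=5,
                          duration_range=(16.0, 18.0), rng_seed=seed),
        pre=PreprocessConfig(),
        arch=ArchitectureConfig(sensors="AGR"),
        train=TrainingConfig(max_epochs=6, early_stopping=False, seed=seed),
    )
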