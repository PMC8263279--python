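"""End-to-end study runner.

Reproduces the study layout: per subject, the first two sessions train a
subject-specific classifier for each binary problem (left vs right execution;
left vs right imagery) and the last session is the held-out test set. Channel
scalers and hidden-size selection only ever see training sessions. The
imagery models are additionally scored on every other subject's held-out
session, yielding the cross-subject transfer matrix.

Runs are reproducible: all randomness derives from ``RunConfig.seed``, and
``run_pipeline`` serializes the exact configuration next to its result
tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dbn, evaluation, preprocessing, simulate
from .dbn import ArchGrid, DbnModel, FineTuneConfig, TrainingHistory
from .preprocessing import BandpassSpec, SampleMatrix
from .rbm import CdConfig
from .simulate import (
    EXECUTION_TASKS,
    IMAGERY_TASKS,
    HrfParams,
    NoiseComponent,
    NoiseSpec,
    SimulationConfig,
)

__all__ = ["RunConfig", "SubjectResult", "StudyResult", "run_study", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Merged configuration for a full run.

    ``fixed_arch`` skips the cross-validated grid search and trains every
    subject at the given (h1, h2); with ``fixed_arch=None`` the grid is
    searched per subject and paradigm.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    cd: CdConfig = field(default_factory=CdConfig)
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    grid: ArchGrid = field(default_factory=ArchGrid)
    fixed_arch: tuple[int, int] | None = (10, 10)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = dict(d["simulation"])
        sim["task_set"] = tuple(sim["task_set"])
        sim["hrf_params"] = HrfParams(**sim["hrf_params"])
        noise = sim["noise_spec"]
        sim["noise_spec"] = NoiseSpec(
            components=tuple(NoiseComponent(**c) for c in noise["components"]),
            white_sigma=noise["white_sigma"],
        )
        grid = dict(d["grid"])
        grid["candidates"] = tuple(grid["candidates"])
        fixed = d["fixed_arch"]
        return cls(
            simulation=SimulationConfig(**sim),
            bandpass=BandpassSpec(**d["bandpass"]),
            cd=CdConfig(**d["cd"]),
            finetune=FineTuneConfig(**d["finetune"]),
            grid=ArchGrid(**grid),
            fixed_arch=None if fixed is None else tuple(fixed),
            seed=d["seed"],
        )


@dataclass
class SubjectResult:
    subject_id: str
    reports: dict[str, evaluation.AccuracyReport]  # paradigm -> report
    models: dict[str, DbnModel]
    histories: dict[str, TrainingHistory]
    test_sets: dict[str, SampleMatrix]


@dataclass
class StudyResult:
    config: RunConfig
    subjects: list[SubjectResult]
    transfer: evaluation.TransferMatrix

    def accuracy_table(self, paradigm: str) -> pd.DataFrame:
        rows = [
            {
                "subject": s.subject_id,
                "sample_accuracy": s.reports[paradigm].sample_accuracy,
                "trial_accuracy": s.reports[paradigm].trial_accuracy,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


_PARADIGMS = {"execution": EXECUTION_TASKS, "imagery": IMAGERY_TASKS}


def _prepare_subject(
    profile, sessions, config: RunConfig
) -> tuple[dict[str, SampleMatrix], dict[str, SampleMatrix]]:
    """Filter, epoch, normalize and assemble train/test matrices per paradigm.

    The scaler is fitted on training sessions only; the test session is the
    last one. Test data never influences any fitted statistic.
    """
    filtered = [
        preprocessing.filter_recording(rec, config.bandpass) for rec in sessions
    ]
    epoch_sets = [
        preprocessing.extract_epochs(rec, config.simulation.task_s)
        for rec in filtered
    ]
    train_sets, test_set = epoch_sets[:-1], epoch_sets[-1]
    scaler = preprocessing.fit_scaler(train_sets)
    norm_train = [preprocessing.apply_scaler(scaler, e) for e in train_sets]
    norm_test = preprocessing.apply_scaler(scaler, test_set)
    train, test = {}, {}
    for name, pair in _PARADIGMS.items():
        train[name] = preprocessing.assemble_samples(norm_train, pair)
        test[name] = preprocessing.assemble_samples(norm_test, pair)
    return train, test


def _train_one(
    x: np.ndarray,
    y: np.ndarray,
    trial_index: np.ndarray,
    config: RunConfig,
    seed: int,
) -> tuple[DbnModel, TrainingHistory]:
    cd = dataclasses.replace(config.cd, seed=seed)
    ft = dataclasses.replace(config.finetune, seed=seed + 1)
    if config.fixed_arch is not None:
        h1, h2 = config.fixed_arch
        model, history = dbn._fit_once(x, y, h1, h2, cd, ft)
        return model, history
    return dbn.train_full(x, y, trial_index, config.grid, cd, ft)


def run_study(config: RunConfig) -> StudyResult:
    """Simulate, preprocess, train and score every subject; build the
    imagery transfer matrix."""
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    study = simulate.simulate_study(sim)
    subjects: list[SubjectResult] = []
    for idx, (profile, sessions) in enumerate(study):
        train, test = _prepare_subject(profile, sessions, config)
        reports, models, histories, tests = {}, {}, {}, {}
        for p_idx, (name, _) in enumerate(_PARADIGMS.items()):
            tr = train[name]
            seed = (config.seed * 1009 + idx * 11 + p_idx * 3) % (2**31 - 1)
            model, history = _train_one(
                tr.x, tr.y, tr.trial_index, config, seed
            )
            reports[name] = evaluation.score(model, test[name])
            models[name] = model
            histories[name] = history
            tests[name] = test[name]
        subjects.append(
            SubjectResult(
                subject_id=profile.subject_id,
                reports=reports,
                models=models,
                histories=histories,
                test_sets=tests,
            )
        )
    transfer = evaluation.transfer_evaluate(
        {s.subject_id: s.models["imagery"] for s in subjects},
        {s.subject_id: s.test_sets["imagery"] for s in subjects},
    )
    return StudyResult(config=config, subjects=subjects, transfer=transfer)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the full study and write result tables (2 d.p.) plus the exact
    configuration used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_study(config)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    for paradigm in _PARADIGMS:
        table = result.accuracy_table(paradigm)
        table.to_csv(
            outdir / f"accuracy_{paradigm}.csv", index=False, float_format="%.2f"
        )
    result.transfer.to_frame().to_csv(
        outdir / "transfer_imagery.csv", float_format="%.2f"
    )
    return outdir
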