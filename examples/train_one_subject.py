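"""Train and score a subject-specific imagery classifier.

Simulates three sessions for one subject, trains a 16-10-10-2 deep belief
network on the left/right motor-imagery pair of the first two sessions, and
scores the held-out third session at sample and trial level.
"""

import numpy as np

from fnirsdbn.dbn import FineTuneConfig, _fit_once
from fnirsdbn.evaluation import score
from fnirsdbn.pipeline import RunConfig, _prepare_subject
from fnirsdbn.rbm import CdConfig
from fnirsdbn.simulate import SimulationConfig, simulate_study

config = RunConfig(
    simulation=SimulationConfig(n_subjects=1, trials_per_task_per_session=10),
    seed=7,
)
profile, sessions = simulate_study(config.simulation)[0]
train, test = _prepare_subject(profile, sessions, config)

tr, te = train["imagery"], test["imagery"]
print(f"training matrix {tr.x.shape}, test matrix {te.x.shape} "
      "(rows are single 16-channel time points in [0,1])")

model, history = _fit_once(
    tr.x, tr.y, 10, 10, CdConfig(seed=1), FineTuneConfig(seed=2)
)
print(f"pretraining reconstruction errors (final epoch): "
      f"RBM1 {history.pretrain_errors[0][-1]:.4f}, "
      f"RBM2 {history.pretrain_errors[1][-1]:.4f}")
print(f"fine-tuning loss: {history.finetune_loss[0]:.4f} -> "
      f"{history.finetune_loss[-1]:.4f}")

report = score(model, te)
print(f"\nheld-out session: sample accuracy {report.sample_accuracy:.2f}% "
      f"({report.n_samples} samples), trial accuracy "
      f"{report.trial_accuracy:.2f}% ({report.n_trials} trials)")
print("Sample accuracy scores every 50 ms time point independently; trial "
      "accuracy majority-votes the 160 points of each trial.")
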