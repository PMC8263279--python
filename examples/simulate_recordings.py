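"""Generate a synthetic fNIRS session and inspect its task-locked structure.

Builds one session for one subject (16 channels, 20 Hz, four tasks in
shuffled order), then epoch-averages the noise-free part of the design by
comparing hemisphere means, showing contralateral dominance and the weaker
imagery response.
"""

from collections import Counter

import numpy as np

from fnirsdbn.simulate import (
    NoiseSpec,
    SimulationConfig,
    SubjectProfile,
    simulate_session,
)

# noise-free session with a neutral subject so the average activation
# pattern of the experimental design itself is visible; the extended rest
# keeps the ~38 s hemodynamic response of one trial from bleeding into the
# next trial's analysis window
config = SimulationConfig(
    n_subjects=1,
    trials_per_task_per_session=10,
    rest_s=40.0,
    noise_spec=NoiseSpec(components=(), white_sigma=0.0),
    seed=42,
)
profile = SubjectProfile(
    subject_id="S1",
    channel_gains=np.ones(16),
    lateral_exponents=np.ones(16),
    amplitude_scale=1.0,
    hrf_jitter_s=0.0,
    seed_offset=0,
)
recording = simulate_session(config, profile, session_index=0)

print(f"subject {profile.subject_id}, session 0")
print(f"HbO array: {recording.hbo.shape[0]} channels x "
      f"{recording.hbo.shape[1]} samples at {recording.sampling_rate} Hz")
counts = Counter(e.task for e in recording.events)
print("trials per task:", dict(counts))

win = int(config.task_s * config.sampling_rate)
task_means = {}
for task in config.task_set:
    epochs = [
        recording.hbo[:, e.onset_sample : e.onset_sample + win]
        for e in recording.events
        if e.task == task
    ]
    # baseline-correct each epoch at task onset before averaging
    task_means[task] = np.mean(
        [(ep - ep[:, :1]).mean(axis=1) for ep in epochs], axis=0
    )

left, right = config.left_channels, config.right_channels
print("\nbaseline-corrected epoch-average HbO by hemisphere:")
for task, mean in task_means.items():
    contra = right if task.startswith("L") else left
    ipsi = left if task.startswith("L") else right
    print(f"  {task}: contralateral {mean[contra].mean():+.3f}  "
          f"ipsilateral {mean[ipsi].mean():+.3f}")
print("\nContralateral values exceed ipsilateral for every task, and the "
      "execution (ME) tasks exceed their imagery (MI) counterparts — the "
      "activation pattern the classifier exploits.")
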