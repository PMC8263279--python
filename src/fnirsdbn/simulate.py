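"""Trial-structured synthetic fNIRS recordings.

Emulates a left/right arm flexion-extension study: four tasks (motor
execution and motor imagery of each arm), 16 channels at 20 Hz split into a
left and a right hemisphere group, a canonical double-gamma hemodynamic
response convolved with the 8 s task boxcar, contralateral-dominant HbO
amplitude, weaker responses for imagery than execution, and additive
physiological noise (cardiac, respiratory, Mayer waves, white noise).

The generator is fully deterministic given the configuration seed: subject
profiles are pure functions of ``(seed, subject_id)`` and every session draws
from a seed sequence derived from ``(seed, subject, session)``, split by
purpose (trial order, oscillation phases, white noise) so that changing the
channel count never reorders trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "HrfParams",
    "NoiseComponent",
    "NoiseSpec",
    "SimulationConfig",
    "SubjectProfile",
    "TrialEvent",
    "SessionRecording",
    "TASK_SET",
    "EXECUTION_TASKS",
    "IMAGERY_TASKS",
    "hemodynamic_kernel",
    "trial_response",
    "physiological_noise",
    "simulate_session",
    "simulate_study",
]

#: Canonical task labels: left/right arm flexion-extension, motor execution
#: (ME) and motor imagery (MI).
TASK_SET = ("L-FE_ME", "R-FE_ME", "L-FE_MI", "R-FE_MI")
EXECUTION_TASKS = ("L-FE_ME", "R-FE_ME")
IMAGERY_TASKS = ("L-FE_MI", "R-FE_MI")


class ConfigurationError(ValueError):
    """Raised for invalid simulation or filter configuration."""


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic impulse response parameters.

    ``peak_delay_s`` and ``undershoot_delay_s`` are the modes (seconds) of the
    positive lobe and of the late undershoot; ``undershoot_ratio`` scales the
    undershoot relative to the main lobe. Dispersions set each gamma's width.
    The defaults place the peak of the 8 s boxcar-convolved response near
    18 s after task onset, matching the slow arm-movement HbO response.
    """

    peak_delay_s: float = 14.0
    undershoot_delay_s: float = 26.0
    undershoot_ratio: float = 0.1
    peak_disp_s: float = 2.6
    undershoot_disp_s: float = 2.6


@dataclass(frozen=True)
class NoiseComponent:
    frequency_hz: float
    amplitude: float


@dataclass(frozen=True)
class NoiseSpec:
    """Sinusoidal physiological components plus white noise.

    Defaults model cardiac (~1.1 Hz), respiratory (~0.25 Hz) and Mayer-wave
    (~0.1 Hz) oscillations plus a broadband sensor-noise floor; amplitudes
    are in units of a single trial's noise-free response peak. Only the
    Mayer component and the in-band share of the white noise survive the
    0.01-0.2 Hz analysis band-pass.
    """

    components: tuple[NoiseComponent, ...] = (
        NoiseComponent(1.1, 0.10),
        NoiseComponent(0.25, 0.10),
        NoiseComponent(0.10, 0.07),
    )
    white_sigma: float = 0.50


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters (defaults follow the acquisition
    protocol: 3 sessions, 30 trials per task per session, 16 channels, 20 Hz,
    2 s cue + 8 s task + 17 s rest + 1 s test cue per trial)."""

    n_subjects: int = 10
    n_sessions: int = 3
    trials_per_task_per_session: int = 30
    task_set: tuple[str, ...] = TASK_SET
    sampling_rate: float = 20.0
    cue_s: float = 2.0
    task_s: float = 8.0
    rest_s: float = 17.0
    test_cue_s: float = 1.0
    n_channels: int = 16
    exec_amplitude: float = 1.0
    imagery_amplitude_ratio: float = 0.6
    contralateral_ratio: float = 1.5
    hbr_ratio: float = -0.3
    hrf_params: HrfParams = field(default_factory=HrfParams)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not 0 < self.imagery_amplitude_ratio < 1:
            raise ConfigurationError("imagery_amplitude_ratio must lie in (0,1)")
        if self.contralateral_ratio <= 1:
            raise ConfigurationError("contralateral_ratio must exceed 1")
        nyq = self.sampling_rate / 2
        for comp in self.noise_spec.components:
            if comp.frequency_hz >= nyq:
                raise ConfigurationError(
                    f"noise component at {comp.frequency_hz} Hz is at/above "
                    f"Nyquist ({nyq} Hz)"
                )

    @property
    def trial_period_s(self) -> float:
        return self.cue_s + self.task_s + self.rest_s + self.test_cue_s

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_period_s * self.sampling_rate))

    @property
    def left_channels(self) -> np.ndarray:
        """Left-hemisphere channel indices (first half by default)."""
        return np.arange(self.n_channels // 2)

    @property
    def right_channels(self) -> np.ndarray:
        return np.arange(self.n_channels // 2, self.n_channels)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject idiosyncrasy: channel gains, a per-channel lateralization
    topography, global amplitude and HRF timing jitter. Deterministic
    function of (config.seed, subject_id).

    ``lateral_exponents`` raises the configured contralateral ratio to a
    per-channel power, so which channels carry the left/right contrast — and
    in which direction — differs between subjects: most channels are
    contralateral-dominant (positive exponents), a minority reversed
    (negative exponents), emulating individual motor-cortex topography. This
    is what makes subject-specific classifiers genuinely subject-specific.
    """

    subject_id: str
    channel_gains: np.ndarray
    lateral_exponents: np.ndarray
    amplitude_scale: float
    hrf_jitter_s: float
    seed_offset: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.channel_gains) <= 0):
            raise ConfigurationError("channel_gains must be positive")
        if np.any(np.asarray(self.lateral_exponents) == 0):
            raise ConfigurationError("lateral_exponents must be nonzero")


@dataclass(frozen=True)
class TrialEvent:
    onset_sample: int  # 0-based sample of task onset
    task: str


@dataclass
class SessionRecording:
    hbo: np.ndarray  # (n_channels, T)
    hbr: np.ndarray  # (n_channels, T)
    sampling_rate: float
    events: list[TrialEvent]
    subject_id: str
    session_index: int


def hemodynamic_kernel(
    hrf_params: HrfParams, sampling_rate: float, duration_s: float = 30.0
) -> np.ndarray:
    """Unit-peak double-gamma hemodynamic impulse response.

    Each lobe is a gamma density with its mode at the requested delay; the
    kernel is zero at t=0 and normalized to unit peak.
    """
    if sampling_rate <= 0 or duration_s <= 0:
        raise ConfigurationError("sampling_rate and duration_s must be positive")
    if duration_s < 30:
        raise ConfigurationError("duration_s must cover the response (>= 30 s)")
    t = np.arange(int(round(duration_s * sampling_rate))) / sampling_rate
    p = hrf_params

    def lobe(mode: float, disp: float) -> np.ndarray:
        # gamma with scale=disp and mode=(shape-1)*scale at the requested delay
        shape = mode / disp + 1.0
        return stats.gamma.pdf(t, a=shape, scale=disp)

    kernel = lobe(p.peak_delay_s, p.peak_disp_s)
    if p.undershoot_ratio:
        under = lobe(p.undershoot_delay_s, p.undershoot_disp_s)
        kernel = kernel - p.undershoot_ratio * under / under.max() * kernel.max()
    return kernel / kernel.max()


def _task_arm(task: str) -> str:
    if task not in TASK_SET:
        raise ValueError(f"unknown task label {task!r}")
    return "L" if task.startswith("L") else "R"


def _is_imagery(task: str) -> bool:
    return task.endswith("MI")


def trial_amplitude(
    task: str, channel: int, profile: SubjectProfile, config: SimulationConfig
) -> float:
    """Peak HbO scale for one (task, channel): execution amplitude, imagery
    attenuation, contralateral dominance and subject channel gain."""
    arm = _task_arm(task)
    if not 0 <= channel < config.n_channels:
        raise ValueError(f"channel {channel} outside [0, {config.n_channels})")
    amp = config.exec_amplitude * profile.amplitude_scale
    if _is_imagery(task):
        amp *= config.imagery_amplitude_ratio
    hemisphere = "L" if channel in config.left_channels else "R"
    if hemisphere != arm:  # contralateral channel
        amp *= config.contralateral_ratio ** float(
            profile.lateral_exponents[channel]
        )
    return amp * float(profile.channel_gains[channel])


def _subject_kernel(profile: SubjectProfile, config: SimulationConfig) -> np.ndarray:
    hrf = replace(
        config.hrf_params,
        peak_delay_s=config.hrf_params.peak_delay_s + profile.hrf_jitter_s,
    )
    return hemodynamic_kernel(hrf, config.sampling_rate)


def _response_kernel(
    profile: SubjectProfile, config: SimulationConfig
) -> np.ndarray:
    """Subject kernel rescaled so the boxcar-convolved single-trial response
    has unit peak: trial amplitudes are then true HbO peak scales, on the
    same scale as the noise amplitudes."""
    kernel = _subject_kernel(profile, config)
    boxcar = np.ones(int(round(config.task_s * config.sampling_rate)))
    return kernel / np.convolve(boxcar, kernel).max()


def trial_response(
    task: str, channel: int, profile: SubjectProfile, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (hbo, hbr) response of one trial on one channel, starting at
    task onset: an 8 s boxcar convolved with the subject's hemodynamic kernel,
    peak-normalized and scaled by :func:`trial_amplitude`. HbR is a scaled
    negative copy."""
    amp = trial_amplitude(task, channel, profile, config)
    kernel = _response_kernel(profile, config)
    boxcar = np.ones(int(round(config.task_s * config.sampling_rate)))
    hbo = amp * np.convolve(boxcar, kernel)
    return hbo, config.hbr_ratio * hbo


def physiological_noise(
    n_samples: int,
    sampling_rate: float,
    noise_spec: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of fixed-frequency sinusoids with uniform random phases plus white
    Gaussian noise; zero mean in expectation."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    nyq = sampling_rate / 2
    t = np.arange(n_samples) / sampling_rate
    out = np.zeros(n_samples)
    for comp in noise_spec.components:
        if comp.frequency_hz >= nyq:
            raise ConfigurationError(
                f"noise frequency {comp.frequency_hz} Hz at/above Nyquist"
            )
        phase = rng.uniform(0, 2 * np.pi)
        out += comp.amplitude * np.sin(2 * np.pi * comp.frequency_hz * t + phase)
    if noise_spec.white_sigma:
        out += noise_spec.white_sigma * rng.standard_normal(n_samples)
    return out


def subject_profile(config: SimulationConfig, subject_index: int) -> SubjectProfile:
    """Deterministic profile for one subject under the configuration seed."""
    ss = np.random.SeedSequence([config.seed, 0x5EED, subject_index])
    rng = np.random.default_rng(ss)
    gains = np.exp(rng.normal(0.0, 0.15, size=config.n_channels))
    # per-channel lateralization class: strongly contralateral hot spots,
    # weakly lateralized channels, and a minority with reversed dominance;
    # proportions keep every subject classifiable while making the spatial
    # pattern subject-specific
    n = config.n_channels
    classes = rng.choice(3, size=n, p=(0.45, 0.10, 0.45))
    lateral = np.where(
        classes == 0,
        rng.normal(1.8, 0.3, n),
        np.where(
            classes == 1, rng.normal(0.3, 0.2, n), rng.normal(-1.2, 0.3, n)
        ),
    )
    lateral[lateral == 0] = 0.05
    amplitude_scale = float(np.exp(rng.normal(0.0, 0.05)))
    # equalize total left/right contrast energy across subjects: subjects
    # differ in WHERE the contrast lives, not in how much of it there is
    ratio = config.contralateral_ratio
    contrast = amplitude_scale * gains * (ratio**lateral - 1.0)
    target = (ratio - 1.0) * 2.0 * np.sqrt(n)
    contrast *= target / np.linalg.norm(contrast)
    scaled = np.maximum(contrast / (amplitude_scale * gains), -0.9)
    lateral = np.log1p(scaled) / np.log(ratio)
    lateral[lateral == 0] = 0.05
    hrf_jitter = float(rng.uniform(-0.15, 0.15))
    return SubjectProfile(
        subject_id=f"S{subject_index + 1}",
        channel_gains=gains,
        lateral_exponents=lateral,
        amplitude_scale=amplitude_scale,
        hrf_jitter_s=hrf_jitter,
        seed_offset=subject_index,
    )


def simulate_session(
    config: SimulationConfig,
    profile: SubjectProfile,
    session_index: int,
) -> SessionRecording:
    """One session: every task repeated ``trials_per_task_per_session`` times
    in shuffled order, trial responses superposed on a per-channel noise
    floor. Reproducible given (config.seed, subject, session)."""
    ss = np.random.SeedSequence(
        [config.seed, 0xA11CE, profile.seed_offset, session_index]
    )
    order_rng, phase_rng, white_rng = map(np.random.default_rng, ss.spawn(3))

    tasks = list(config.task_set) * config.trials_per_task_per_session
    order = order_rng.permutation(len(tasks))
    tasks = [tasks[i] for i in order]

    spt = config.samples_per_trial
    n_samples = len(tasks) * spt
    cue_offset = int(round(config.cue_s * config.sampling_rate))
    events = [
        TrialEvent(onset_sample=i * spt + cue_offset, task=task)
        for i, task in enumerate(tasks)
    ]

    kernel = _response_kernel(profile, config)
    task_len = int(round(config.task_s * config.sampling_rate))

    # amplitude-weighted boxcar train per channel, one shared convolution each
    hbo = np.zeros((config.n_channels, n_samples))
    stim = np.zeros((config.n_channels, n_samples))
    for ev in events:
        for ch in range(config.n_channels):
            stim[ch, ev.onset_sample : ev.onset_sample + task_len] = trial_amplitude(
                ev.task, ch, profile, config
            )
    for ch in range(config.n_channels):
        hbo[ch] = np.convolve(stim[ch], kernel)[:n_samples]
        hbo[ch] += physiological_noise(
            n_samples,
            config.sampling_rate,
            NoiseSpec(config.noise_spec.components, white_sigma=0.0),
            phase_rng,
        )
        if config.noise_spec.white_sigma:
            hbo[ch] += config.noise_spec.white_sigma * white_rng.standard_normal(
                n_samples
            )
    hbr = config.hbr_ratio * hbo
    return SessionRecording(
        hbo=hbo,
        hbr=hbr,
        sampling_rate=config.sampling_rate,
        events=events,
        subject_id=profile.subject_id,
        session_index=session_index,
    )


def simulate_study(
    config: SimulationConfig,
) -> list[tuple[SubjectProfile, list[SessionRecording]]]:
    """All subjects, all sessions."""
    if config.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    study = []
    for s in range(config.n_subjects):
        profile = subject_profile(config, s)
        sessions = [
            simulate_session(config, profile, k) for k in range(config.n_sessions)
        ]
        study.append((profile, sessions))
    return study
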