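"""Synthetic study generator with known ground truth.

The simulator stands in for human synchronizers and listeners so the full
analysis pipeline can be exercised end-to-end:

* **Motor responses** come from an error-correcting phase oscillator: each
  next event is the previous one plus the intrinsic period, pulled toward
  the nearest upcoming stimulus onset by a coupling fraction, with
  per-event phase noise and optional random-walk drift of the intrinsic
  rate.  Events are rendered as Gaussian amplitude bursts whose width
  depends on the effector (narrow tap transients vs broader
  whisper-syllable bursts).
* **A participant population** whose eight condition couplings (effector ×
  stimulus × rate) arise from three latent components — one fast-general
  and two slow effector-specific — plus independent noise, clipped to
  [0, 1].
* **Perception responses** from a logistic psychometric model with a guess
  floor and lapse rate, giving binary deviant/standard reports per trial.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .envelopes import EnvelopeSignal
from .errors import InvalidParameterError
from .schedules import BlockSpec, OnsetSchedule

__all__ = [
    "OscillatorParams",
    "EffectorKernel",
    "PopulationModel",
    "PsychometricModel",
    "TAP_KERNEL",
    "WHISPER_KERNEL",
    "STIMULUS_FWHM",
    "CONDITIONS",
    "render_burst_envelope",
    "render_stimulus_envelope",
    "simulate_motor_response",
    "default_loadings",
    "simulate_population",
    "simulate_perception_responses",
]


@dataclass(frozen=True)
class OscillatorParams:
    """Error-correcting phase-oscillator parameters.

    coupling : fraction of each cycle's phase error corrected, in [0, 1].
    phase_noise_sd : radians of timing noise per event.
    lag : constant motor lag in seconds.
    drift_sd : Hz random-walk step of the intrinsic rate per event.
    rate_offset : fractional detuning of the intrinsic rate relative to the
        stimulus start rate (e.g. 0.05 = 5% fast).
    """

    coupling: float
    phase_noise_sd: float = 0.0
    lag: float = 0.0
    drift_sd: float = 0.0
    rate_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidParameterError("coupling must lie in [0, 1]")
        if self.phase_noise_sd < 0 or self.drift_sd < 0:
            raise InvalidParameterError("noise and drift SDs must be nonnegative")


@dataclass(frozen=True)
class EffectorKernel:
    """Shape of a motor event in the rendered envelope."""

    label: str
    burst_fwhm: float
    amplitude_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.burst_fwhm <= 0:
            raise InvalidParameterError("burst_fwhm must be positive")


TAP_KERNEL = EffectorKernel("tap", burst_fwhm=0.03, amplitude_jitter=0.1)
WHISPER_KERNEL = EffectorKernel("whisper", burst_fwhm=0.12, amplitude_jitter=0.1)

# burst widths used when rendering the acoustic stimulus envelope itself
STIMULUS_FWHM = {"syllable": 0.10, "tone": 0.05}

# canonical condition order: effector x stimulus x rate
CONDITIONS: tuple[tuple[str, str, str], ...] = (
    ("tap", "syllable", "fast"),
    ("tap", "tone", "fast"),
    ("whisper", "syllable", "fast"),
    ("whisper", "tone", "fast"),
    ("tap", "syllable", "slow"),
    ("tap", "tone", "slow"),
    ("whisper", "syllable", "slow"),
    ("whisper", "tone", "slow"),
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def render_burst_envelope(
    event_times: np.ndarray,
    duration: float,
    fs: float,
    burst_fwhm: float,
    amplitudes: np.ndarray | None = None,
    channel_label: str = "motor",
) -> EnvelopeSignal:
    """Render event times as a sum of Gaussian amplitude bursts."""
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    env = np.zeros(n)
    sigma = burst_fwhm * _FWHM_TO_SIGMA
    half = 4.0 * sigma
    if amplitudes is None:
        amplitudes = np.ones(len(event_times))
    for te, amp in zip(event_times, amplitudes):
        i0 = max(0, int((te - half) * fs))
        i1 = min(n, int((te + half) * fs) + 1)
        if i0 >= i1:
            continue
        env[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - te) / sigma) ** 2)
    return EnvelopeSignal(env, fs, channel_label)


def render_stimulus_envelope(
    schedule: OnsetSchedule, stimulus_class: str, fs: float = 100.0
) -> EnvelopeSignal:
    """Render a schedule as an acoustic stimulus envelope."""
    return render_burst_envelope(
        schedule.onsets,
        schedule.duration,
        fs,
        STIMULUS_FWHM[stimulus_class],
        channel_label="acoustic",
    )


def simulate_motor_events(
    stimulus: OnsetSchedule, params: OscillatorParams, seed: int | None = None
) -> np.ndarray:
    """Event times of the error-correcting oscillator following a stimulus."""
    rng = np.random.default_rng(seed)
    onsets = stimulus.onsets + params.lag
    duration = stimulus.duration
    rate = stimulus.rates[0] * (1.0 + params.rate_offset)
    t = onsets[0]
    events = [t]
    while True:
        if params.drift_sd > 0:
            rate = max(rate + rng.normal(0.0, params.drift_sd), 0.1)
        period = 1.0 / rate
        predicted = t + period
        # error correction toward the nearest stimulus onset strictly after t
        later = onsets[np.searchsorted(onsets, t, side="right"):]
        if len(later):
            nearest = later[np.argmin(np.abs(later - predicted))]
            predicted = predicted + params.coupling * (nearest - predicted)
        jitter = rng.normal(0.0, params.phase_noise_sd) * period / (2.0 * np.pi)
        t_next = predicted + jitter
        if t_next <= t:  # noise pushed the event backwards; keep time moving
            t_next = t + 1e-3
        if t_next > duration:
            break
        events.append(t_next)
        t = t_next
    return np.array(events)


def simulate_motor_response(
    stimulus: OnsetSchedule,
    params: OscillatorParams,
    kernel: EffectorKernel,
    fs: float = 100.0,
    seed: int | None = None,
) -> EnvelopeSignal:
    """Simulate a motor-response envelope to a stimulus schedule."""
    if fs < 100:
        raise InvalidParameterError("fs must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    events = simulate_motor_events(stimulus, params, seed=rng.integers(2**31))
    amps = np.ones(len(events))
    if kernel.amplitude_jitter > 0:
        amps = np.maximum(
            1.0 + rng.normal(0.0, kernel.amplitude_jitter, len(events)), 0.05
        )
    return render_burst_envelope(
        events, stimulus.duration, fs, kernel.burst_fwhm, amps, channel_label="motor"
    )


@dataclass(frozen=True)
class PopulationModel:
    """Latent-component model of per-participant condition couplings.

    Condition couplings are ``base + loadings @ z + noise`` clipped to
    [0, 1], with z standard-normal latent scores scaled by
    ``component_sds``.  The default loading matrix puts the four fast
    conditions on a single fast-general component and splits the slow
    conditions between a slow-whisper and a slow-tap component.
    """

    n_participants: int
    component_loadings: np.ndarray = None  # (8 conditions x 3 components)
    component_sds: np.ndarray = None
    noise_sd: float = 0.04
    base_coupling: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        L = self.component_loadings
        if L is None:
            L = default_loadings()
        L = np.asarray(L, dtype=float)
        object.__setattr__(self, "component_loadings", L)
        sds = self.component_sds
        if sds is None:
            sds = np.ones(L.shape[1])
        sds = np.asarray(sds, dtype=float)
        object.__setattr__(self, "component_sds", sds)
        if not np.all(np.isfinite(L)):
            raise InvalidParameterError("loadings must be finite")
        if np.any(sds < 0) or self.noise_sd < 0:
            raise InvalidParameterError("SDs must be nonnegative")


def default_loadings(scale: float = 0.18) -> np.ndarray:
    """8-condition x 3-component loading matrix: fast-general,
    slow-whisper, slow-tap."""
    L = np.zeros((len(CONDITIONS), 3))
    for i, (effector, _stim, rate) in enumerate(CONDITIONS):
        if rate == "fast":
            L[i, 0] = scale
        elif effector == "whisper":
            L[i, 1] = scale
        else:
            L[i, 2] = scale
    return L


def simulate_population(model: PopulationModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-participant condition couplings from the latent model.

    Returns
    -------
    couplings : DataFrame
        One row per participant × condition with the ground-truth coupling.
    latents : DataFrame
        One row per participant with the latent component scores.
    """
    rng = np.random.default_rng(model.seed)
    k = model.component_loadings.shape[1]
    z = rng.standard_normal((model.n_participants, k)) * model.component_sds
    raw = (
        model.base_coupling
        + z @ model.component_loadings.T
        + rng.normal(0.0, model.noise_sd, (model.n_participants, len(CONDITIONS)))
    )
    coup = np.clip(raw, 0.0, 1.0)
    rows = []
    for p in range(model.n_participants):
        for c, (effector, stim, rate) in enumerate(CONDITIONS):
            rows.append(
                {
                    "participant": f"P{p:03d}",
                    "effector": effector,
                    "stimulus": stim,
                    "rate": rate,
                    "coupling": coup[p, c],
                }
            )
    couplings = pd.DataFrame(rows)
    latents = pd.DataFrame(
        z, columns=[f"component_{i+1}" for i in range(k)]
    )
    latents.insert(0, "participant", [f"P{p:03d}" for p in range(model.n_participants)])
    return couplings, latents


@dataclass(frozen=True)
class PsychometricModel:
    """Logistic deviant-detection model with guess floor and lapse rate.

    P(report deviant | shift s) = guess + (1 − guess − lapse) ·
    logistic(slope · (s − threshold)).  Standards are answered at the
    false-alarm rate implied by s = 0.
    """

    threshold: float
    slope: float
    lapse: float = 0.02
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidParameterError("slope must be positive")
        if not 0 <= self.lapse < 1 or not 0 <= self.guess < 1:
            raise InvalidParameterError("lapse and guess must lie in [0, 1)")

    def p_report_deviant(self, shift: float) -> float:
        return self.guess + (1.0 - self.guess - self.lapse) * float(
            expit(self.slope * (shift - self.threshold))
        )


def simulate_perception_responses(
    block: BlockSpec,
    model: PsychometricModel | dict,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-trial deviant/standard reports for a perception block.

    ``model`` may be a single PsychometricModel or a dict keyed by
    ``(stimulus_class, rate_label)`` with rate_label "fast"/"slow" split at
    3 Hz.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, trial in enumerate(block.trials):
        if isinstance(model, dict):
            rate_label = "fast" if trial.base_rate >= 3.0 else "slow"
            m = model[(trial.stimulus_class, rate_label)]
        else:
            m = model
        p = m.p_report_deviant(trial.shift_fraction)
        report_deviant = bool(rng.random() < p)
        rows.append(
            {
                "trial": i,
                "stimulus": trial.stimulus_class,
                "base_rate": trial.base_rate,
                "is_deviant": trial.is_deviant,
                "shift_fraction": trial.shift_fraction,
                "response": "deviant" if report_deviant else "standard",
                "correct": report_deviant == trial.is_deviant,
            }
        )
    return pd.DataFrame(rows)
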