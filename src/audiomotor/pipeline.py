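"""End-to-end synthetic-study pipelines.

``simulate_study`` renders a full synthetic synchronization study from a
single configuration: a latent-component participant population, per-trial
motor responses to accelerating stimulus sequences, windowed PLVs with
permutation baselines, and envelope spectral features.
``run_synchronization_analysis`` writes the per-trial and per-condition
tables plus a PCA of the condition scores; ``run_perception_analysis``
simulates the deviant-detection task and applies the chance screen.  All
output files carry (package version, config hash, root seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, provenance
from .envelope_features import spectral_peak
from .envelopes import FAST_BAND, SLOW_BAND
from .errors import NoPeakError
from .qc import chance_screen
from .schedules import make_accelerating_schedule, make_perception_block
from .simulate import (
    CONDITIONS,
    STIMULUS_FWHM,
    TAP_KERNEL,
    WHISPER_KERNEL,
    OscillatorParams,
    PopulationModel,
    PsychometricModel,
    default_loadings,
    render_stimulus_envelope,
    simulate_motor_response,
    simulate_perception_responses,
    simulate_population,
)
from .stats import pca_varimax
from .sync_metrics import permutation_baseline

__all__ = [
    "simulate_study",
    "run_synchronization_analysis",
    "run_perception_analysis",
    "condition_matrix",
    "default_psychometric_models",
]

_KERNELS = {"tap": TAP_KERNEL, "whisper": WHISPER_KERNEL}
_BANDS = {"fast": FAST_BAND, "slow": SLOW_BAND}


def _schedules(config: RunConfig) -> dict:
    lo_f, hi_f, step_f = config.fast_rates
    lo_s, hi_s, step_s = config.slow_rates
    return {
        "fast": make_accelerating_schedule(lo_f, hi_f, step_f, config.tokens_per_step),
        "slow": make_accelerating_schedule(lo_s, hi_s, step_s, config.tokens_per_step),
    }


def _features_or_nan(env, f_max: float = 10.0):
    try:
        f = spectral_peak(env, f_max)
        return f.peak_freq, f.peak_amp, f.peak_width
    except NoPeakError:
        return np.nan, np.nan, np.nan


def simulate_study(config: RunConfig) -> dict:
    """Simulate and analyze a full synchronization study.

    Returns a dict with ``trials`` (per-trial PLVs and envelope features),
    ``conditions`` (per participant × condition normalized PLV),
    ``couplings`` and ``latents`` (ground truth).
    """
    ss_pop, ss_trials = config.seed_sequences(2)
    model = PopulationModel(
        n_participants=config.n_participants,
        component_loadings=default_loadings(config.loading_scale),
        noise_sd=config.noise_sd,
        base_coupling=config.base_coupling,
        seed=ss_pop.generate_state(1)[0] % 2**31,
    )
    couplings, latents = simulate_population(model)
    coup_idx = couplings.set_index(["participant", "effector", "stimulus", "rate"])

    schedules = _schedules(config)
    stim_envs = {
        (stim, rate): render_stimulus_envelope(schedules[rate], stim, config.fs)
        for stim in STIMULUS_FWHM
        for rate in schedules
    }
    stim_feats = {key: _features_or_nan(env) for key, env in stim_envs.items()}

    n_total = config.n_participants * len(CONDITIONS) * config.n_trials_per_condition
    children = ss_trials.spawn(n_total)
    rows = []
    idx = 0
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        for effector, stim, rate in CONDITIONS:
            coupling = float(coup_idx.loc[(pid, effector, stim, rate), "coupling"])
            params = OscillatorParams(
                coupling=coupling,
                phase_noise_sd=config.phase_noise_sd,
                lag=config.lag,
                rate_offset=config.rate_offset,
            )
            for trial in range(config.n_trials_per_condition):
                child = children[idx]
                idx += 1
                rng = np.random.default_rng(child)
                env_mot = simulate_motor_response(
                    schedules[rate],
                    params,
                    _KERNELS[effector],
                    fs=config.fs,
                    seed=rng.integers(2**31),
                )
                est = permutation_baseline(
                    stim_envs[(stim, rate)],
                    env_mot,
                    _BANDS[rate],
                    n_permutations=config.n_permutations,
                    rng=rng,
                )
                mot_pf, mot_pa, mot_pw = _features_or_nan(env_mot)
                ac_pf, ac_pa, ac_pw = stim_feats[(stim, rate)]
                rows.append(
                    {
                        "participant": pid,
                        "effector": effector,
                        "stimulus": stim,
                        "rate": rate,
                        "trial": trial,
                        "coupling": coupling,
                        "raw_plv": est.raw_plv,
                        "baseline_plv": est.baseline_plv,
                        "normalized_plv": est.normalized_plv,
                        "n_windows": est.n_windows,
                        "n_permutations": est.n_permutations,
                        "motor_peak_freq_hz": mot_pf,
                        "motor_peak_amp": mot_pa,
                        "motor_peak_width_hz": mot_pw,
                        "acoustic_peak_freq_hz": ac_pf,
                        "acoustic_peak_amp": ac_pa,
                        "acoustic_peak_width_hz": ac_pw,
                    }
                )
    trials = pd.DataFrame(rows)
    conditions = (
        trials.groupby(["participant", "effector", "stimulus", "rate"], sort=True)[
            "normalized_plv"
        ]
        .agg(["mean", "count"])
        .rename(columns={"mean": "plv", "count": "n_trials"})
        .reset_index()
    )
    return {
        "trials": trials,
        "conditions": conditions,
        "couplings": couplings,
        "latents": latents,
    }


def condition_matrix(conditions: pd.DataFrame, value: str = "plv") -> pd.DataFrame:
    """Pivot the long condition table to a participant × 8-condition matrix."""
    wide = conditions.pivot_table(
        index="participant",
        columns=["effector", "stimulus", "rate"],
        values=value,
    )
    wide = wide[[tuple(c) for c in CONDITIONS]]
    wide.columns = ["_".join(c) for c in wide.columns]
    return wide


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    prov = provenance(config)
    header = (
        f"# package_version={prov['package_version']} "
        f"config_hash={prov['config_hash']} seed={prov['seed']}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_synchronization_analysis(config: RunConfig, outdir) -> dict:
    """Simulate, analyze, and write the synchronization-task tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_study(config)
    _write_csv(result["trials"], outdir / "trials.csv", config)
    _write_csv(result["conditions"], outdir / "conditions.csv", config)
    _write_csv(result["couplings"], outdir / "ground_truth_couplings.csv", config)
    _write_csv(result["latents"], outdir / "ground_truth_latents.csv", config)

    wide = condition_matrix(result["conditions"])
    solution = pca_varimax(wide, retain="kaiser")
    _write_csv(
        solution.loadings_frame().reset_index(names="condition"),
        outdir / "pca_loadings.csv",
        config,
    )
    pca_json = {
        "provenance": provenance(config),
        "eigenvalues": solution.eigenvalues.tolist(),
        "n_retained": solution.n_retained,
        "variance_explained": solution.variance_explained,
        "rotation": solution.rotation,
    }
    (outdir / "pca.json").write_text(json.dumps(pca_json, indent=2))
    result["pca"] = solution
    return result


def default_psychometric_models(config: RunConfig, threshold_jitter: float = 0.0,
                                rng: np.random.Generator | None = None) -> dict:
    """Per-condition psychometric models.

    Threshold placement encodes the rate × stimulus interaction of the
    deviant task: syllables are easier (threshold further below the tested
    shift range) at fast rates, tones at slow rates.  Thresholds sit at or
    below the tested shift ranges so deviant accuracy stays well above
    chance, mirroring the task's difficulty calibration.
    """
    base = {
        ("syllable", "fast"): 0.22,
        ("syllable", "slow"): 0.30,
        ("tone", "fast"): 0.16,
        ("tone", "slow"): 0.10,
    }
    models = {}
    for key, thr in base.items():
        if threshold_jitter > 0 and rng is not None:
            thr = thr + rng.normal(0.0, threshold_jitter)
        models[key] = PsychometricModel(threshold=thr, slope=25.0, lapse=0.02)
    return models


def run_perception_analysis(config: RunConfig, outdir) -> dict:
    """Simulate the deviant-detection task and apply the chance screen."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    half = config.n_perception_trials // 2
    all_rows = []
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        rng = np.random.default_rng(ss[p])
        models = default_psychometric_models(config, threshold_jitter=0.02, rng=rng)
        for stim, shift_range in (
            ("syllable", config.syllable_shift_range),
            ("tone", config.tone_shift_range),
        ):
            for rate_label, center in (("fast", 4.5), ("slow", 2.0)):
                block = make_perception_block(
                    stim,
                    half,
                    rate_center=center,
                    rate_grid_fraction=0.02,
                    n_grid=5,
                    shift_range=shift_range,
                    seed=int(rng.integers(2**31)),
                )
                resp = simulate_perception_responses(
                    block, models, seed=int(rng.integers(2**31))
                )
                resp.insert(0, "participant", pid)
                resp["rate"] = rate_label
                all_rows.append(resp)
    responses = pd.concat(all_rows, ignore_index=True)
    report = chance_screen(responses, chance=config.chance_level)
    accuracy = report.accuracy
    _write_csv(responses, outdir / "perception_trials.csv", config)
    _write_csv(accuracy, outdir / "perception_accuracy.csv", config)
    (outdir / "exclusions.json").write_text(
        json.dumps({"provenance": provenance(config), **report.to_json_dict()}, indent=2)
    )
    return {"responses": responses, "accuracy": accuracy, "report": report}
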