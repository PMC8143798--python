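"""Simulation-based parameter recovery: generate -> detect -> analyze.

Each runner simulates sessions whose generative parameters are the
coefficients the analyses are meant to estimate, pushes the synthetic data
through the full pipeline (saccade detection on the eye traces, movement
selection, spike counting, model fits), and returns the recovered values
next to the ground truth.  Sessions are simulated in chunks of a few
thousand trials so memory stays flat regardless of the total run size.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .interaction import (amplitude_timecourse, estimate_efferent_lag,
                          fit_interaction_model, influence_window_halfwidth,
                          spike_timecourse_by_amplitude)
from .kinematics import DirectionClass, classify_direction
from .pipeline import amplitude_dataset, detect_all, fit_toward_amplitude_model
from .rfmap import population_average
from .simulate import fixture_config, simulate_session
from .spikes import rate_curve

_CHUNK = 2000


def _chunk_seeds(seed: int, n_chunks: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_chunks)]


def _pooled_dataset(fixture: str, seed: int, n_trials: int,
                    mode: str = "post_stimulus",
                    first_per_trial: bool | None = None,
                    cfg_analysis: AnalysisConfig | None = None):
    """Simulate ``n_trials`` in chunks and pool pipeline movement rows."""
    n_chunks = max(1, -(-n_trials // _CHUNK))
    per_chunk = -(-n_trials // n_chunks)
    frames = []
    sim_cfg = None
    for cs in _chunk_seeds(seed, n_chunks):
        sim_cfg = fixture_config(fixture, seed=cs, n_trials=per_chunk)
        bundle, _ = simulate_session(sim_cfg)
        frames.append(amplitude_dataset(bundle, cfg_analysis, mode=mode,
                                        first_per_trial=first_per_trial))
    return pd.concat(frames, ignore_index=True), sim_cfg


@dataclass
class RecoveryResult:
    value: float
    se: float
    true_value: float
    n: int
    extra: dict


def recover_amplitude_model(fixture: str = "exp1_near", seed: int = 1,
                            n_trials: int = 28000) -> tuple[RecoveryResult, RecoveryResult]:
    """Recover (slope, intercept) of the toward-movement amplitude model."""
    data, sim_cfg = _pooled_dataset(fixture, seed, n_trials)
    res = fit_toward_amplitude_model(data)
    fit = res.fit
    slope = RecoveryResult(value=fit.beta1, se=fit.se1_robust,
                           true_value=sim_cfg.beta1_toward, n=fit.n_obs,
                           extra={"classical_se": fit.se1, "t": fit.t1, "p": fit.p1})
    intercept = RecoveryResult(value=fit.beta0, se=fit.se0_robust,
                               true_value=sim_cfg.baseline_amp_mean, n=fit.n_obs,
                               extra={"classical_se": fit.se0})
    return slope, intercept


def recover_sustained_slope(seed: int = 1, n_trials: int = 9000) -> tuple[RecoveryResult, RecoveryResult]:
    """Recover the sustained-discharge gain from movements >550 ms post-stimulus."""
    data, sim_cfg = _pooled_dataset("exp2_sustained", seed, n_trials,
                                    mode="sustained", first_per_trial=False)
    res = fit_toward_amplitude_model(data)
    fit = res.fit
    slope = RecoveryResult(value=fit.beta1, se=fit.se1_robust,
                           true_value=sim_cfg.beta1_toward, n=fit.n_obs,
                           extra={"classical_se": fit.se1})
    intercept = RecoveryResult(value=fit.beta0, se=fit.se0_robust,
                               true_value=sim_cfg.baseline_amp_mean, n=fit.n_obs,
                               extra={})
    return slope, intercept


def recover_interaction(seed: int = 1, n_trials: int = 40000) -> RecoveryResult:
    """Recover the spikes-by-eccentricity interaction coefficient."""
    data, sim_cfg = _pooled_dataset("ecc_interaction", seed, n_trials)
    tow = data[data["toward"]]
    fit = fit_interaction_model(tow["count"].to_numpy(int),
                                tow["eccentricity"].to_numpy(),
                                tow["amplitude"].to_numpy())
    return RecoveryResult(value=fit.interaction, se=fit.interaction_se_robust,
                          true_value=sim_cfg.gain_vs_ecc[1], n=fit.n_obs,
                          extra={"classical_se": fit.interaction_se,
                                 "gain_at_1deg": float(fit.beta[1] + fit.beta[3])})


def recover_influence_halfwidth(seed: int = 1, n_trials: int = 6000) -> RecoveryResult:
    """Recover the boxcar influence half-width from the 5-ms spike time course."""
    n_chunks = max(1, -(-n_trials // _CHUNK))
    per_chunk = -(-n_trials // n_chunks)
    sacc, trains = [], []
    sim_cfg = None
    for cs in _chunk_seeds(seed, n_chunks):
        sim_cfg = fixture_config("boxcar_influence", seed=cs, n_trials=per_chunk)
        bundle, _ = simulate_session(sim_cfg)
        trial_by_id = {t.trial_id: t for t in bundle.trials}
        for s in detect_all(bundle):
            t = trial_by_id[s.trial_id]
            nid = next(iter(t.spikes), None)
            if nid is None:
                continue
            if classify_direction(s, sim_cfg.neuron_direction) is DirectionClass.TOWARD:
                sacc.append(s)
                trains.append(t.train(nid))
    tc = spike_timecourse_by_amplitude(sacc, trains)
    hw = influence_window_halfwidth(tc)
    return RecoveryResult(value=hw, se=float("nan"),
                          true_value=sim_cfg.influence_halfwidth,
                          n=len(sacc), extra={"per_bin_n": tc.n_movements.tolist()})


def recover_efferent_lag(seed: int = 1, n_trials: int = 9000) -> RecoveryResult:
    """Recover the efferent delay by cross-correlating the amplitude and
    normalized population-rate time courses."""
    n_chunks = max(1, -(-n_trials // _CHUNK))
    per_chunk = -(-n_trials // n_chunks)
    frames = []
    curve_sum: dict[str, np.ndarray] = {}
    curve_n: dict[str, int] = defaultdict(int)
    sim_cfg = None
    grid = None
    window = (-100.0, 150.0)
    for cs in _chunk_seeds(seed, n_chunks):
        sim_cfg = fixture_config("efferent_lag", seed=cs, n_trials=per_chunk)
        bundle, _ = simulate_session(sim_cfg)
        frames.append(amplitude_dataset(bundle, first_per_trial=True))
        by_neuron = defaultdict(list)
        for t in bundle.trials:
            for nid in t.spikes:
                by_neuron[nid].append(t)
        for nid, ts in by_neuron.items():
            c = rate_curve([t.train(nid) for t in ts],
                           [t.stimulus_onset_ms for t in ts], window)
            grid = c.time
            if nid not in curve_sum:
                curve_sum[nid] = c.rate * c.n_trials
            else:
                curve_sum[nid] += c.rate * c.n_trials
            curve_n[nid] += c.n_trials
    data = pd.concat(frames, ignore_index=True)
    tow = data[data["toward"]]
    centers, mean, _sem, _n = amplitude_timecourse(
        tow["onset_rel_stim_ms"].to_numpy(), tow["amplitude"].to_numpy())
    curves = [curve_sum[nid] / curve_n[nid] for nid in sorted(curve_sum)]
    refs = [float(np.max(c)) for c in curves]
    pop = population_average(grid, curves, refs)
    lag = estimate_efferent_lag(centers, mean, pop.time, pop.mean)
    return RecoveryResult(value=lag, se=float("nan"),
                          true_value=sim_cfg.efferent_delay,
                          n=int(len(tow)), extra={})
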