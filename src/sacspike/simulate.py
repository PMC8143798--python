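"""Synthetic sessions with the statistical structure the analyses assume.

Each trial carries one 'recorded' neuron (sessions in the experiments record
one analyzed neuron at a time; trials cycle through the configured neuron
list), an inhomogeneous-Poisson spike train (baseline discharge, a
condition-dependent stimulus-locked visual burst, and a low-rate sustained
plateau), a renewal process of microsaccades, and a continuous eye trace
synthesized from raised-cosine velocity waveforms plus fixational noise.

The amplitude-coupling rule is the generative counterpart of the statistic
the analyses estimate: each movement's amplitude is

    A = floor + (baseline_amp + beta1_eff * S - floor) * exp(sigma*z - sigma^2/2)

where ``S`` counts the coupling neuron's spikes in the influence window
(``count_window``: [onset, onset+20) ms; ``boxcar_kernel``: [onset - delay -
h, onset - delay + h) with the efferent delay shifting the window into the
past), and ``beta1_eff`` depends on movement direction (toward/opposite the
neuron's RF) and, optionally, linearly on the neuron's preferred
eccentricity.  The multiplicative lognormal scatter keeps E[A | S] exactly
linear in S while guaranteeing positive, right-skewed amplitudes like real
microsaccade data; additive Gaussian scatter is available via
``noise_model="gaussian"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io import NeuronMeta, SessionBundle, Trial
from .kinematics import EyeTrace, angular_distance
from .spikes import SpikeTrain


class SimulationError(ValueError):
    pass


@dataclass
class RostralTuning:
    """Movement-field tuning of a rostral motor neuron in log-polar space."""

    preferred_amplitude: float = 0.2   # deg
    preferred_direction: float = 0.0   # deg
    sd_logecc: float = 0.6             # in log(amp/0.03) units
    sd_direction: float = 40.0         # deg
    peak_rate: float = 200.0           # sp/s at the hotspot
    burst_halfwidth: float = 10.0      # ms, motor burst around movement onset


@dataclass
class SimConfig:
    seed: int = 0
    n_trials: int = 200
    trial_length: float = 1000.0          # ms
    stimulus_onset: Union[float, tuple[float, float]] = 500.0
    conditions: Sequence[float] = (20.0, 40.0, 80.0)     # e.g. contrast (%)
    burst_latency: dict = field(default_factory=lambda: {20.0: 45.0, 40.0: 40.0, 80.0: 35.0})
    burst_peak_rate: dict = field(default_factory=lambda: {20.0: 150.0, 40.0: 250.0, 80.0: 350.0})
    burst_shape_k: float = 2.0            # gamma-pulse shape
    burst_tau: float = 12.0               # ms, gamma-pulse time constant
    sustained_rate: float = 20.0          # sp/s plateau after the burst
    sustained_onset: float = 120.0        # ms after stimulus, ramped over 50 ms
    baseline_rate: float = 10.0           # sp/s
    isi_mean: float = 700.0               # ms, mean inter-saccade interval
    isi_shape: float = 4.0                # gamma renewal shape
    baseline_amp_mean: float = 0.14253    # deg
    noise_model: str = "lognormal"        # or "gaussian"
    amp_log_sd: float = 0.8               # lognormal sigma (dimensionless)
    amp_noise_sd: float = 0.03            # deg (gaussian mode)
    amp_floor: float = 0.07               # deg, smallest generated amplitude
    beta1_toward: float = 0.066294        # deg per spike
    beta1_opposite: float = 0.0
    influence_mode: str = "count_window"  # or "boxcar_kernel"
    influence_halfwidth: float = 30.0     # ms (boxcar mode)
    efferent_delay: float = 20.0          # ms (boxcar mode)
    neuron_eccentricities: Sequence[float] = (1.5, 2.5, 3.5, 4.5)
    neuron_direction: float = 0.0         # RF direction shared by caudal neurons
    gain_vs_ecc: Optional[tuple[float, float]] = None   # beta1(ecc) = g0 + g1*ecc
    toward_bias: float = 0.7              # P(toward) for post-stimulus movements
    toward_bias_window: tuple[float, float] = (0.0, 250.0)
    duration_scale: float = 20.0          # D = max(15, scale * A**0.4) ms
    eye_noise_sd: float = 0.005           # deg
    sampling_rate: float = 1000.0         # Hz
    rostral: Optional[RostralTuning] = None
    session_id: str = "sim"

    def validate(self) -> None:
        for name in ("sustained_rate", "baseline_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for c in self.conditions:
            if self.burst_peak_rate.get(c, 0.0) < 0:
                raise SimulationError("burst peak rates must be >= 0")
        if self.isi_mean <= 0 or self.isi_shape <= 0:
            raise SimulationError("inter-saccade interval parameters must be positive")
        if self.influence_mode not in ("count_window", "boxcar_kernel"):
            raise SimulationError(f"unknown influence_mode {self.influence_mode!r}")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise SimulationError(f"unknown noise_model {self.noise_model!r}")
        if not 0.0 <= self.toward_bias <= 1.0:
            raise SimulationError("toward_bias must lie in [0, 1]")
        if self.baseline_amp_mean <= self.amp_floor:
            raise SimulationError("baseline_amp_mean must exceed amp_floor")
        for ecc in self.neuron_eccentricities:
            if self.beta1_at(ecc) < 0:
                raise SimulationError(
                    f"effective toward gain negative at eccentricity {ecc}")

    def beta1_at(self, ecc: float) -> float:
        if self.gain_vs_ecc is None:
            return self.beta1_toward
        g0, g1 = self.gain_vs_ecc
        return g0 + g1 * ecc


@dataclass
class MovementTruth:
    trial_id: str
    neuron_id: str
    onset_ms: float
    direction: float
    toward: bool
    amplitude: float
    spike_count: int          # spikes in the configured influence window
    beta_eff: float
    duration_ms: float


@dataclass
class GroundTruth:
    config: SimConfig
    movements: list[MovementTruth]
    stimulus_onsets: dict[str, float]


def _raised_cosine_displacement(t_rel: np.ndarray, amplitude: float,
                                duration: float) -> np.ndarray:
    """Radial displacement profile of a raised-cosine-velocity saccade."""
    u = np.clip(t_rel / duration, 0.0, 1.0)
    return amplitude * (u - np.sin(2 * np.pi * u) / (2 * np.pi))


def saccade_duration(amplitude: float, scale: float = 20.0) -> float:
    return max(15.0, scale * amplitude ** 0.4)


def _gamma_pulse(t: np.ndarray, onset: float, k: float, tau: float,
                 peak: float) -> np.ndarray:
    """Gamma-shaped rate pulse normalized so its maximum equals ``peak``."""
    u = np.clip((t - onset) / tau, 0.0, None)
    mode = k - 1.0
    if mode <= 0:
        shape = np.exp(-u)
    else:
        shape = (u / mode) ** mode * np.exp(mode - u)
    return peak * shape


def _spike_times_from_rate(rate_per_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(rate_per_ms)
    total = int(counts.sum())
    if total == 0:
        return np.array([])
    bins = np.repeat(np.arange(counts.size), counts)
    return np.sort(bins + rng.random(total))


def _draw_direction(rng: np.random.Generator, cfg: SimConfig, onset_rel_stim: float) -> float:
    lo, hi = cfg.toward_bias_window
    if lo <= onset_rel_stim < hi:
        toward = rng.random() < cfg.toward_bias
        off = (rng.random() * 180.0) - 90.0
        if toward:
            return (cfg.neuron_direction + off) % 360.0
        return (cfg.neuron_direction + 180.0 + off) % 360.0
    return rng.random() * 360.0


def simulate_session(cfg: SimConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate one full synthetic session (bit-identical for a fixed seed)."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_spikes, rng_events, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    dt = 1000.0 / cfg.sampling_rate
    n_samp = int(round(cfg.trial_length / dt))
    tgrid = np.arange(n_samp) * dt

    neurons = [NeuronMeta(neuron_id=f"n{k}", cls="visual_motor", site="caudal",
                          rf_eccentricity=float(e), rf_direction=cfg.neuron_direction)
               for k, e in enumerate(cfg.neuron_eccentricities)]
    rostral_meta = None
    if cfg.rostral is not None:
        rostral_meta = NeuronMeta(neuron_id="rostral0", cls="rostral_motor",
                                  site="rostral", rf_eccentricity=cfg.rostral.preferred_amplitude,
                                  rf_direction=cfg.rostral.preferred_direction)

    conditions = list(cfg.conditions)
    trials: list[Trial] = []
    movements: list[MovementTruth] = []
    stim_onsets: dict[str, float] = {}
    margin = 80.0  # keep whole waveforms inside the trace

    for i in range(cfg.n_trials):
        tid = f"t{i:05d}"
        neuron = neurons[i % len(neurons)]
        cond = conditions[i % len(conditions)]
        if isinstance(cfg.stimulus_onset, (tuple, list)):
            lo, hi = cfg.stimulus_onset
            stim = float(lo + rng_events.random() * (hi - lo))
        else:
            stim = float(cfg.stimulus_onset)
        stim_onsets[tid] = stim

        # --- caudal spike train: baseline + visual burst + sustained plateau
        rate = np.full(n_samp, cfg.baseline_rate, dtype=float)
        peak = cfg.burst_peak_rate.get(cond, 0.0)
        if peak > 0:
            lat = cfg.burst_latency.get(cond, 40.0)
            rate += _gamma_pulse(tgrid, stim + lat, cfg.burst_shape_k,
                                 cfg.burst_tau, peak)
        if cfg.sustained_rate > 0:
            ramp = np.clip((tgrid - stim - cfg.sustained_onset) / 50.0, 0.0, 1.0)
            rate += cfg.sustained_rate * ramp
        spike_times = _spike_times_from_rate(rate * dt / 1000.0, rng_spikes) * dt

        # --- microsaccade renewal process
        scale = cfg.isi_mean / cfg.isi_shape
        t = -float(rng_events.random()) * cfg.isi_mean
        onsets: list[float] = []
        while True:
            t += float(rng_events.gamma(cfg.isi_shape, scale))
            if t >= cfg.trial_length - margin:
                break
            if t >= margin:
                onsets.append(t)

        # --- movement parameters via the coupling rule
        ev_dir = []
        ev_amp = []
        ev_dur = []
        for onset in onsets:
            d = _draw_direction(rng_events, cfg, onset - stim)
            toward = angular_distance(d, cfg.neuron_direction) <= 90.0
            beta = cfg.beta1_at(neuron.rf_eccentricity) if toward else cfg.beta1_opposite
            if cfg.influence_mode == "count_window":
                w0, w1 = onset, onset + 20.0
            else:
                c = onset - cfg.efferent_delay
                w0, w1 = c - cfg.influence_halfwidth, c + cfg.influence_halfwidth
            S = int(np.searchsorted(spike_times, w1, side="left")
                    - np.searchsorted(spike_times, w0, side="left"))
            mu = cfg.baseline_amp_mean + beta * S
            if cfg.noise_model == "lognormal":
                # shifted lognormal: E[A|S] = mu exactly, A >= amp_floor, and
                # the right-skewed tail of real microsaccade amplitudes
                z = rng_events.standard_normal()
                scatter = math.exp(cfg.amp_log_sd * z - cfg.amp_log_sd ** 2 / 2.0)
                amp = cfg.amp_floor + (mu - cfg.amp_floor) * scatter
            else:
                amp = max(mu + cfg.amp_noise_sd * rng_events.standard_normal(),
                          cfg.amp_floor)
            dur = saccade_duration(amp, cfg.duration_scale)
            ev_dir.append(d)
            ev_amp.append(amp)
            ev_dur.append(dur)
            movements.append(MovementTruth(
                trial_id=tid, neuron_id=neuron.neuron_id, onset_ms=float(onset),
                direction=float(d), toward=bool(toward), amplitude=float(amp),
                spike_count=S, beta_eff=float(beta), duration_ms=float(dur)))

        # --- eye trace
        x = rng_noise.standard_normal(n_samp) * cfg.eye_noise_sd
        y = rng_noise.standard_normal(n_samp) * cfg.eye_noise_sd
        for onset, d, amp, dur in zip(onsets, ev_dir, ev_amp, ev_dur):
            disp = _raised_cosine_displacement(tgrid - onset, amp, dur)
            rad = math.radians(d)
            x += disp * math.cos(rad)
            y += disp * math.sin(rad)
        eye = EyeTrace(time=tgrid.copy(), x=x, y=y)

        spikes = {}
        if spike_times.size:
            spikes[neuron.neuron_id] = SpikeTrain(trial_id=tid,
                                                  neuron_id=neuron.neuron_id,
                                                  times=spike_times)
        if cfg.rostral is not None:
            rt = _rostral_spikes(cfg.rostral, onsets, ev_amp, ev_dir,
                                 n_samp, dt, rng_spikes)
            if rt.size:
                spikes["rostral0"] = SpikeTrain(trial_id=tid, neuron_id="rostral0",
                                                times=rt)
        trials.append(Trial(trial_id=tid, stimulus_onset_ms=stim,
                            condition="contrast", condition_value=float(cond),
                            eye=eye, spikes=spikes))

    all_neurons = neurons + ([rostral_meta] if rostral_meta else [])
    bundle = SessionBundle(session_id=cfg.session_id, trials=trials,
                           neurons=all_neurons, sampling_rate=cfg.sampling_rate)
    return bundle, GroundTruth(config=cfg, movements=movements,
                               stimulus_onsets=stim_onsets)


def _rostral_spikes(tuning: RostralTuning, onsets, amps, dirs,
                    n_samp: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Motor bursts around movement onset, gain set by log-polar RF tuning."""
    tgrid = np.arange(n_samp) * dt
    rate = np.full(n_samp, 5.0)
    le0 = math.log(tuning.preferred_amplitude / 0.03)
    for onset, amp, d in zip(onsets, amps, dirs):
        le = math.log(max(amp, 1e-6) / 0.03)
        dd = angular_distance(d, tuning.preferred_direction)
        gain = math.exp(-0.5 * ((le - le0) / tuning.sd_logecc) ** 2
                        - 0.5 * (dd / tuning.sd_direction) ** 2)
        # raised-cosine rate bump within +/- burst_halfwidth of onset
        u = (tgrid - onset) / tuning.burst_halfwidth
        bump = np.where(np.abs(u) < 1.0, 0.5 * (1 + np.cos(np.pi * u)), 0.0)
        rate = rate + tuning.peak_rate * gain * bump
    return _spike_times_from_rate(rate * dt / 1000.0, rng) * dt


# ---------------------------------------------------------------------------
# fixtures

_FIXTURES = ("exp1_near", "exp1_far", "exp2_sustained", "ecc_interaction",
             "exp3_dual_site", "null_opposite", "step_timing",
             "boxcar_influence", "efferent_lag")


def fixture_config(name: str, seed: int = 0, n_trials: int | None = None) -> SimConfig:
    """Generator settings for the named study scenario."""
    if name == "exp1_near":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 2000,
                        trial_length=900.0, stimulus_onset=500.0,
                        neuron_eccentricities=(1.5, 2.5, 3.5, 4.5),
                        baseline_amp_mean=0.14253, beta1_toward=0.066294,
                        session_id="exp1_near")
    elif name == "exp1_far":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 2000,
                        trial_length=900.0, stimulus_onset=500.0,
                        neuron_eccentricities=(5.5, 7.0, 8.5, 10.0),
                        baseline_amp_mean=0.12368, beta1_toward=0.0098876,
                        session_id="exp1_far")
    elif name == "exp2_sustained":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 1000,
                        trial_length=2500.0, stimulus_onset=300.0,
                        conditions=(0.56, 2.22, 4.44),   # cycles/deg
                        burst_latency={0.56: 35.0, 2.22: 45.0, 4.44: 55.0},
                        burst_peak_rate={0.56: 300.0, 2.22: 250.0, 4.44: 150.0},
                        sustained_rate=15.0, baseline_rate=5.0,
                        baseline_amp_mean=0.1098, beta1_toward=0.0126,
                        toward_bias=0.5, toward_bias_window=(0.0, 2500.0),
                        session_id="exp2_sustained")
    elif name == "ecc_interaction":
        # gain declines linearly with preferred eccentricity but stays positive
        cfg = SimConfig(seed=seed, n_trials=n_trials or 2000,
                        trial_length=900.0, stimulus_onset=500.0,
                        neuron_eccentricities=tuple(np.arange(1.0, 10.5, 1.0)),
                        gain_vs_ecc=(0.09, -0.0080709),
                        session_id="ecc_interaction")
    elif name == "exp3_dual_site":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 400,
                        trial_length=1800.0, stimulus_onset=(1550.0, 1650.0),
                        neuron_eccentricities=(6.0,),
                        rostral=RostralTuning(),
                        session_id="exp3_dual_site")
    elif name == "null_opposite":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 2000,
                        trial_length=900.0, stimulus_onset=500.0,
                        beta1_toward=0.066294, beta1_opposite=0.0,
                        toward_bias=0.3,   # oversample opposite movements
                        session_id="null_opposite")
    elif name == "step_timing":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 3000,
                        trial_length=900.0, stimulus_onset=500.0,
                        session_id="step_timing")
    elif name == "boxcar_influence":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 3000,
                        trial_length=900.0, stimulus_onset=500.0,
                        burst_peak_rate={20.0: 0.0, 40.0: 0.0, 80.0: 0.0},
                        sustained_rate=0.0, baseline_rate=40.0,
                        influence_mode="boxcar_kernel",
                        influence_halfwidth=30.0, efferent_delay=0.0,
                        toward_bias=0.9, toward_bias_window=(-1e9, 1e9),
                        session_id="boxcar_influence")
    elif name == "efferent_lag":
        cfg = SimConfig(seed=seed, n_trials=n_trials or 9000,
                        trial_length=900.0, stimulus_onset=500.0,
                        influence_mode="boxcar_kernel",
                        influence_halfwidth=30.0, efferent_delay=20.0,
                        session_id="efferent_lag")
    else:
        raise SimulationError(f"unknown fixture {name!r}; pick one of {_FIXTURES}")
    return cfg


def make_fixture(name: str, seed: int = 0, n_trials: int | None = None) -> SessionBundle:
    bundle, _ = simulate_session(fixture_config(name, seed, n_trials))
    return bundle
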