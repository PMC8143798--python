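"""Event-aligned spike counting, firing-rate estimation, and burst measures.

Firing-rate curves are built from 1-ms binned spike counts smoothed with a
Gaussian kernel (sigma 10 ms by default) and averaged across trials; the
kernel conserves spike mass, so the integral of a single-trial curve equals
that trial's spike count.  All counting windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import stdtr

from .config import AnalysisConfig
from .kinematics import Saccade


class SpikeError(ValueError):
    pass


@dataclass
class SpikeTrain:
    """Spike times (ms, relative to trial start) of one neuron on one trial."""

    trial_id: str
    neuron_id: str
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SpikeError("spike times must be a 1-d sequence")
        if not np.all(np.isfinite(self.times)):
            raise SpikeError("spike times must be finite")
        if np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (self.trial_id == other.trial_id
                and self.neuron_id == other.neuron_id
                and np.array_equal(self.times, other.times))


@dataclass
class RateCurve:
    time: np.ndarray       # ms, uniform grid (relative to the align event)
    rate: np.ndarray       # spikes/s, across-trial mean
    n_trials: int
    sem: np.ndarray        # spikes/s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)


@dataclass
class BurstMeasure:
    peak_rate: float   # spikes/s
    peak_time: float   # ms after the align event (stimulus onset)


@dataclass
class TTestResult:
    statistic: float
    p: float
    df: float
    mean_a: float = float("nan")
    mean_b: float = float("nan")


def count_spikes(train: SpikeTrain, t0: float, t1: float) -> int:
    """Number of spikes in the half-open window [t0, t1)."""
    if not t0 < t1:
        raise SpikeError("window must satisfy t0 < t1")
    t = train.times
    return int(np.searchsorted(t, t1, side="left") - np.searchsorted(t, t0, side="left"))


def rate_curve(trains: Sequence[SpikeTrain], align_times: Sequence[float],
               window: tuple[float, float], kernel_sd_ms: float = 10.0,
               bin_ms: float = 1.0) -> RateCurve:
    """Across-trial mean firing rate aligned to a per-trial event.

    Each trial's spikes are re-referenced to its align time, binned at
    ``bin_ms``, smoothed with a Gaussian kernel, scaled to spikes/s, and the
    resulting single-trial curves are averaged; the SEM is over trials.
    """
    trains = list(trains)
    if len(trains) == 0:
        raise SpikeError("rate_curve needs at least one trial")
    if len(trains) != len(align_times):
        raise SpikeError("need exactly one align time per trial")
    t0, t1 = window
    if not t0 < t1:
        raise SpikeError("window must be an ordered pair")
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    per_trial = np.empty((len(trains), centers.size))
    sigma_bins = kernel_sd_ms / bin_ms
    for i, (train, at) in enumerate(zip(trains, align_times)):
        rel = train.times - at
        counts, _ = np.histogram(rel, bins=edges)
        smoothed = gaussian_filter1d(counts.astype(float), sigma_bins,
                                     mode="constant", truncate=8.0)
        per_trial[i] = smoothed * (1000.0 / bin_ms)
    mean = per_trial.mean(axis=0)
    if len(trains) > 1:
        sem = per_trial.std(axis=0, ddof=1) / np.sqrt(len(trains))
    else:
        sem = np.zeros_like(mean)
    return RateCurve(time=centers, rate=mean, n_trials=len(trains), sem=sem)


def measure_visual_burst(curve: RateCurve, cfg: AnalysisConfig | None = None,
                         window: tuple[float, float] | None = None) -> BurstMeasure:
    """Peak rate and its time restricted to the visual-burst search window.

    The window is half-open; ties in the maximum resolve to the earliest
    grid point, so the result is deterministic on flat curves.
    """
    if window is None:
        window = (cfg or AnalysisConfig()).visual_burst_window
    w0, w1 = window
    mask = (curve.time >= w0) & (curve.time < w1)
    if not mask.any():
        raise SpikeError("visual-burst window lies outside the curve support")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmax(curve.rate[mask]))]
    return BurstMeasure(peak_rate=float(curve.rate[k]), peak_time=float(curve.time[k]))


def split_by_saccade_coincidence(
    trial_ids: Sequence[str],
    stimulus_onsets: Sequence[float],
    saccades: Sequence[Saccade],
    cfg: AnalysisConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Split trials into saccade-free and burst-coincident-saccade sets.

    'No saccade' trials have no microsaccade onset or offset anywhere in
    [-100, 200) ms around stimulus onset.  'With saccade' trials have a
    movement starting or ending inside the visual-burst interval
    (default 30-100 ms after stimulus onset).  Trials matching neither
    criterion belong to neither set.
    """
    cfg = cfg or AnalysisConfig()
    w0, w1 = cfg.visual_burst_window
    by_trial: dict[str, list[Saccade]] = {tid: [] for tid in trial_ids}
    for s in saccades:
        if s.trial_id in by_trial:
            by_trial[s.trial_id].append(s)
    no_sacc: list[str] = []
    with_sacc: list[str] = []
    for tid, onset in zip(trial_ids, stimulus_onsets):
        events = by_trial[tid]
        # any part of a movement inside [-100, 200) disqualifies the trial
        quiet = all(
            not (s.onset_ms - onset < 200.0 and s.offset_ms - onset >= -100.0)
            for s in events)
        coincident = any(
            w0 <= s.onset_ms - onset < w1 or w0 <= s.offset_ms - onset < w1
            for s in events)
        if quiet:
            no_sacc.append(tid)
        elif coincident:
            with_sacc.append(tid)
    return no_sacc, with_sacc


def _two_sided_p(t: float, df: float) -> float:
    # stdtr is the Student-t CDF; two-sided p from the closed-form statistic.
    return float(2.0 * stdtr(df, -abs(t)))


def compare_peak_rates(group_a: Sequence[float], group_b: Sequence[float],
                       paired: bool = True) -> TTestResult:
    """Paired or two-sample (pooled-variance) t-test from closed forms."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SpikeError("need at least two observations per group")
    if paired:
        if a.size != b.size:
            raise SpikeError("paired test requires equal-length groups")
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            if np.all(d == 0):
                return TTestResult(statistic=0.0, p=1.0, df=n - 1,
                                   mean_a=float(a.mean()), mean_b=float(b.mean()))
            raise SpikeError("zero variance of paired differences: t undefined")
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if a.mean() == b.mean():
                return TTestResult(statistic=0.0, p=1.0, df=na + nb - 2,
                                   mean_a=float(a.mean()), mean_b=float(b.mean()))
            raise SpikeError("zero pooled variance: t undefined")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    return TTestResult(statistic=float(t), p=_two_sided_p(t, df), df=float(df),
                       mean_a=float(a.mean()), mean_b=float(b.mean()))
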