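"""Linking peri-saccadic spike counts to microsaccade metrics.

The central statistic is a linear model of movement amplitude on the number
of 'visual' spikes a movement-unrelated neuron fires in the first 0-20 ms of
the movement:

    amplitude = beta0 + beta1 * n_spikes

fit by ordinary least squares to movement-level rows (never to per-level
means), after discarding predictor levels with fewer than 15 movements and
spike counts above five.  Around it sit the temporal and spatial analyses:
amplitude time courses (50 ms running window, 10 ms step), the sliding
2-deg / 1-deg-step eccentricity slope profile, the four-term
spikes x eccentricity interaction model, burst-timing trial sorting with a
Bonferroni-corrected three-consecutive-bin significance criterion, per-
amplitude-bin 5-ms spike-count time courses, and cross-correlation
estimation of the efferent (SC-to-muscle) lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import fdtrc, stdtr

from .config import AnalysisConfig
from .kinematics import Saccade
from .spikes import SpikeTrain, count_spikes


class InteractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spike counting and movement selection

def intra_saccadic_count(s: Saccade, train: SpikeTrain,
                         cfg: AnalysisConfig | None = None) -> int:
    """Spikes in the intra-saccadic window (default 0-20 ms after onset)."""
    w0, w1 = (cfg or AnalysisConfig()).intra_saccadic_window
    return count_spikes(train, s.onset_ms + w0, s.onset_ms + w1)


def select_movements(saccades: Sequence[Saccade],
                     stimulus_onsets: dict[str, float],
                     mode: str,
                     cfg: AnalysisConfig | None = None,
                     first_per_trial: bool | None = None) -> list[Saccade]:
    """Select movements by latency relative to stimulus onset.

    ``post_stimulus``: onset 0-200 ms after stimulus onset (the movements
    entering the amplitude model); by default only the first qualifying
    movement of each trial is kept.
    ``sustained``: onset more than 550 ms after stimulus onset (spiking here
    is sustained discharge, not the visual burst).
    ``baseline``: onset 500-1500 ms before stimulus onset.
    """
    cfg = cfg or AnalysisConfig()
    if mode == "post_stimulus":
        lo, hi = 0.0, 200.0
        if first_per_trial is None:
            first_per_trial = True
    elif mode == "sustained":
        lo, hi = cfg.sustained_min_time, np.inf
        first_per_trial = bool(first_per_trial)
    elif mode == "baseline":
        lo, hi = -1500.0, -500.0
        first_per_trial = bool(first_per_trial)
    else:
        raise InteractionError(f"unknown selection mode: {mode!r}")
    picked: list[Saccade] = []
    seen: set[str] = set()
    for s in sorted(saccades, key=lambda s: (s.trial_id, s.onset_ms)):
        onset = stimulus_onsets.get(s.trial_id)
        if onset is None:
            continue
        rel = s.onset_ms - onset
        if mode == "sustained":
            ok = rel > lo
        else:
            ok = lo <= rel < hi
        if not ok:
            continue
        if first_per_trial and s.trial_id in seen:
            continue
        seen.add(s.trial_id)
        picked.append(s)
    return picked


# ---------------------------------------------------------------------------
# the amplitude model

@dataclass
class AmplitudeModelFit:
    beta0: float
    beta1: float
    se0: float
    se1: float
    t0: float
    t1: float
    p0: float
    p1: float
    F: float
    pF: float
    n_per_level: dict[int, int]
    levels_used: list[int]
    n_obs: int
    se0_robust: float = float("nan")
    se1_robust: float = float("nan")


def filter_levels(n_per_level: dict[int, int],
                  cfg: AnalysisConfig | None = None) -> list[int]:
    """Predictor levels retained for fitting.

    A level survives if it has at least ``min_trials_per_level`` movements
    and does not exceed ``max_spike_level`` spikes (the cutoff that excludes
    spike counts bigger than five under the defaults).
    """
    cfg = cfg or AnalysisConfig()
    return sorted(lvl for lvl, n in n_per_level.items()
                  if n >= cfg.min_trials_per_level and lvl <= cfg.max_spike_level)


def _ols(X: np.ndarray, y: np.ndarray):
    """Normal-equations OLS with classical SEs and the model-vs-constant F."""
    n, k = X.shape
    if n <= k:
        raise InteractionError(f"need more than {k} observations, got {n}")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise InteractionError("rank-deficient design (constant predictor?)")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    rss = float(resid @ resid)
    sigma2 = rss / dof
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    tss = float(((y - y.mean()) ** 2).sum())
    q = k - 1
    if rss <= 0:
        F = np.inf if tss > rss else 0.0
    else:
        F = max((tss - rss) / q, 0.0) / sigma2
    pF = float(fdtrc(q, dof, F)) if np.isfinite(F) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.array([float(2.0 * stdtr(dof, -abs(ti))) if np.isfinite(ti) else 0.0
                  for ti in t])
    # HC1 heteroskedasticity-robust SEs: amplitude scatter grows with the
    # conditional mean, so classical SEs understate the sampling variance
    meat = X.T @ (X * (resid ** 2)[:, None])
    cov_r = XtX_inv @ meat @ XtX_inv * (n / dof)
    se_r = np.sqrt(np.clip(np.diag(cov_r), 0.0, None))
    return beta, se, t, p, float(F), pF, dof, se_r


def fit_amplitude_model(counts: Sequence[int], amplitudes: Sequence[float],
                        cfg: AnalysisConfig | None = None,
                        apply_filter: bool = True) -> AmplitudeModelFit:
    """OLS fit of amplitude on intra-saccadic spike count (movement-level rows)."""
    cfg = cfg or AnalysisConfig()
    x = np.asarray(counts, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InteractionError("counts and amplitudes must be equal-length vectors")
    levels, level_n = np.unique(x.astype(int), return_counts=True)
    n_per_level = {int(l): int(n) for l, n in zip(levels, level_n)}
    if apply_filter:
        keep_levels = filter_levels(n_per_level, cfg)
    else:
        keep_levels = sorted(n_per_level)
    if len(keep_levels) < 2:
        raise InteractionError(
            f"need at least 2 retained predictor levels, got {keep_levels}")
    mask = np.isin(x.astype(int), keep_levels)
    x, y = x[mask], y[mask]
    X = np.column_stack([np.ones_like(x), x])
    beta, se, t, p, F, pF, _, se_r = _ols(X, y)
    return AmplitudeModelFit(
        beta0=float(beta[0]), beta1=float(beta[1]),
        se0=float(se[0]), se1=float(se[1]),
        t0=float(t[0]), t1=float(t[1]), p0=float(p[0]), p1=float(p[1]),
        F=F, pF=pF, n_per_level=n_per_level, levels_used=keep_levels,
        n_obs=int(x.size), se0_robust=float(se_r[0]), se1_robust=float(se_r[1]))


@dataclass
class InteractionModelFit:
    """amp ~ 1 + n + ecc + n*ecc; ``beta`` ordered as that design."""
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_obs: int
    se_robust: np.ndarray

    @property
    def interaction(self) -> float:
        return float(self.beta[3])

    @property
    def interaction_se(self) -> float:
        return float(self.se[3])

    @property
    def interaction_se_robust(self) -> float:
        return float(self.se_robust[3])


def fit_interaction_model(counts: Sequence[int], eccentricities: Sequence[float],
                          amplitudes: Sequence[float]) -> InteractionModelFit:
    """Four-term OLS: amplitude on spikes, eccentricity, and their product."""
    n = np.asarray(counts, dtype=float)
    e = np.asarray(eccentricities, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if not (n.shape == e.shape == y.shape):
        raise InteractionError("counts, eccentricities, amplitudes must align")
    X = np.column_stack([np.ones_like(n), n, e, n * e])
    beta, se, t, p, _F, _pF, _dof, se_r = _ols(X, y)
    return InteractionModelFit(beta=beta, se=se, t=t, p=p, n_obs=int(y.size),
                               se_robust=se_r)


# ---------------------------------------------------------------------------
# eccentricity profile

@dataclass
class EccentricitySlopeProfile:
    centers: np.ndarray
    slopes: np.ndarray       # NaN where undefined
    slope_sems: np.ndarray
    n_neurons: np.ndarray
    n_movements: np.ndarray


def eccentricity_slope_profile(
    neuron_eccentricities: dict[str, float],
    movement_neuron_ids: Sequence[str],
    counts: Sequence[int],
    amplitudes: Sequence[float],
    cfg: AnalysisConfig | None = None,
    window_width: float = 2.0,
    step: float = 1.0,
    start_center: float = 1.0,
) -> EccentricitySlopeProfile:
    """Amplitude-model slope in a 2-deg eccentricity window slid in 1-deg steps.

    Window membership is inclusive on both edges, so a neuron exactly at a
    window boundary contributes to both adjacent windows.
    """
    cfg = cfg or AnalysisConfig()
    nid = np.asarray(movement_neuron_ids)
    cnt = np.asarray(counts, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    eccs = np.array([neuron_eccentricities[i] for i in nid])
    if len(neuron_eccentricities) == 0:
        raise InteractionError("need at least one neuron")
    max_ecc = max(neuron_eccentricities.values())
    centers = np.arange(start_center, max_ecc + window_width / 2 + step / 2, step)
    half = window_width / 2.0
    slopes = np.full(centers.size, np.nan)
    sems = np.full(centers.size, np.nan)
    n_neu = np.zeros(centers.size, dtype=int)
    n_mov = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        in_win = {k for k, v in neuron_eccentricities.items()
                  if c - half <= v <= c + half}
        n_neu[i] = len(in_win)
        if not in_win:
            continue
        mask = np.isin(nid, sorted(in_win))
        n_mov[i] = int(mask.sum())
        try:
            fit = fit_amplitude_model(cnt[mask].astype(int), amp[mask], cfg)
        except InteractionError:
            continue
        slopes[i] = fit.beta1
        sems[i] = fit.se1
    return EccentricitySlopeProfile(centers=centers, slopes=slopes,
                                    slope_sems=sems, n_neurons=n_neu,
                                    n_movements=n_mov)


# ---------------------------------------------------------------------------
# time courses

def amplitude_timecourse(onset_times_rel_stim: Sequence[float],
                         amplitudes: Sequence[float],
                         cfg: AnalysisConfig | None = None,
                         span: tuple[float, float] = (-100.0, 150.0)):
    """Running mean of movement amplitude versus onset time from stimulus.

    Windows of ``timecourse_window`` ms (default 50) are stepped by
    ``timecourse_step`` ms (default 10); each grid point is the mean
    amplitude of movements whose onsets fall in the half-open window centred
    there.  Empty windows yield NaN.  Returns (centers, mean, sem, n).
    """
    cfg = cfg or AnalysisConfig()
    t = np.asarray(onset_times_rel_stim, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.size == 0:
        raise InteractionError("need at least one movement")
    centers = np.arange(span[0], span[1] + cfg.timecourse_step / 2, cfg.timecourse_step)
    half = cfg.timecourse_window / 2.0
    mean = np.full(centers.size, np.nan)
    sem = np.full(centers.size, np.nan)
    n = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        mask = (t >= c - half) & (t < c + half)
        n[i] = int(mask.sum())
        if n[i]:
            vals = a[mask]
            mean[i] = vals.mean()
            sem[i] = vals.std(ddof=1) / np.sqrt(n[i]) if n[i] > 1 else 0.0
    return centers, mean, sem, n


def moving_average(values: Sequence[float], width: int = 20, step: int = 1) -> np.ndarray:
    """Plain moving average over sorted trials (display smoothing only)."""
    v = np.asarray(values, dtype=float)
    if v.size < width:
        return np.array([])
    starts = np.arange(0, v.size - width + 1, step)
    return np.array([v[s:s + width].mean() for s in starts])


# ---------------------------------------------------------------------------
# burst-timing sort

@dataclass
class TimingSortResult:
    order: np.ndarray          # permutation sorting burst-minus-onset ascending
    bin_means: np.ndarray      # mean amplitude per bin of sort_bin_size trials
    bin_times: np.ndarray      # mean burst-minus-onset time per bin (ms)
    significant: np.ndarray    # per-bin Bonferroni-corrected test vs bin 1
    start_bin: int | None      # first bin of a 3-consecutive significant run
    end_bin: int | None        # first bin after start opening a 3-bin quiet run


def sort_and_test_timing(burst_minus_onset: Sequence[float],
                         amplitudes: Sequence[float],
                         cfg: AnalysisConfig | None = None) -> TimingSortResult:
    """Sort trials by burst-peak time relative to movement onset and locate
    the bins where amplitude departs from, then returns to, baseline.

    Trials are sorted ascending, cut into consecutive bins of
    ``sort_bin_size`` trials (a trailing partial bin is dropped), and each
    bin's amplitudes are compared with the first (baseline) bin by a pooled-
    variance two-sample t-test at a Bonferroni-adjusted alpha.  The onset of
    the effect is the first bin opening a run of ``consecutive_bins``
    significant bins; the offset is the first bin after it opening an
    equally long non-significant run.
    """
    cfg = cfg or AnalysisConfig()
    key = np.asarray(burst_minus_onset, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if key.shape != amp.shape:
        raise InteractionError("timing keys and amplitudes must align")
    if key.size < 2 * cfg.sort_bin_size:
        raise InteractionError(
            f"need at least {2 * cfg.sort_bin_size} trials, got {key.size}")
    order = np.argsort(key, kind="stable")
    amp_sorted = amp[order]
    key_sorted = key[order]
    n_bins = key.size // cfg.sort_bin_size
    bins = [amp_sorted[i * cfg.sort_bin_size:(i + 1) * cfg.sort_bin_size]
            for i in range(n_bins)]
    times = np.array([key_sorted[i * cfg.sort_bin_size:(i + 1) * cfg.sort_bin_size].mean()
                      for i in range(n_bins)])
    means = np.array([b.mean() for b in bins])
    alpha = cfg.alpha / (n_bins - 1) if cfg.bonferroni else cfg.alpha
    sig = np.zeros(n_bins, dtype=bool)
    base = bins[0]
    from .spikes import compare_peak_rates
    for i in range(1, n_bins):
        res = compare_peak_rates(bins[i], base, paired=False)
        sig[i] = res.p < alpha

    def _first_run(flags: np.ndarray, value: bool, begin: int) -> int | None:
        run = 0
        for i in range(begin, flags.size):
            run = run + 1 if flags[i] == value else 0
            if run == cfg.consecutive_bins:
                return i - cfg.consecutive_bins + 1
        return None

    start = _first_run(sig, True, 1)
    end = _first_run(sig, False, start + cfg.consecutive_bins) if start is not None else None
    return TimingSortResult(order=order, bin_means=means, bin_times=times,
                            significant=sig, start_bin=start, end_bin=end)


# ---------------------------------------------------------------------------
# spike time course by amplitude bin

@dataclass
class SpikeTimecourseByAmplitude:
    amplitude_edges: np.ndarray   # deg, 0.1-wide bins
    time_edges: np.ndarray        # ms, 5-ms bins around movement onset
    mean_count: np.ndarray        # (n_amp_bins, n_time_bins)
    n_movements: np.ndarray       # per amplitude bin
    counts: list                  # per amp bin: (n_movements, n_time_bins) array


def spike_timecourse_by_amplitude(saccades: Sequence[Saccade],
                                  trains: Sequence[SpikeTrain],
                                  cfg: AnalysisConfig | None = None,
                                  amplitude_edges: Sequence[float] | None = None
                                  ) -> SpikeTimecourseByAmplitude:
    """Mean spike count in 5-ms bins around movement onset, per amplitude bin.

    Movements are grouped into 0.1-deg amplitude bins from 0.1 to 0.8 deg
    (movements below 0.1 deg are excluded); for each movement the paired
    train is binned at 5 ms over (-100, +100) ms around its onset.
    """
    cfg = cfg or AnalysisConfig()
    if amplitude_edges is None:
        amplitude_edges = np.arange(0.1, 0.8 + 1e-9, 0.1)
    amplitude_edges = np.asarray(amplitude_edges, dtype=float)
    t0, t1 = cfg.spike_bin_range
    time_edges = np.arange(t0, t1 + cfg.spike_bin / 2, cfg.spike_bin)
    n_amp = amplitude_edges.size - 1
    per_bin: list[list[np.ndarray]] = [[] for _ in range(n_amp)]
    for s, tr in zip(saccades, trains):
        k = int(np.searchsorted(amplitude_edges, s.amplitude, side="right")) - 1
        if not 0 <= k < n_amp:
            continue
        rel = tr.times - s.onset_ms
        hist, _ = np.histogram(rel, bins=time_edges)
        per_bin[k].append(hist.astype(float))
    mean = np.zeros((n_amp, time_edges.size - 1))
    n_mov = np.zeros(n_amp, dtype=int)
    stacked = []
    for k, rows in enumerate(per_bin):
        n_mov[k] = len(rows)
        arr = np.array(rows) if rows else np.empty((0, time_edges.size - 1))
        stacked.append(arr)
        if rows:
            mean[k] = arr.mean(axis=0)
    return SpikeTimecourseByAmplitude(amplitude_edges=amplitude_edges,
                                      time_edges=time_edges, mean_count=mean,
                                      n_movements=n_mov, counts=stacked)


def influence_window_halfwidth(tc: SpikeTimecourseByAmplitude,
                               baseline_bins: Sequence[int] = (0, 1),
                               alpha: float = 0.01) -> float:
    """Outermost 5-ms bin edge (ms) with significantly elevated spike counts.

    For each time bin, pooled counts from enlarged-amplitude movements (all
    amplitude bins above the baseline ones) are compared with the baseline-
    amplitude movements (default the 0.1-0.2 and 0.2-0.3 deg bins) by a one-
    sided two-sample t-test at ``alpha``.  The half-width is the largest
    absolute edge of the contiguous run of significant bins containing
    movement onset.
    """
    from .spikes import compare_peak_rates
    base_rows = np.vstack([tc.counts[i] for i in baseline_bins
                           if tc.counts[i].shape[0] > 0])
    enl_idx = [i for i in range(len(tc.counts)) if i not in set(baseline_bins)]
    enl_rows = np.vstack([tc.counts[i] for i in enl_idx
                          if tc.counts[i].shape[0] > 0])
    if base_rows.shape[0] < 2 or enl_rows.shape[0] < 2:
        raise InteractionError("need movements in both baseline and enlarged bins")
    nt = tc.time_edges.size - 1
    sig = np.zeros(nt, dtype=bool)
    for j in range(nt):
        try:
            res = compare_peak_rates(enl_rows[:, j], base_rows[:, j], paired=False)
        except Exception:
            continue
        sig[j] = res.statistic > 0 and res.p / 2 < alpha
    centers = (tc.time_edges[:-1] + tc.time_edges[1:]) / 2.0
    j0 = int(np.argmin(np.abs(centers)))
    if not sig[j0]:
        cand = np.flatnonzero(sig)
        if cand.size == 0:
            return 0.0
        j0 = int(cand[np.argmin(np.abs(centers[cand]))])
    lo = j0
    while lo > 0 and sig[lo - 1]:
        lo -= 1
    hi = j0
    while hi < nt - 1 and sig[hi + 1]:
        hi += 1
    return float(max(abs(tc.time_edges[lo]), abs(tc.time_edges[hi + 1])))


# ---------------------------------------------------------------------------
# efferent lag

def estimate_efferent_lag(behavior_time: Sequence[float],
                          behavior: Sequence[float],
                          rate_time: Sequence[float],
                          rate: Sequence[float],
                          max_lag_ms: float = 100.0,
                          grid_ms: float = 1.0) -> float:
    """Lag (ms) of the behavioral curve behind the firing-rate curve.

    Both curves are linearly interpolated onto a common 1-ms grid over their
    overlapping support, mean-subtracted, and cross-correlated using full
    overlap only; the returned lag maximizes the correlation over
    [0, max_lag_ms], positive meaning behavior follows the burst.
    """
    bt = np.asarray(behavior_time, dtype=float)
    bv = np.asarray(behavior, dtype=float)
    rt = np.asarray(rate_time, dtype=float)
    rv = np.asarray(rate, dtype=float)
    ok_b = np.isfinite(bv)
    bt, bv = bt[ok_b], bv[ok_b]
    lo = max(bt.min(), rt.min())
    hi = min(bt.max(), rt.max())
    if hi <= lo:
        raise InteractionError("curves do not overlap in time")
    grid = np.arange(lo, hi + grid_ms / 2, grid_ms)
    b = np.interp(grid, bt, bv)
    r = np.interp(grid, rt, rv)
    b = b - b.mean()
    r = r - r.mean()
    lags = np.arange(0, int(max_lag_ms / grid_ms) + 1)
    best_lag, best_c = 0, -np.inf
    for lag in lags:
        if lag >= grid.size - 2:
            break
        bb = b[lag:]
        rr = r[:grid.size - lag]
        bb = bb - bb.mean()
        rr = rr - rr.mean()
        denom = np.sqrt((bb @ bb) * (rr @ rr))
        c = (bb @ rr) / denom if denom > 0 else -np.inf
        if c > best_c:
            best_c, best_lag = c, lag
    return float(best_lag * grid_ms)
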