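"""Movement-field construction, 2-D Gaussian ROI selection, and the
population-level comparisons of rostral/caudal activity.

Movement fields are built on log-polar axes: radial amplitude is mapped to
log(amplitude / 0.03) with the 0.03-deg origin offset, direction stays in
degrees.  A rotated 2-D Gaussian with a non-negative additive baseline is
fit to the per-cell peak peri-movement rates; microsaccades within a chosen
Mahalanobis radius (2 s.d. by default) of the fitted peak form the
'preferred' movement set used for per-neuron normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinematics import Saccade
from .spikes import SpikeTrain, TTestResult, compare_peak_rates

ORIGIN_OFFSET_DEG = 0.03


class RFError(ValueError):
    pass


def to_logpolar(amplitude_deg, direction_deg):
    """Map (amplitude, direction) to the (log-eccentricity, direction) plane."""
    amp = np.asarray(amplitude_deg, dtype=float)
    return np.log(np.maximum(amp, 1e-6) / ORIGIN_OFFSET_DEG), np.asarray(direction_deg, dtype=float)


@dataclass
class MovementRFMap:
    logecc_edges: np.ndarray
    direction_edges: np.ndarray     # deg, covering [0, 360]
    rate: np.ndarray                # (n_logecc, n_dir) mean peri-movement rate, sp/s
    counts: np.ndarray              # movements per cell


@dataclass
class Gaussian2DFit:
    mean: tuple[float, float]       # (log-ecc, direction deg)
    sd: tuple[float, float]
    orientation: float              # radians, rotation of the first axis
    peak_rate: float
    baseline: float
    converged: bool
    degenerate: bool = False


def peri_movement_rate(s: Saccade, train: SpikeTrain, halfwidth_ms: float = 15.0) -> float:
    """Mean firing rate (sp/s) within +/-halfwidth of movement onset."""
    t = train.times
    n = int(np.searchsorted(t, s.onset_ms + halfwidth_ms, side="left")
            - np.searchsorted(t, s.onset_ms - halfwidth_ms, side="left"))
    return n / (2.0 * halfwidth_ms / 1000.0)


def build_movement_rf(saccades: Sequence[Saccade], trains: Sequence[SpikeTrain],
                      halfwidth_ms: float = 15.0,
                      n_logecc: int = 12, n_dir: int = 18) -> MovementRFMap:
    """Mean peri-movement firing rate on a (log-eccentricity, direction) grid."""
    saccades = list(saccades)
    if not saccades or len(saccades) != len(trains):
        raise RFError("need paired saccades and spike trains")
    le, dirs = to_logpolar([s.amplitude for s in saccades],
                           [s.direction for s in saccades])
    le_edges = np.linspace(le.min() - 1e-9, le.max() + 1e-9, n_logecc + 1)
    dir_edges = np.linspace(0.0, 360.0, n_dir + 1)
    rates = np.array([peri_movement_rate(s, tr, halfwidth_ms)
                      for s, tr in zip(saccades, trains)])
    i = np.clip(np.searchsorted(le_edges, le, side="right") - 1, 0, n_logecc - 1)
    j = np.clip(np.searchsorted(dir_edges, dirs, side="right") - 1, 0, n_dir - 1)
    rate_sum = np.zeros((n_logecc, n_dir))
    counts = np.zeros((n_logecc, n_dir), dtype=int)
    np.add.at(rate_sum, (i, j), rates)
    np.add.at(counts, (i, j), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, rate_sum / np.maximum(counts, 1), 0.0)
    return MovementRFMap(logecc_edges=le_edges, direction_edges=dir_edges,
                         rate=mean, counts=counts)


def _gauss2d(params, le, dr):
    x0, y0, sx, sy, theta, amp, base = params
    ct, st = math.cos(theta), math.sin(theta)
    u = (le - x0) * ct + (dr - y0) * st
    v = -(le - x0) * st + (dr - y0) * ct
    return base + amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def fit_rf_gaussian(rf: MovementRFMap, min_cells: int = 6) -> Gaussian2DFit:
    """Least-squares rotated 2-D Gaussian fit to the occupied map cells.

    Direction is unwrapped locally around the map peak so the circular axis
    behaves like a plane near the hotspot.  Flat maps are flagged degenerate
    rather than fit.
    """
    le_c = (rf.logecc_edges[:-1] + rf.logecc_edges[1:]) / 2.0
    dr_c = (rf.direction_edges[:-1] + rf.direction_edges[1:]) / 2.0
    LE, DR = np.meshgrid(le_c, dr_c, indexing="ij")
    occ = rf.counts > 0
    if occ.sum() < min_cells:
        raise RFError(f"need at least {min_cells} occupied cells, got {int(occ.sum())}")
    z = rf.rate[occ]
    if np.ptp(z) <= 1e-12:
        return Gaussian2DFit(mean=(float(LE[occ].mean()), float(DR[occ].mean())),
                             sd=(1.0, 1.0), orientation=0.0,
                             peak_rate=float(z.mean()), baseline=float(z.mean()),
                             converged=False, degenerate=True)
    ipk = np.unravel_index(int(np.argmax(np.where(occ, rf.rate, -np.inf))), rf.rate.shape)
    peak_dir = DR[ipk]
    # unwrap direction to within +/-180 of the peak
    dr_unw = (DR - peak_dir + 180.0) % 360.0 - 180.0 + peak_dir
    le_o = LE[occ]
    dr_o = dr_unw[occ]
    span_le = max(np.ptp(le_o), 0.1)
    span_dr = max(np.ptp(dr_o), 10.0)
    p0 = [float(LE[ipk]), float(peak_dir), span_le / 4, span_dr / 4, 0.0,
          float(z.max() - z.min()), float(max(z.min(), 0.0))]
    lb = [le_o.min() - span_le, peak_dir - 180.0, 1e-3, 1e-1, -math.pi / 2, 1e-9, 0.0]
    ub = [le_o.max() + span_le, peak_dir + 180.0, 5 * span_le, 5 * span_dr,
          math.pi / 2, 10 * float(z.max()) + 1e-9, float(z.max()) + 1e-9]
    res = least_squares(lambda p: _gauss2d(p, le_o, dr_o) - z, p0,
                        bounds=(lb, ub), max_nfev=5000)
    x0, y0, sx, sy, theta, amp, base = res.x
    return Gaussian2DFit(mean=(float(x0), float(y0) % 360.0),
                         sd=(float(sx), float(sy)), orientation=float(theta),
                         peak_rate=float(base + amp), baseline=float(base),
                         converged=bool(res.success))


def mahalanobis(fit: Gaussian2DFit, logecc, direction_deg) -> np.ndarray:
    """Mahalanobis distance of log-polar points from the fitted RF peak."""
    le = np.asarray(logecc, dtype=float)
    # measure the angular offset on the circle
    dd = (np.asarray(direction_deg, dtype=float) - fit.mean[1] + 180.0) % 360.0 - 180.0
    ct, st = math.cos(fit.orientation), math.sin(fit.orientation)
    u = (le - fit.mean[0]) * ct + dd * st
    v = -(le - fit.mean[0]) * st + dd * ct
    return np.sqrt((u / fit.sd[0]) ** 2 + (v / fit.sd[1]) ** 2)


def select_roi_movements(saccades: Sequence[Saccade], fit: Gaussian2DFit,
                         k: float = 2.0) -> list[Saccade]:
    """Movements within ``k`` s.d. (Mahalanobis) of the fitted RF peak."""
    if fit.degenerate:
        raise RFError("cannot select an ROI from a degenerate fit")
    saccades = list(saccades)
    le, dr = to_logpolar([s.amplitude for s in saccades],
                         [s.direction for s in saccades])
    d = mahalanobis(fit, le, dr)
    return [s for s, di in zip(saccades, d) if di <= k]


@dataclass
class PopulationCurve:
    time: np.ndarray
    mean: np.ndarray      # dimensionless; 1 = a neuron's own reference peak
    sem: np.ndarray
    n_neurons: int


def population_average(time: Sequence[float],
                       neuron_curves: Sequence[Sequence[float]],
                       reference_peaks: Sequence[float]) -> PopulationCurve:
    """Average across neurons after dividing each by its own reference peak.

    The same divisor must be used for all of a neuron's conditions; callers
    pass that one reference peak per neuron here for each condition's curves.
    """
    curves = np.asarray(neuron_curves, dtype=float)
    refs = np.asarray(reference_peaks, dtype=float)
    if curves.ndim != 2 or curves.shape[0] != refs.size:
        raise RFError("need one reference peak per neuron curve")
    if np.any(refs <= 0):
        raise RFError("reference peaks must be positive")
    normed = curves / refs[:, None]
    n = curves.shape[0]
    sem = (normed.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros(curves.shape[1])
    return PopulationCurve(time=np.asarray(time, dtype=float),
                           mean=normed.mean(axis=0), sem=sem, n_neurons=n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact for small n) and the paired comparisons

@dataclass
class WilcoxonResult:
    statistic: float   # W+ : sum of ranks of positive differences
    p: float
    n: int             # nonzero differences used
    exact: bool


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(absd.size)
    sorted_abs = absd[order]
    i = 0
    r = 1
    while i < sorted_abs.size:
        j = i
        while j + 1 < sorted_abs.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        avg = (r + (r + j - i)) / 2.0
        ranks[order[i:j + 1]] = avg
        r += j - i + 1
        i = j + 1
    return ranks


def _exact_wplus_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by dynamic programming over the 2^n sign flips.

    Ranks are doubled to integers so midranks from ties stay exact.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # distribution of 2*W+ over all sign assignments
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[:total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    lo = dist[:min(w2, total - w2) + 1].sum()
    hi = dist[max(w2, total - w2):].sum()
    return float(min(1.0, lo + hi))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         exact_max_n: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on (a, b) pairs.

    Zero differences are discarded; ties get midranks.  The null
    distribution is exact (sign-flip enumeration via DP) for up to
    ``exact_max_n`` nonzero pairs, and a tie-corrected normal approximation
    beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise RFError("paired test requires equal-length inputs")
    if a.size < 2:
        raise RFError("need at least two pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise RFError("all differences are zero: test degenerate")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_wplus_p(ranks, w_plus)
        return WilcoxonResult(statistic=w_plus, p=p, n=n, exact=True)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu) / sigma
    p = float(2.0 * 0.5 * math.erfc(abs(z) / math.sqrt(2.0)))
    return WilcoxonResult(statistic=w_plus, p=min(1.0, p), n=n, exact=False)


def paired_burst_comparison(baseline_rates: Sequence[float],
                            coincident_rates: Sequence[float],
                            method: str = "signed_rank") -> WilcoxonResult | TTestResult:
    """Per-neuron paired comparison of baseline vs burst-coincident rates.

    ``signed_rank`` (default) is the paired member of the rank-test family;
    ``rank_sum`` applies a Mann-Whitney/rank-sum on the two samples for
    callers reading 'paired ranksum' the other way.
    """
    a = np.asarray(baseline_rates, dtype=float)
    b = np.asarray(coincident_rates, dtype=float)
    if a.size < 5 or b.size < 5:
        raise RFError("need at least five neurons per condition")
    if method == "signed_rank":
        return wilcoxon_signed_rank(b, a)
    if method == "rank_sum":
        return _rank_sum(b, a)
    raise RFError(f"unknown method: {method!r}")


def _rank_sum(a: np.ndarray, b: np.ndarray) -> WilcoxonResult:
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    rr = np.empty(pooled.size)
    sp = pooled[order]
    i, r = 0, 1
    while i < sp.size:
        j = i
        while j + 1 < sp.size and sp[j + 1] == sp[i]:
            j += 1
        rr[order[i:j + 1]] = (r + r + j - i) / 2.0
        r += j - i + 1
        i = j + 1
    n1, n2 = a.size, b.size
    w = rr[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - mu) / sigma
    p = float(math.erfc(abs(z) / math.sqrt(2.0)))
    return WilcoxonResult(statistic=float(w), p=min(1.0, p), n=n1 + n2, exact=False)


def amplitude_group_comparison(coincident_amps: Sequence[float],
                               baseline_amps: Sequence[float]) -> TTestResult:
    """Two-sample t-test of burst-coincident vs baseline movement amplitudes.

    Callers are expected to have applied the +/-25 deg stimulus-congruence
    direction filter upstream.
    """
    a = np.asarray(coincident_amps, dtype=float)
    b = np.asarray(baseline_amps, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RFError("both amplitude groups must be nonempty")
    return compare_peak_rates(a, b, paired=False)


def congruent_with_stimulus(direction_deg: float, stimulus_direction_deg: float,
                            halfwidth: float = 25.0) -> bool:
    """Direction filter for the amplitude comparison (within +/-25 deg)."""
    d = (direction_deg - stimulus_direction_deg) % 360.0
    return min(d, 360.0 - d) <= halfwidth
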