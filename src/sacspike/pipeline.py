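"""Stage-chaining helpers: from a session bundle to movement-level rows.

A trial's 'coupling' neuron is the caudal neuron whose spikes were recorded
on that trial (sessions record one analyzed caudal neuron per trial; trials
with no caudal spikes at all — which essentially never happens at realistic
baseline rates — are skipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .interaction import fit_amplitude_model, intra_saccadic_count, select_movements
from .io import SessionBundle, Site
from .kinematics import DetectParams, DirectionClass, classify_direction, detect_saccades


def detect_all(bundle: SessionBundle, params: DetectParams | None = None):
    """Detected saccades for every trial, tagged with trial ids."""
    out = []
    for t in bundle.trials:
        out.extend(detect_saccades(t.eye, params, trial_id=t.trial_id))
    return out


def amplitude_dataset(bundle: SessionBundle,
                      cfg: AnalysisConfig | None = None,
                      mode: str = "post_stimulus",
                      detect_params: DetectParams | None = None,
                      first_per_trial: bool | None = None) -> pd.DataFrame:
    """Movement-level rows for the amplitude model.

    Runs detection on every trial, selects movements by latency mode,
    classifies them toward/opposite the trial neuron's RF, and counts that
    neuron's spikes in the intra-saccadic window.  Columns: trial_id,
    neuron_id, eccentricity, onset_rel_stim_ms, amplitude, direction_deg,
    toward, count.
    """
    cfg = cfg or AnalysisConfig()
    caudal = {n.neuron_id: n for n in bundle.neurons if n.site is Site.CAUDAL}
    saccades = detect_all(bundle, detect_params)
    stim = {t.trial_id: t.stimulus_onset_ms for t in bundle.trials}
    selected = select_movements(saccades, stim, mode, cfg,
                                first_per_trial=first_per_trial)
    trial_by_id = {t.trial_id: t for t in bundle.trials}
    rows = []
    for s in selected:
        trial = trial_by_id[s.trial_id]
        nids = [nid for nid in trial.spikes if nid in caudal]
        if len(nids) != 1:
            continue
        neuron = caudal[nids[0]]
        cls = classify_direction(s, neuron.rf_direction, cfg.toward_halfwidth)
        rows.append({
            "trial_id": s.trial_id,
            "neuron_id": neuron.neuron_id,
            "eccentricity": neuron.rf_eccentricity,
            "onset_rel_stim_ms": s.onset_ms - trial.stimulus_onset_ms,
            "amplitude": s.amplitude,
            "direction_deg": s.direction,
            "toward": cls is DirectionClass.TOWARD,
            "count": intra_saccadic_count(s, trial.train(neuron.neuron_id), cfg),
        })
    return pd.DataFrame(rows, columns=["trial_id", "neuron_id", "eccentricity",
                                       "onset_rel_stim_ms", "amplitude",
                                       "direction_deg", "toward", "count"])


@dataclass
class PipelineFitSummary:
    fit: object
    n_movements: int
    data: pd.DataFrame


def fit_toward_amplitude_model(data: pd.DataFrame,
                               cfg: AnalysisConfig | None = None,
                               toward: bool = True) -> PipelineFitSummary:
    """Fit the amplitude model to the toward (or opposite) movement rows."""
    cfg = cfg or AnalysisConfig()
    sub = data[data["toward"] == toward]
    fit = fit_amplitude_model(sub["count"].to_numpy(dtype=int),
                              sub["amplitude"].to_numpy(), cfg)
    return PipelineFitSummary(fit=fit, n_movements=len(sub), data=sub)
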