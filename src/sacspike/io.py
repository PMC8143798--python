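"""Session container and the plain-text on-disk layout.

A session lives in one directory of delimited text files:

* ``session.json``    — session_id and sampling_rate (Hz)
* ``trials.csv``      — trial_id, stimulus_onset_ms, condition, condition_value
* ``neurons.csv``     — neuron_id, cls, site, rf_ecc_deg, rf_dir_deg
* ``spikes.csv``      — long format: trial_id, neuron_id, time_ms
* ``eye_<trial>.csv`` — time_ms, x_deg, y_deg, one file per trial

All times are milliseconds relative to trial start; numeric text carries at
least nine significant digits so a write/read/write cycle is byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .kinematics import EyeTrace
from .spikes import SpikeTrain

_FLOAT_FMT = "%.17g"  # full float precision: read(write(b)) == b exactly


class SessionLoadError(IOError):
    """A required file is missing or unreadable."""


class SessionValidationError(ValueError):
    """Cross-references or invariants of a session are violated."""


class NeuronClass(Enum):
    VISUAL = "visual"
    VISUAL_MOTOR = "visual_motor"
    ROSTRAL_MOTOR = "rostral_motor"


class Site(Enum):
    ROSTRAL = "rostral"
    CAUDAL = "caudal"


@dataclass
class NeuronMeta:
    neuron_id: str
    cls: NeuronClass
    site: Site
    rf_eccentricity: float  # deg; RF hotspot eccentricity
    rf_direction: float     # deg in [0, 360)

    def __post_init__(self) -> None:
        if isinstance(self.cls, str):
            self.cls = NeuronClass(self.cls)
        if isinstance(self.site, str):
            self.site = Site(self.site)
        if not 0.0 <= self.rf_direction < 360.0:
            raise SessionValidationError(
                f"neuron {self.neuron_id}: rf_direction must lie in [0, 360)")
        if self.site is Site.CAUDAL and not (np.isfinite(self.rf_eccentricity)
                                             and self.rf_eccentricity > 0):
            raise SessionValidationError(
                f"neuron {self.neuron_id}: caudal neurons need a positive "
                f"finite rf_eccentricity")


@dataclass
class Trial:
    trial_id: str
    stimulus_onset_ms: float
    condition: str
    condition_value: float
    eye: EyeTrace
    spikes: dict[str, SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # a neuron with no spikes on a trial is represented by absence, so the
        # long-format spike table round-trips exactly
        self.spikes = {nid: tr for nid, tr in self.spikes.items() if tr.times.size}

    def train(self, neuron_id: str) -> SpikeTrain:
        """Spike train of one neuron on this trial (empty if it fired none)."""
        got = self.spikes.get(neuron_id)
        if got is not None:
            return got
        return SpikeTrain(trial_id=self.trial_id, neuron_id=neuron_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trial):
            return NotImplemented
        return (self.trial_id == other.trial_id
                and self.stimulus_onset_ms == other.stimulus_onset_ms
                and self.condition == other.condition
                and self.condition_value == other.condition_value
                and self.eye == other.eye
                and self.spikes == other.spikes)


@dataclass
class SessionBundle:
    session_id: str
    trials: list[Trial]
    neurons: list[NeuronMeta]
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise SessionValidationError("sampling_rate must be positive")
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SessionValidationError(f"duplicate trial ids: {dupes}")
        known = {n.neuron_id for n in self.neurons}
        bad = sorted({nid for t in self.trials for nid in t.spikes if nid not in known})
        if bad:
            raise SessionValidationError(
                f"trials reference unknown neuron ids: {bad}")

    def neuron(self, neuron_id: str) -> NeuronMeta:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (self.session_id == other.session_id
                and self.sampling_rate == other.sampling_rate
                and self.neurons == other.neurons
                and self.trials == other.trials)


def write_session(bundle: SessionBundle, path: Union[str, Path]) -> None:
    """Serialize a bundle into the documented directory layout."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "session.json").write_text(json.dumps(
        {"session_id": bundle.session_id, "sampling_rate": bundle.sampling_rate},
        indent=1, sort_keys=True) + "\n")
    pd.DataFrame(
        [{"trial_id": t.trial_id, "stimulus_onset_ms": t.stimulus_onset_ms,
          "condition": t.condition, "condition_value": t.condition_value}
         for t in bundle.trials],
        columns=["trial_id", "stimulus_onset_ms", "condition", "condition_value"],
    ).to_csv(root / "trials.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [{"neuron_id": n.neuron_id, "cls": n.cls.value, "site": n.site.value,
          "rf_ecc_deg": n.rf_eccentricity, "rf_dir_deg": n.rf_direction}
         for n in bundle.neurons],
        columns=["neuron_id", "cls", "site", "rf_ecc_deg", "rf_dir_deg"],
    ).to_csv(root / "neurons.csv", index=False, float_format=_FLOAT_FMT)
    rows = []
    for t in bundle.trials:
        for nid in sorted(t.spikes):
            for tm in t.spikes[nid].times:
                rows.append((t.trial_id, nid, tm))
    pd.DataFrame(rows, columns=["trial_id", "neuron_id", "time_ms"]).to_csv(
        root / "spikes.csv", index=False, float_format=_FLOAT_FMT)
    for t in bundle.trials:
        pd.DataFrame({"time_ms": t.eye.time, "x_deg": t.eye.x, "y_deg": t.eye.y}
                     ).to_csv(root / f"eye_{t.trial_id}.csv", index=False,
                              float_format=_FLOAT_FMT)


def _require(root: Path, name: str) -> Path:
    p = root / name
    if not p.exists():
        raise SessionLoadError(f"missing session file: {p}")
    return p


def read_session(path: Union[str, Path]) -> SessionBundle:
    """Load and validate a session directory written by :func:`write_session`."""
    root = Path(path)
    if not root.is_dir():
        raise SessionLoadError(f"not a session directory: {root}")
    meta = json.loads(_require(root, "session.json").read_text())
    # round_trip parsing: read(write(b)) must reproduce floats bit-exactly
    trials_df = pd.read_csv(_require(root, "trials.csv"), dtype={"trial_id": str},
                            float_precision="round_trip")
    neurons_df = pd.read_csv(_require(root, "neurons.csv"), dtype={"neuron_id": str},
                             float_precision="round_trip")
    spikes_df = pd.read_csv(_require(root, "spikes.csv"),
                            dtype={"trial_id": str, "neuron_id": str},
                            float_precision="round_trip")

    neurons = [NeuronMeta(neuron_id=r.neuron_id, cls=r.cls, site=r.site,
                          rf_eccentricity=float(r.rf_ecc_deg),
                          rf_direction=float(r.rf_dir_deg))
               for r in neurons_df.itertuples()]

    spike_groups: dict[tuple[str, str], np.ndarray] = {}
    if len(spikes_df):
        for (tid, nid), g in spikes_df.groupby(["trial_id", "neuron_id"], sort=False):
            spike_groups[(tid, nid)] = g["time_ms"].to_numpy(dtype=float)

    trials: list[Trial] = []
    for r in trials_df.itertuples():
        eye_df = pd.read_csv(_require(root, f"eye_{r.trial_id}.csv"),
                             float_precision="round_trip")
        eye = EyeTrace(time=eye_df["time_ms"].to_numpy(),
                       x=eye_df["x_deg"].to_numpy(),
                       y=eye_df["y_deg"].to_numpy())
        spikes = {nid: SpikeTrain(trial_id=tid, neuron_id=nid, times=times)
                  for (tid, nid), times in spike_groups.items() if tid == r.trial_id}
        trials.append(Trial(trial_id=r.trial_id,
                            stimulus_onset_ms=float(r.stimulus_onset_ms),
                            condition=str(r.condition),
                            condition_value=float(r.condition_value),
                            eye=eye, spikes=spikes))
    return SessionBundle(session_id=str(meta["session_id"]), trials=trials,
                         neurons=neurons, sampling_rate=float(meta["sampling_rate"]))
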