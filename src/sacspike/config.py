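"""Analysis configuration.

All temporal windows are in milliseconds relative to the event named by the
analysis (stimulus onset or movement onset), and all windows are half-open
``[t0, t1)`` unless stated otherwise.  The defaults are the constants used
throughout the analyses: the 30-100 ms visual-burst interval, the 0-20 ms
intra-saccadic spike-counting window, the >=15-trials-per-level cutoff with
spike counts above five excluded, the 50 ms / 10 ms amplitude running
average, 30-trial sorting bins with a 3-consecutive-bin significance
criterion, 5-ms spike-count bins over +/-100 ms, the >550 ms sustained
selection, and the 4.5 deg near/far eccentricity split.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union

import yaml


class ConfigError(ValueError):
    """Malformed, unknown, or out-of-range configuration input."""


@dataclass
class AnalysisConfig:
    visual_burst_window: tuple[float, float] = (30.0, 100.0)
    intra_saccadic_window: tuple[float, float] = (0.0, 20.0)
    toward_halfwidth: float = 90.0
    min_trials_per_level: int = 15
    max_spike_level: int = 5
    timecourse_window: float = 50.0
    timecourse_step: float = 10.0
    sort_bin_size: int = 30
    consecutive_bins: int = 3
    alpha: float = 0.05
    bonferroni: bool = True
    spike_bin: float = 5.0
    spike_bin_range: tuple[float, float] = (-100.0, 100.0)
    sustained_min_time: float = 550.0
    near_eccentricity_max: float = 4.5
    rate_kernel_sd: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.visual_burst_window = _as_window(self.visual_burst_window, "visual_burst_window")
        self.intra_saccadic_window = _as_window(self.intra_saccadic_window, "intra_saccadic_window")
        self.spike_bin_range = _as_window(self.spike_bin_range, "spike_bin_range")
        for name in ("min_trials_per_level", "sort_bin_size", "consecutive_bins"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.max_spike_level < 0:
            raise ConfigError("max_spike_level must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("toward_halfwidth", "timecourse_window", "timecourse_step",
                     "spike_bin", "near_eccentricity_max", "rate_kernel_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def _as_window(value, name: str) -> tuple[float, float]:
    try:
        t0, t1 = (float(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name} must be a (t0, t1) pair") from exc
    if not t0 < t1:
        raise ConfigError(f"{name} must be an ordered pair, got ({t0}, {t1})")
    return (t0, t1)


_FIELD_NAMES = {f.name for f in fields(AnalysisConfig)}


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat YAML mapping.

    Keys absent from the file take the default values above.  Unknown keys
    raise :class:`ConfigError` rather than being ignored: a silently
    misspelled window bound would corrupt every downstream result.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a flat key-value mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return AnalysisConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
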