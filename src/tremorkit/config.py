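"""Pipeline configuration.

All tunable constants of the detection pipeline live here so that a model can
carry a snapshot of the exact settings it was fitted under.  A short hash of
the snapshot is embedded in persisted models and in the headers of every
tabular output file; scoring features produced under a different snapshot is
refused downstream.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from typing import Any


@dataclass(frozen=True)
class SamplingConfig:
    """Canonical-rate resampling and gap handling."""

    target_rates: tuple[int, ...] = (50, 100)
    #: inter-sample interval > gap_factor * nominal interval starts a new block
    gap_factor: float = 1.5
    window_s: float = 4.0


@dataclass(frozen=True)
class WelchConfig:
    """Welch spectral-estimation parameters for 4-s windows.

    2-s Hann segments at 50% overlap give three averaged segments per window
    and a 0.5 Hz frequency resolution, enough to localise 3-7 Hz peaks while
    still averaging down estimator variance.
    """

    segment_s: float = 2.0
    overlap: float = 0.5
    taper: str = "hann"


@dataclass(frozen=True)
class FilterbankConfig:
    """Mel-style filterbank over the 0-25 Hz band used for the cepstral
    coefficients.  ``warp`` selects the frequency warping: ``mel_inertial``
    (log-like warp ``ln(1 + f/b)`` with break frequency ``warp_break_hz``,
    denser filters over the tremor band) or ``linear``."""

    n_filters: int = 15
    band: tuple[float, float] = (0.0, 25.0)
    warp: str = "mel_inertial"
    warp_break_hz: float = 4.0
    n_coefficients: int = 12


@dataclass(frozen=True)
class DetectorConfig:
    l2_strength: float = 0.01
    target_specificity: float = 0.95
    cycling_oversample: float = 100.0
    seed: int = 0
    max_iter: int = 1000


@dataclass(frozen=True)
class BandConfig:
    """Frequency bands of the decision cascade (Hz)."""

    rest_tremor_band: tuple[float, float] = (3.0, 7.0)
    movement_band: tuple[float, float] = (0.5, 3.0)
    #: total width of the tremor-power integration band around the dominant
    #: 3-7 Hz peak
    power_bandwidth: float = 1.25
    peak_search: tuple[float, float] = (0.5, 25.0)


@dataclass(frozen=True)
class AggregationConfig:
    daytime_hours: tuple[int, int] = (8, 22)
    min_valid_days: int = 3
    min_hours_per_day: float = 10.0
    gate_pct: float = 3.5
    mode_estimator: str = "kde"  # or "histogram"


@dataclass(frozen=True)
class EvaluationConfig:
    icc_variant: str = "ICC2"
    specificity_weighting: str = "pooled_prevalence"  # or "equal"


@dataclass(frozen=True)
class PipelineConfig:
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    filterbank: FilterbankConfig = field(default_factory=FilterbankConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict[str, Any]:
        return _jsonify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        sections = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            sub_cls = f.default_factory  # type: ignore[union-attr]
            known = {x.name for x in dataclasses.fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in [{f.name}]: {sorted(unknown)}")
            kwargs = {k: _tuplify(v) for k, v in sub.items()}
            sections[f.name] = sub_cls(**kwargs)
        return cls(**sections)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def hash(self) -> str:
        """Stable short hash of the full configuration snapshot."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonify(v) for v in obj]
    return obj


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


DEFAULT_CONFIG = PipelineConfig()
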