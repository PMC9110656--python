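"""Configuration objects for the simulator and the end-to-end pipeline.

Configs are plain dataclasses with eager validation; they load from YAML
mappings with unknown keys rejected, and every pipeline output embeds a
snapshot plus a stable hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

from .registry import DEFAULT_DOMAIN_COUNTS, DOMAINS, N_TASKS

SCORES = (0, 1, 2, 3)


def _as_score_map(m: Mapping[Any, float], name: str) -> dict[int, float]:
    out = {int(k): float(v) for k, v in m.items()}
    if set(out) != set(SCORES):
        raise ValueError(f"{name} must map every score in {SCORES}")
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic ARAT-session generator.

    The generator draws a latent severity per subject and arm, maps it to
    ordinal task scores through ordered thresholds, and synthesises
    score-dependent 6-axis wrist signals: slower, smaller-amplitude and
    more tremulous movement at lower scores, a near-stationary trace at
    score 0, and class imbalance toward score 3 on the less affected arm.
    """

    n_subjects: int = 20
    sessions_per_subject: int = 2
    #: latent severity theta in [0,1] (0 = unimpaired); per-arm Normal draws
    severity_more_affected: tuple[float, float] = (0.45, 0.20)  # mean, sd
    severity_less_affected: tuple[float, float] = (0.05, 0.05)
    #: ordered cutpoints on ability (1 - theta + noise): score = #exceeded
    score_thresholds: tuple[float, float, float] = (0.25, 0.50, 0.75)
    score_noise_sd: float = 0.08
    #: mean task duration per score, seconds (lower score -> longer, <= 60)
    duration_by_score: dict[int, float] = field(
        default_factory=lambda: {0: 10.0, 1: 36.0, 2: 16.0, 3: 6.0}
    )
    #: pathological oscillation band, Hz
    tremor_band_hz: tuple[float, float] = (3.0, 8.0)
    #: tremor acceleration amplitude per score, m/s^2 (decreasing with score)
    tremor_amp_by_score: dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 1.2, 2: 0.5, 3: 0.0}
    )
    reach_amplitude_m: float = 0.25
    missing_rate: float = 0.03
    noise_sd_accel: float = 0.05  # m/s^2 per axis
    noise_sd_gyro: float = 0.02  # rad/s per axis
    sampling_hz: float = 50.0
    domain_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_COUNTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.sessions_per_subject not in (1, 2):
            raise ValueError("sessions_per_subject must be 1 or 2")
        for name in ("severity_more_affected", "severity_less_affected"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")
        t = tuple(self.score_thresholds)
        if not (t[0] < t[1] < t[2]):
            raise ValueError("score_thresholds must be strictly increasing")
        self.score_thresholds = t
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        self.duration_by_score = _as_score_map(self.duration_by_score, "duration_by_score")
        if any(not (0.0 < d <= 60.0) for d in self.duration_by_score.values()):
            raise ValueError("duration_by_score values must lie in (0, 60]")
        lo, hi = self.tremor_band_hz
        if not (0.0 < lo < hi):
            raise ValueError("tremor_band_hz must be an increasing positive interval")
        self.tremor_amp_by_score = _as_score_map(
            self.tremor_amp_by_score, "tremor_amp_by_score"
        )
        if any(a < 0 for a in self.tremor_amp_by_score.values()):
            raise ValueError("tremor amplitudes must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("sensor noise sds must be >= 0")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if set(self.domain_counts) != set(DOMAINS) or sum(
            self.domain_counts.values()
        ) != N_TASKS:
            raise ValueError(f"domain_counts must cover {DOMAINS} and sum to {N_TASKS}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        return _from_dict(cls, d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ModelConfig:
    """Ordinal-classifier options: L2 strength, SMOTE neighbourhood, seed."""

    C: float = 1.0
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelConfig":
        return _from_dict(cls, d)


@dataclass
class PipelineConfig:
    """Everything needed to run simulate -> preprocess -> extract -> evaluate."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    #: accelerometer tilt-correction gain of the orientation filter, per sample
    orientation_gain: float = 0.02
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if not 0.0 <= self.orientation_gain <= 1.0:
            raise ValueError("orientation_gain must lie in [0, 1]")
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        model = d.pop("model", {})
        cfg = _from_dict(cls, d, skip=("simulation", "model"))
        cfg.simulation = (
            sim if isinstance(sim, SimulationConfig) else SimulationConfig.from_dict(sim)
        )
        cfg.model = model if isinstance(model, ModelConfig) else ModelConfig.from_dict(model)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the config snapshot, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _from_dict(cls, d: Mapping[str, Any], skip: tuple[str, ...] = ()):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in d.items() if k not in skip}
    return cls(**kwargs)
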