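"""Configuration objects for the generator, the matcher and whole runs.

Everything is a plain dataclass that round-trips losslessly through YAML, so a
run directory can always be reproduced from the ``resolved_config.yaml`` it
writes.  Defaults marked "invented" in the docstrings are phenomenological
choices that no published number pins down; they are exposed here precisely so
that they are visible and overridable.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

Side = str  # "L" | "R"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-night generator.

    Durations are seconds, event-scale times milliseconds, amplitudes
    microvolts.  The inter-event-interval (IEI) law of sharp negative events
    (SNs) is log-normal, parameterized by its median and mode; the bilateral
    pair process offsets the follower by ``interclaustral_lag_ms`` with the
    leader the larger of the two.  Imc channels lead the claustra by
    ``imc_ipsi_lead_ms`` (same side) and ``imc_contra_lead_ms`` (opposite
    side); consistency requires ``contra - ipsi == interclaustral_lag_ms``.
    """

    duration_s: float = 3600.0
    rate_hz: float = 1000.0
    noise_rms_uv: float = 15.0          # pink-noise floor (invented)
    fast_noise_rms_uv: float = 5.0      # 30-48 Hz broadband activity (invented)
    fast_noise_band_hz: tuple = (30.0, 48.0)
    sleep_cycle_s: tuple = (90.0, 150.0)
    remp_nosw_mean_s: float = 57.0      # REM_P duration, no dominance switch
    remp_nosw_sd_s: float = 16.6
    remp_onesw_mean_s: float = 88.5     # REM_P duration, one switch
    remp_onesw_sd_s: float = 19.6
    p_switch: float = 103.0 / 162.0     # P(exactly one switch) per episode
    p_two_switches: float = 0.02        # residual tail (invented)
    unsettled_s: float = 4.0            # unsettled time around each switch
    sn_iei_median_ms: float = 60.2
    sn_iei_mode_ms: float = 40.0
    sn_duration_median_ms: float = 6.0  # falling-phase duration (invented)
    sn_duration_spread: float = 0.15     # lognormal shape on duration (invented)
    sn_amp_median_uv: float = 450.0      # (invented)
    sn_amp_spread: float = 0.15           # lognormal shape on amplitude (invented)
    follower_amp_factor: float = 0.8     # follower/leader amplitude (invented)
    interclaustral_lag_ms: float = 20.0
    lag_jitter_sd_ms: float = 3.0        # (invented)
    p_bilateral: float = 0.97    # generative rate; ~0.90 observed after detection
    imc_ipsi_lead_ms: float = 30.0
    imc_contra_lead_ms: float = 50.0
    imc_amp_uv: float = 150.0            # Imc deflection amplitude (invented)
    swr_rate_hz: float = 1.0             # per-side sharp-wave-ripple rate in SW
    swr_amp_uv: float = 300.0            # (invented)
    n_units: int = 4
    p_spike_range: tuple = (0.14, 0.43)
    p_multispike_range: tuple = (0.003, 0.03)
    spike_jitter_sd_ms: float = 2.0      # around steepest descent (invented)
    spike_background_hz: float = 0.1     # out-of-SN firing (invented)
    lesion_side: str = "none"            # none | left | right
    lesioned_remp_mean_s: float = 33.0
    lesioned_remp_sd_s: float = 8.0      # (invented)
    min_sw_s: float = 20.0               # floor on SW episode length (invented)
    min_remp_s: float = 20.0             # floor on REM_P episode length (invented)
    side_bias_ar: float = 0.9            # AR(1) across-night side tendency
    seed: int = 0

    def __post_init__(self) -> None:
        self.sleep_cycle_s = tuple(self.sleep_cycle_s)
        self.p_spike_range = tuple(self.p_spike_range)
        self.p_multispike_range = tuple(self.p_multispike_range)
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for name in (
            "noise_rms_uv", "unsettled_s", "sn_iei_median_ms", "sn_iei_mode_ms",
            "sn_duration_median_ms", "sn_amp_median_uv", "lag_jitter_sd_ms",
            "imc_ipsi_lead_ms", "imc_contra_lead_ms", "swr_rate_hz",
            "spike_jitter_sd_ms", "lesioned_remp_mean_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_switch", "p_two_switches", "p_bilateral"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.p_switch + self.p_two_switches > 1.0:
            raise ValueError("p_switch + p_two_switches exceeds 1")
        if not self.sn_iei_mode_ms < self.sn_iei_median_ms:
            raise ValueError("IEI mode must be below the median (right-skewed law)")
        if abs(
            (self.imc_contra_lead_ms - self.imc_ipsi_lead_ms)
            - self.interclaustral_lag_ms
        ) > 1e-9:
            raise ValueError(
                "imc_contra_lead_ms - imc_ipsi_lead_ms must equal "
                "interclaustral_lag_ms"
            )
        if self.lesion_side not in ("none", "left", "right"):
            raise ValueError("lesion_side must be none|left|right")
        lo, hi = self.p_spike_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("p_spike_range must be an ordered probability range")


@dataclass
class MatchParams:
    """Parameters of the bilateral SN matching stage (milliseconds)."""

    xcorr_window_ms: float = 100.0
    kernel_tau_ms: float = 10.0
    lag_window_ms: float = 51.0
    chunk_hours: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class RunConfig:
    """One reproducible end-to-end run.

    ``beta_pct`` selects the sleep-segmentation threshold: a number applies
    the fixed percentile rule to the beta-power trace; the string ``"otsu"``
    (default) picks the percentile per night by two-class variance
    maximization on the log band-power histogram, which adapts to the night's
    actual SW fraction (see docs/methods.md).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    match: MatchParams = field(default_factory=MatchParams)
    alpha_detect: float = 0.025
    alpha_pair: float = 0.05
    beta_band_hz: tuple = (12.0, 30.0)
    beta_pct: Union[float, str] = "otsu"
    keep_quantile: float = 0.75
    xcorr_norm_pct: float = 99.9
    lag_ms: float = 20.0
    window_s: float = 10.0
    xcorr_step_s: float = 0.1
    dominance_threshold_l: float | None = None  # None -> calibrate per night
    dominance_threshold_r: float | None = None
    min_dominance_s: float = 3.0
    min_episode_s: float = 15.0
    prominence_floor: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        if isinstance(self.match, dict):
            self.match = MatchParams(**self.match)
        self.beta_band_hz = tuple(self.beta_band_hz)
        for name in ("alpha_detect", "alpha_pair"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    # ------------------------------------------------------------ YAML I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable content hash identifying this configuration."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj
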