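"""Configuration objects for the synthetic study generator and the processing pipeline.

The defaults describe a 12-pig crossover experiment: each animal is ventilated
through a PEEP staircase (5, 10, 15, 20, back to 5 cmH2O, 20 min per level) in
two position blocks (prone and supine, order randomized per animal) separated
by a washout at baseline settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

#: Canonical channel names carried by a waveform recording.
CHANNELS = ("ABP", "ICP", "CVP", "Paw", "Pes", "Flow", "Volume")

#: PRx-relevant slow-wave band (Hz) of arterial blood pressure.
SLOW_WAVE_BAND = (0.005, 0.05)


def _default_noise_sd() -> dict[str, float]:
    # Additive white measurement noise per channel, in channel units.
    return {
        "ABP": 1.0,
        "ICP": 0.3,
        "CVP": 0.5,
        "Paw": 0.3,
        "Pes": 0.3,
        "Flow": 0.02,
        "Volume": 0.005,
    }


@dataclass(frozen=True)
class CovariateEffects:
    """Modifiers of an animal's PEEP->ICP slope per unit of baseline covariate.

    Each coefficient multiplies the deviation of the animal's baseline value
    from the cohort mean and is added to the population-mean ICP/PEEP slope
    (mmHg per 5 cmH2O of PEEP).  Signs follow the physiology they emulate:
    higher baseline ICP and CVP amplify the ICP response, stiffer respiratory
    systems (higher E_rs) and higher transpulmonary pressures damp it.
    """

    icp0: float = 0.06   # per mmHg baseline ICP
    cvp: float = 0.15    # per mmHg baseline CVP
    e_rs: float = -0.03  # per cmH2O/L respiratory-system elastance
    tpp_ei: float = -0.15  # per cmH2O end-inspiratory transpulmonary pressure
    tpp_ee: float = -0.12  # per cmH2O end-expiratory transpulmonary pressure

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic crossover study.

    Waveform-level parameters (sampling rate, oscillation amplitudes) shape the
    raw channels; animal-level parameters (elastances, slopes, offsets) define
    the ground truth the downstream pipeline is expected to recover.
    """

    # --- study design ---
    n_animals: int = 12
    weight_kg: float = 25.0
    peep_sequence: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 5.0)
    period_minutes: float = 20.0
    washout_minutes: float = 20.0

    # --- ventilation ---
    resp_rate: float = 25.0          # breaths/min (protocol range 20-30)
    vt_ml_per_kg: float = 7.5        # tidal volume during the PEEP trial
    airway_resistance: float = 8.0   # cmH2O/(L/s)
    chest_wall_resistance: float = 1.5  # cmH2O/(L/s), esophageal signal
    e_cw_mean: float = 19.0          # chest-wall elastance, cmH2O/L
    e_cw_sd: float = 4.0
    e_l_mean: float = 33.0           # lung elastance, cmH2O/L
    e_l_sd: float = 6.0
    pes_ee_base: float = 4.0         # end-expiratory esophageal pressure at PEEP 5
    pes_ee_sd: float = 1.5
    pes_peep_transmission: float = 0.35  # fraction of PEEP above 5 reaching pleura

    # --- waveforms ---
    sampling_rate: float = 100.0     # Hz
    heart_rate: float = 96.0         # beats/min
    abp_mean: float = 85.0           # mmHg
    abp_pulse_amp: float = 15.0      # mmHg, cardiac component amplitude
    abp_resp_amp: float = 2.0        # mmHg, ventilation-synchronous component
    abp_slow_sd: float = 2.5         # mmHg, SD of the slow (0.005-0.05 Hz) component
    n_slow_waves: int = 4            # sinusoids per slow-wave process
    icp_slow_sd: float = 1.5         # mmHg, SD of the ICP slow component

    # --- intracranial physiology ---
    baseline_icp_mean: float = 6.0   # mmHg, prone reference
    baseline_icp_sd: float = 3.0
    supine_icp_offset: float = 5.0   # mmHg added in supine position
    coupling_g: float = -0.12        # population-mean reactivity coefficient
    coupling_sd: float = 0.20
    icp_peep_slope: float = 1.0      # mmHg per 5 cmH2O PEEP, population mean
    icp_peep_slope_sd: float = 0.35
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    # ICP pulse amplitude: AMP = amp_base + amp_slope * max(ICP - amp_threshold, 0)
    amp_base: float = 1.0            # mmHg
    amp_slope: float = 0.12          # per mmHg of mean ICP above threshold
    amp_threshold: float = 15.0      # mmHg

    # --- other hemodynamics ---
    baseline_cvp_mean: float = 12.0  # mmHg
    baseline_cvp_sd: float = 2.0
    cvp_peep_transmission: float = 0.2  # mmHg per cmH2O of PEEP above 5

    # --- noise ---
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    hold_noise_sd: float = 0.2       # cmH2O, added to occlusion-hold pressures
    summary_noise_sd: float = 0.35   # mmHg, per-period ICP summary noise (fast generator)

    seed: int = 0

    # ------------------------------------------------------------------

    @property
    def cardiac_hz(self) -> float:
        return self.heart_rate / 60.0

    @property
    def vt_l(self) -> float:
        return self.vt_ml_per_kg * self.weight_kg / 1000.0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.period_minutes <= 5:
            raise ValueError("period_minutes must exceed 5 (one full PRx window)")
        if self.sampling_rate <= 0 or self.heart_rate <= 0 or self.resp_rate <= 0:
            raise ValueError("rates must be positive")
        if self.sampling_rate < 20 * self.cardiac_hz:
            raise ValueError("sampling_rate must be at least 20x the cardiac frequency")
        if abs(self.coupling_g) > 1:
            raise ValueError("|coupling_g| must not exceed 1")
        if self.e_cw_mean <= 0 or self.e_l_mean <= 0:
            raise ValueError("elastances must be positive")
        if not self.peep_sequence:
            raise ValueError("peep_sequence must not be empty")
        if self.vt_ml_per_kg <= 0 or self.weight_kg <= 0:
            raise ValueError("tidal volume must be positive")

    def replace(self, **kwargs: Any) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    def noiseless(self) -> "SynthConfig":
        """Copy with every measurement-noise source switched off (animal-level
        parameter heterogeneity is kept; zero it via the *_sd fields)."""
        return self.replace(
            noise_sd={k: 0.0 for k in self.noise_sd},
            hold_noise_sd=0.0,
            summary_noise_sd=0.0,
        )

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["peep_sequence"] = list(self.peep_sequence)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SynthConfig":
        d = dict(d)
        if "peep_sequence" in d:
            d["peep_sequence"] = tuple(d["peep_sequence"])
        if isinstance(d.get("covariate_effects"), dict):
            d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings (simulate -> process -> mechanics -> stats)."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    out_dir: str = "lungbrain_run"
    amp_method: str = "spectral"      # 'spectral' or 'beat'
    artifact_level: str = "block"     # 'block' or 'raw'
    icp_limits: tuple[float, float] = (-10.0, 60.0)
    cpp_limits: tuple[float, float] = (0.0, 150.0)
    min_valid_pairs: int = 24         # of 30 per correlation window
    min_raw_fraction: float = 0.5     # valid raw samples per 10-s block
    alpha: float = 0.05
    covariates: tuple[str, ...] | None = None
    write_waveforms: bool = False
    make_plots: bool = False

    def validate(self) -> None:
        self.synth.validate()
        if self.amp_method not in ("spectral", "beat"):
            raise ValueError("amp_method must be 'spectral' or 'beat'")
        if self.artifact_level not in ("block", "raw"):
            raise ValueError("artifact_level must be 'block' or 'raw'")
        if not 0 < self.min_raw_fraction <= 1:
            raise ValueError("min_raw_fraction must be in (0, 1]")
        if not 0 < self.min_valid_pairs <= 30:
            raise ValueError("min_valid_pairs must be in (0, 30]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.as_dict()
        d["icp_limits"] = list(self.icp_limits)
        d["cpp_limits"] = list(self.cpp_limits)
        if self.covariates is not None:
            d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("synth"), dict):
            d["synth"] = SynthConfig.from_dict(d["synth"])
        for key in ("icp_limits", "cpp_limits"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("covariates") is not None:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def config_hash(cfg: SynthConfig | RunConfig) -> str:
    """Stable SHA-256 digest of a configuration (for run manifests)."""
    payload = json.dumps(cfg.as_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()
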