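"""Seeded synthetic physiology for a PEEP x position crossover experiment.

The generator produces ground-truth-labelled multichannel recordings (ABP, ICP,
CVP, airway and esophageal pressure, flow, volume) with the statistical
structure the analysis pipeline assumes:

* arterial pressure carries slow vasogenic oscillations (0.005-0.05 Hz),
  a cardiac pulse and a ventilation-synchronous component;
* ICP is coupled to the *slow* ABP component through a reactivity coefficient
  ``g`` in [-1, 1] (negative = intact autoregulation), so that the downstream
  pressure reactivity index recovers ``g`` in the noise-free limit;
* the ICP pulse amplitude grows with mean ICP above a compliance threshold,
  which is what makes the compensatory reserve index (RAP) approach 1 when
  intracranial reserve is exhausted;
* PEEP raises mean ICP by an animal-specific slope that depends on baseline
  covariates (ICP, CVP, elastance, transpulmonary pressures);
* ventilator waveforms are consistent with each animal's chest-wall and lung
  elastances, and per-period occlusion holds satisfy the elastance identities
  exactly before measurement noise.

Nothing here integrates an organ-level circulation model; the signals are a
phenomenological stand-in with controllable effect sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SLOW_WAVE_BAND, SynthConfig

PRONE_FIRST = "prone-first"
SUPINE_FIRST = "supine-first"


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Annotation:
    """A labelled interval of a recording (period, hold, or injected artifact)."""

    kind: str          # 'period' | 'artifact'
    label: str
    start_s: float
    end_s: float
    info: dict = field(default_factory=dict)


@dataclass
class WaveformRecording:
    """Uniformly sampled multichannel recording."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    start_time: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start_s}, {ann.end_s}] outside recording span"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "WaveformRecording":
        return WaveformRecording(
            channels={k: v.copy() for k, v in self.channels.items()},
            sampling_rate=self.sampling_rate,
            start_time=self.start_time,
            annotations=list(self.annotations),
        )


@dataclass(frozen=True)
class AnimalTruth:
    """Ground-truth parameters of one simulated animal."""

    animal: str
    index: int
    sequence: str            # 'prone-first' or 'supine-first'
    coupling_g: float
    icp_peep_slope: float    # mmHg per 5 cmH2O
    e_cw: float              # cmH2O/L
    e_l: float
    e_rs: float
    baseline_icp: float      # mmHg, prone reference
    baseline_cvp: float
    pes_ee_base: float       # cmH2O at PEEP 5
    supine_offset: float
    vt_l: float
    rr: float
    tpp_ei0: float           # baseline end-inspiratory transpulmonary pressure
    tpp_ee0: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ArtifactSpec:
    """Description of one artifact to inject into a recording channel."""

    channel: str
    start_s: float
    end_s: float
    kind: str            # 'spike' | 'dropout' | 'flatline'
    value: float = 0.0   # target value for spike/dropout; ignored for flatline


@dataclass
class SimulatedStudy:
    recordings: list[WaveformRecording]
    ground_truths: list[AnimalTruth]
    design: pd.DataFrame
    holds: pd.DataFrame


# ---------------------------------------------------------------------------
# design layout


def build_design(config: SynthConfig, sequence: str, animal: str) -> pd.DataFrame:
    """Lay out the period table for one animal: two position blocks separated
    by a washout at baseline settings (washout in the second block's posture)."""
    first, second = (
        ("prone", "supine") if sequence == PRONE_FIRST else ("supine", "prone")
    )
    period_s = config.period_minutes * 60.0
    washout_s = config.washout_minutes * 60.0
    rows = []
    t = 0.0
    n_levels = len(config.peep_sequence)
    for block, position in ((1, first), (2, second)):
        if block == 2 and washout_s > 0:
            rows.append(
                dict(animal=animal, sequence=sequence, block=0, period_order=0,
                     position=position, peep=config.peep_sequence[0],
                     label="washout", period_index=-1,
                     start_s=t, end_s=t + washout_s)
            )
            t += washout_s
        for i, peep in enumerate(config.peep_sequence):
            if i == 0:
                label = "baseline"
            elif peep == config.peep_sequence[0] and i == n_levels - 1:
                label = "return"
            else:
                label = "intervention"
            rows.append(
                dict(animal=animal, sequence=sequence, block=block,
                     period_order=block, position=position, peep=peep,
                     label=label, period_index=i, start_s=t, end_s=t + period_s)
            )
            t += period_s
    df = pd.DataFrame(rows)
    df["period_id"] = [
        f"{r.animal}-b{r.block}-p{r.period_index}" for r in df.itertuples()
    ]
    return df


# ---------------------------------------------------------------------------
# animal-level parameter draws


def _animal_rng(config: SynthConfig, animal_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(animal_index)])


def draw_animal(config: SynthConfig, animal_index: int,
                rng: np.random.Generator | None = None) -> AnimalTruth:
    """Draw one animal's ground-truth parameters (deterministic per seed/index)."""
    if rng is None:
        rng = _animal_rng(config, animal_index)
    sequence = PRONE_FIRST if rng.integers(2) == 0 else SUPINE_FIRST  # drawing lots
    e_cw = max(float(rng.normal(config.e_cw_mean, config.e_cw_sd)), 2.0)
    e_l = max(float(rng.normal(config.e_l_mean, config.e_l_sd)), 2.0)
    e_rs = e_cw + e_l
    pes_ee_base = float(rng.normal(config.pes_ee_base, config.pes_ee_sd))
    icp0 = float(rng.normal(config.baseline_icp_mean, config.baseline_icp_sd))
    cvp0 = float(rng.normal(config.baseline_cvp_mean, config.baseline_cvp_sd))
    g = float(np.clip(rng.normal(config.coupling_g, config.coupling_sd), -1.0, 1.0))
    slope_resid = float(rng.normal(0.0, config.icp_peep_slope_sd))

    vt = config.vt_l
    peep0 = config.peep_sequence[0]
    tpp_ei0 = (peep0 + e_rs * vt) - (pes_ee_base + e_cw * vt)
    tpp_ee0 = peep0 - pes_ee_base
    # cohort expectations of the same quantities, for centring
    tpp_ei_mean = peep0 + config.e_l_mean * vt - config.pes_ee_base
    tpp_ee_mean = peep0 - config.pes_ee_base
    c = config.covariate_effects
    slope = (
        config.icp_peep_slope
        + c.icp0 * (icp0 - config.baseline_icp_mean)
        + c.cvp * (cvp0 - config.baseline_cvp_mean)
        + c.e_rs * (e_rs - (config.e_cw_mean + config.e_l_mean))
        + c.tpp_ei * (tpp_ei0 - tpp_ei_mean)
        + c.tpp_ee * (tpp_ee0 - tpp_ee_mean)
        + slope_resid
    )
    return AnimalTruth(
        animal=f"pig{animal_index:02d}", index=animal_index, sequence=sequence,
        coupling_g=g, icp_peep_slope=slope, e_cw=e_cw, e_l=e_l, e_rs=e_rs,
        baseline_icp=icp0, baseline_cvp=cvp0, pes_ee_base=pes_ee_base,
        supine_offset=config.supine_icp_offset, vt_l=vt, rr=config.resp_rate,
        tpp_ei0=tpp_ei0, tpp_ee0=tpp_ee0,
    )


def _slow_process(rng: np.random.Generator, t: np.ndarray, k: int) -> np.ndarray:
    """Standardized sum of k sinusoids with random frequencies in the slow band."""
    lo, hi = SLOW_WAVE_BAND
    freqs = rng.uniform(lo, hi, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    z = np.zeros_like(t)
    for f, p in zip(freqs, phases):
        z += np.sin(2 * np.pi * f * t + p)
    return z / np.sqrt(k / 2.0)  # unit-amplitude sinusoids: variance k/2


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


# ---------------------------------------------------------------------------
# waveform synthesis


def simulate_animal(config: SynthConfig,
                    animal_index: int) -> tuple[WaveformRecording, AnimalTruth]:
    """Simulate one animal's full recording across both position blocks.

    Deterministic for a fixed ``(config.seed, animal_index)``.
    """
    config.validate()
    if animal_index >= config.n_animals:
        raise ValueError("animal_index out of range")
    rng = _animal_rng(config, animal_index)
    truth = draw_animal(config, animal_index, rng)
    design = build_design(config, truth.sequence, truth.animal)

    fs = config.sampling_rate
    duration = float(design["end_s"].iloc[-1])
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # per-sample period attributes
    starts = design["start_s"].to_numpy()
    idx = np.searchsorted(starts, t, side="right") - 1
    peep_t = design["peep"].to_numpy()[idx]
    supine_t = (design["position"].to_numpy()[idx] == "supine").astype(float)

    # slow vasogenic processes: one driving ABP, one independent for ICP
    z_abp = _slow_process(rng, t, config.n_slow_waves)
    z_ind = _slow_process(rng, t, config.n_slow_waves)
    phi_icp = rng.uniform(0, 2 * np.pi)

    f_c = config.cardiac_hz
    f_r = config.resp_rate / 60.0
    cardiac = np.sin(2 * np.pi * f_c * t)

    abp = (
        config.abp_mean
        + config.abp_slow_sd * z_abp
        + config.abp_pulse_amp * cardiac
        + config.abp_resp_amp * np.sin(2 * np.pi * f_r * t)
        + _noise(rng, config.noise_sd.get("ABP", 0.0), n)
    )

    g = truth.coupling_g
    icp_slow = config.icp_slow_sd * (g * z_abp + np.sqrt(max(1 - g * g, 0.0)) * z_ind)
    icp_level = (
        truth.baseline_icp
        + truth.supine_offset * supine_t
        + truth.icp_peep_slope * (peep_t - config.peep_sequence[0]) / 5.0
        + icp_slow
    )
    pulse_amp = config.amp_base + config.amp_slope * np.maximum(
        icp_level - config.amp_threshold, 0.0
    )
    icp = (
        icp_level
        + 0.5 * pulse_amp * np.sin(2 * np.pi * f_c * t + phi_icp)
        + _noise(rng, config.noise_sd.get("ICP", 0.0), n)
    )

    cvp = (
        truth.baseline_cvp
        + config.cvp_peep_transmission * (peep_t - config.peep_sequence[0])
        + 0.5 * np.sin(2 * np.pi * f_r * t)
        + _noise(rng, config.noise_sd.get("CVP", 0.0), n)
    )

    # ventilator waveforms: volume control, I:E 1:2, 20% end-inspiratory pause
    period = 60.0 / config.resp_rate
    ti = period / 3.0
    ti_flow = 0.8 * ti
    tau = (period - ti) / 5.0
    phase = np.mod(t, period)
    vt = truth.vt_l
    volume = np.where(
        phase < ti_flow,
        vt * phase / ti_flow,
        np.where(phase < ti, vt, vt * np.exp(-(phase - ti) / tau)),
    )
    flow = np.where(
        phase < ti_flow,
        vt / ti_flow,
        np.where(phase < ti, 0.0, -volume / tau),
    )
    insp_flow = np.clip(flow, 0.0, None)
    pes_ee_t = truth.pes_ee_base + config.pes_peep_transmission * (
        peep_t - config.peep_sequence[0]
    )
    paw = (
        peep_t + truth.e_rs * volume + config.airway_resistance * insp_flow
        + _noise(rng, config.noise_sd.get("Paw", 0.0), n)
    )
    pes = (
        pes_ee_t + truth.e_cw * volume + config.chest_wall_resistance * insp_flow
        + _noise(rng, config.noise_sd.get("Pes", 0.0), n)
    )
    flow = flow + _noise(rng, config.noise_sd.get("Flow", 0.0), n)
    volume = volume + _noise(rng, config.noise_sd.get("Volume", 0.0), n)

    channels = {
        "ABP": abp, "ICP": icp, "CVP": cvp,
        "Paw": paw, "Pes": pes, "Flow": flow, "Volume": volume,
    }
    annotations = [
        Annotation(
            kind="period",
            label=f"{r.position}/PEEP{r.peep:g}/{r.label}",
            start_s=float(r.start_s), end_s=float(r.end_s),
            info=dict(animal=r.animal, sequence=r.sequence, block=int(r.block),
                      position=r.position, peep=float(r.peep), label=r.label,
                      period_id=r.period_id, period_order=int(r.period_order)),
        )
        for r in design.itertuples()
    ]
    rec = WaveformRecording(channels=channels, sampling_rate=fs,
                            annotations=annotations)
    return rec, truth


def design_from_recording(rec: WaveformRecording) -> pd.DataFrame:
    """Recover the per-period design rows from a recording's annotations."""
    rows = []
    for ann in rec.annotations:
        if ann.kind != "period":
            continue
        row = dict(ann.info)
        row["start_s"] = ann.start_s
        row["end_s"] = ann.end_s
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occlusion holds and per-period auxiliary measurements


def generate_holds(config: SynthConfig, truth: AnimalTruth,
                   design: pd.DataFrame,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-period occlusion-hold and intermittent measurements.

    Before noise the holds satisfy the elastance identities exactly:
    ``Paw_ei - PEEPtot = VT * E_rs`` and ``Pes_ei - Pes_ee = VT * E_cw``.
    """
    if rng is None:
        rng = np.random.default_rng(
            [int(config.seed), int(truth.index), 7919]
        )
    vt = truth.vt_l
    flow_peak = vt / (0.8 * (60.0 / config.resp_rate) / 3.0)
    sd = config.hold_noise_sd
    peep0 = config.peep_sequence[0]

    # stable per-animal gas-exchange / hemodynamic levels
    pao2_a = rng.normal(188.0, 25.0)
    paco2_a = rng.normal(42.0, 3.0)
    co_a = rng.normal(3.8, 0.8)
    pap_a = rng.normal(21.0, 3.0)
    evlw_a = rng.normal(280.0, 40.0)
    svv_a = rng.normal(7.0, 2.0)

    rows = []
    for r in design.itertuples():
        peep = float(r.peep)
        pes_ee = truth.pes_ee_base + config.pes_peep_transmission * (peep - peep0)
        pes_ei = pes_ee + truth.e_cw * vt
        paw_ei = peep + truth.e_rs * vt
        ratio = float(np.clip(rng.normal(1.0, 0.04), 0.5, 1.5))
        d_paw = 5.0
        rows.append(dict(
            animal=r.animal, period_id=r.period_id, block=int(r.block),
            position=r.position, peep=peep, label=r.label,
            paw_ei=paw_ei + rng.normal(0, sd),
            peep_tot=peep + rng.normal(0, sd),
            pes_ei=pes_ei + rng.normal(0, sd),
            pes_ee=pes_ee + rng.normal(0, sd),
            ppeak_rs=paw_ei + config.airway_resistance * flow_peak + rng.normal(0, sd),
            ppeak_cw=pes_ei + config.chest_wall_resistance * flow_peak + rng.normal(0, sd),
            paw_ee=peep + rng.normal(0, sd),
            vt_ml=vt * 1000.0,
            rr=truth.rr,
            d_paw=d_paw,
            d_pes=d_paw * ratio,
            pao2=pao2_a + rng.normal(0, 5.0),
            paco2=paco2_a + rng.normal(0, 1.0),
            co=co_a - 0.02 * (peep - peep0) + rng.normal(0, 0.15),
            pap=pap_a + 0.15 * (peep - peep0) + rng.normal(0, 0.5),
            cvp=truth.baseline_cvp + config.cvp_peep_transmission * (peep - peep0)
                + rng.normal(0, 0.3),
            evlw=evlw_a + rng.normal(0, 5.0),
            svv=svv_a + rng.normal(0, 0.5),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study level


def simulate_study(config: SynthConfig) -> SimulatedStudy:
    """Simulate the full crossover study (all animals, recordings in memory)."""
    if config.n_animals < 2:
        raise ValueError("a study needs at least 2 animals")
    recordings, truths, designs, holds = [], [], [], []
    for i, (rec, truth, design, hold) in enumerate(iterate_study(config)):
        recordings.append(rec)
        truths.append(truth)
        designs.append(design)
        holds.append(hold)
    return SimulatedStudy(
        recordings=recordings,
        ground_truths=truths,
        design=pd.concat(designs, ignore_index=True),
        holds=pd.concat(holds, ignore_index=True),
    )


def iterate_study(config: SynthConfig):
    """Yield (recording, truth, design, holds) per animal without holding the
    whole study in memory."""
    config.validate()
    for i in range(config.n_animals):
        rec, truth = simulate_animal(config, i)
        design = build_design(config, truth.sequence, truth.animal)
        hold = generate_holds(config, truth, design)
        yield rec, truth, design, hold


def ground_truth_frame(truths: list[AnimalTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.as_dict() for t in truths])


# ---------------------------------------------------------------------------
# artifacts


def inject_artifacts(rec: WaveformRecording,
                     artifacts: list[ArtifactSpec]) -> WaveformRecording:
    """Return a copy of ``rec`` with the described artifacts written into the
    raw samples and recorded as annotations (for mask-recovery tests)."""
    out = rec.copy()
    n = out.n_samples
    fs = out.sampling_rate
    for spec in artifacts:
        if spec.channel not in out.channels:
            raise KeyError(f"unknown channel {spec.channel!r}")
        if spec.start_s < 0 or spec.end_s > out.duration_s or spec.start_s >= spec.end_s:
            raise ValueError(
                f"artifact interval [{spec.start_s}, {spec.end_s}] outside recording"
            )
        i0 = int(round(spec.start_s * fs))
        i1 = min(int(round(spec.end_s * fs)), n)
        x = out.channels[spec.channel]
        if spec.kind in ("spike", "dropout"):
            x[i0:i1] = spec.value
        elif spec.kind == "flatline":
            x[i0:i1] = x[i0 - 1] if i0 > 0 else x[0]
        else:
            raise ValueError(f"unknown artifact kind {spec.kind!r}")
        out.annotations.append(Annotation(
            kind="artifact", label=f"{spec.kind}:{spec.channel}",
            start_s=spec.start_s, end_s=spec.end_s,
            info=dict(channel=spec.channel, kind=spec.kind, value=spec.value),
        ))
    return out


# ---------------------------------------------------------------------------
# fast summary-level generator (for statistical calibration studies)


def simulate_summary_table(config: SynthConfig,
                           seed: int | None = None) -> pd.DataFrame:
    """Generate a per-period StudyTable directly, skipping waveform synthesis.

    Shares the per-animal parameter draws with :func:`simulate_animal`, so the
    effect structure (PEEP slope, position offset, covariate dependencies,
    reactivity coefficient) is identical; per-period summary noise stands in
    for what trend processing would leave behind.  Intended for repeated-run
    statistical calibration and power studies.
    """
    config.validate()
    base = config if seed is None else config.replace(seed=int(seed))
    master = np.random.default_rng([int(base.seed), 104729])
    peep0 = config.peep_sequence[0]
    rows = []
    for i in range(config.n_animals):
        truth = draw_animal(base, i)
        design = build_design(config, truth.sequence, truth.animal)
        holds = generate_holds(base, truth, design, rng=np.random.default_rng(
            [int(base.seed), i, 7919]))
        g = truth.coupling_g
        prx_true = np.clip(g, -0.99, 0.99)
        for r, h in zip(design.itertuples(), holds.itertuples()):
            level = (
                truth.baseline_icp
                + (truth.supine_offset if r.position == "supine" else 0.0)
                + truth.icp_peep_slope * (r.peep - peep0) / 5.0
            )
            icp = level + master.normal(0.0, config.summary_noise_sd)
            amp = config.amp_base + config.amp_slope * max(
                level - config.amp_threshold, 0.0)
            prx_z = np.arctanh(prx_true) + master.normal(0.0, 0.20)
            rap_z = master.normal(0.0, 0.20)
            rows.append(dict(
                animal=r.animal, sequence=r.sequence, block=int(r.block),
                period_order=int(r.period_order), position=r.position,
                peep=float(r.peep), label=r.label, period_id=r.period_id,
                icp=icp, abp=config.abp_mean + master.normal(0, 2.0),
                amp=amp, prx_z=prx_z, prx=np.tanh(prx_z),
                rap_z=rap_z, rap=np.tanh(rap_z),
                cvp=h.cvp, e_rs=truth.e_rs, e_cw=truth.e_cw, e_l=truth.e_l,
                tpp_ei=h.paw_ei - h.pes_ei, tpp_ee=h.peep_tot - h.pes_ee,
                paw_ei=h.paw_ei, vt_ml=h.vt_ml, rr=h.rr,
                pao2=h.pao2, paco2=h.paco2, pap=h.pap, co=h.co,
                mp_rs=0.098 * (h.vt_ml / 1000.0) * h.rr
                      * (h.ppeak_rs - (h.paw_ei - h.paw_ee) / 2.0),
            ))
    tbl = pd.DataFrame(rows)
    tbl["cpp"] = tbl["abp"] - tbl["icp"]
    return add_delta_columns(tbl)


def add_delta_columns(tbl: pd.DataFrame,
                      columns: tuple[str, ...] = ("icp", "prx_z", "rap_z",
                                                  "cpp", "amp")) -> pd.DataFrame:
    """Append change-from-baseline columns (vs the PEEP-baseline row of the
    same position block; washout rows get no delta)."""
    tbl = tbl.copy()
    for col in columns:
        if col in tbl.columns:
            tbl[f"d_{col}"] = np.nan
    for (_, block), grp in tbl.groupby(["animal", "block"]):
        if block == 0:
            continue
        base = grp[grp["label"] == "baseline"]
        if base.empty:
            continue
        for col in columns:
            if col not in tbl.columns:
                continue
            b = base[col].iloc[0]
            tbl.loc[grp.index, f"d_{col}"] = grp[col] - b
    if "d_prx_z" in tbl.columns:
        tbl["d_prx"] = np.tanh(tbl["prx_z"]) - np.tanh(tbl["prx_z"] - tbl["d_prx_z"])
    return tbl
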