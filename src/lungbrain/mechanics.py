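"""Respiratory mechanics from per-period occlusion-hold measurements.

All pressures in cmH2O, tidal volume internally in litres (study tables carry
VT in mL), elastances in cmH2O/L, mechanical power in J/min.  The factor 0.098
converts L*cmH2O/min to J/min.

Derived quantities per hold:

* elastances       E_rs = (Paw_ei - PEEPtot)/VT,  E_cw = (Pes_ei - Pes_ee)/VT,
                   E_l = E_rs - E_cw
* transpulmonary   TPP_ei = Paw_ei - Pes_ei,  TPP_ee = PEEPtot - Pes_ee,
                   TPP_elast = Paw_ei * E_l / E_rs
* peak pressures   Ppeak_l = Ppeak_rs - Ppeak_cw
* mechanical power MP_rs      = 0.098*VT*RR*(Ppeak_rs - (Paw_ei - Paw_ee)/2)
                   MP_lDep    = 0.098*VT*RR*(Ppeak_l - (TPP_ei - TPP_ee)/2)
                   MP_lnonDep = 0.098*VT*RR*(Ppeak_l - (TPP_elast - TPP_ee)/2)

The esophageal catheter position is validated by the expiratory occlusion
test: dPes/dPaw must fall within [0.8, 1.2] (boundaries inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

POWER_FACTOR = 0.098
OCCLUSION_RANGE = (0.8, 1.2)


@dataclass(frozen=True)
class HoldMeasurement:
    """One period's zero-flow hold pressures and ventilator settings."""

    paw_ei: float          # end-inspiratory hold airway pressure, cmH2O
    peep_tot: float        # total end-expiratory hold airway pressure, cmH2O
    pes_ei: float          # end-inspiratory esophageal pressure, cmH2O
    pes_ee: float          # end-expiratory esophageal pressure, cmH2O
    ppeak_rs: float        # max airway pressure, cmH2O
    ppeak_cw: float        # max esophageal pressure, cmH2O
    vt_l: float            # tidal volume, L
    rr: float              # breaths/min
    paw_ee: float | None = None   # set PEEP if no end-expiratory hold value
    d_pes: float | None = None    # expiratory-occlusion esophageal delta
    d_paw: float | None = None    # expiratory-occlusion airway delta

    def __post_init__(self) -> None:
        if self.vt_l <= 0:
            raise ValueError("VT must be positive")
        if self.rr <= 0:
            raise ValueError("respiratory rate must be positive")

    @classmethod
    def from_row(cls, row) -> "HoldMeasurement":
        """Build from a holds-table row (VT column in mL, per table convention)."""
        get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
        return cls(
            paw_ei=float(get("paw_ei")), peep_tot=float(get("peep_tot")),
            pes_ei=float(get("pes_ei")), pes_ee=float(get("pes_ee")),
            ppeak_rs=float(get("ppeak_rs")), ppeak_cw=float(get("ppeak_cw")),
            vt_l=float(get("vt_ml")) / 1000.0, rr=float(get("rr")),
            paw_ee=None if get("paw_ee") is None else float(get("paw_ee")),
            d_pes=None if get("d_pes") is None else float(get("d_pes")),
            d_paw=None if get("d_paw") is None else float(get("d_paw")),
        )


@dataclass(frozen=True)
class MechanicsResult:
    """All derived respiratory-mechanics quantities for one period."""

    e_rs: float
    e_cw: float
    e_l: float
    tpp_ei: float
    tpp_ee: float
    tpp_elast: float
    ppeak_l: float
    mp_rs: float
    mp_ldep: float
    mp_lnondep: float
    occlusion_ratio: float | None = None
    occlusion_pass: bool | None = None


@dataclass(frozen=True)
class OcclusionResult:
    ratio: float
    passed: bool


# ---------------------------------------------------------------------------


def validate_occlusion(d_pes: float, d_paw: float) -> OcclusionResult:
    """Expiratory occlusion test: catheter accepted iff dPes/dPaw in [0.8, 1.2]."""
    if d_paw == 0:
        raise ValueError("dPaw must be non-zero for the occlusion test")
    ratio = d_pes / d_paw
    return OcclusionResult(ratio=ratio,
                           passed=OCCLUSION_RANGE[0] <= ratio <= OCCLUSION_RANGE[1])


def elastances(h: HoldMeasurement) -> tuple[float, float, float]:
    """Respiratory-system, chest-wall and lung elastance (cmH2O/L)."""
    if h.vt_l <= 0:
        raise ValueError("VT must be positive")
    e_rs = (h.paw_ei - h.peep_tot) / h.vt_l
    e_cw = (h.pes_ei - h.pes_ee) / h.vt_l
    e_l = e_rs - e_cw
    if e_cw > e_rs:
        warnings.warn("chest-wall elastance exceeds respiratory-system elastance "
                      "(negative lung elastance)", stacklevel=2)
    return e_rs, e_cw, e_l


def transpulmonary(h: HoldMeasurement) -> tuple[float, float]:
    """Absolute end-inspiratory and end-expiratory transpulmonary pressures."""
    return h.paw_ei - h.pes_ei, h.peep_tot - h.pes_ee


def tpp_elastance_method(paw_ei: float, e_l: float, e_rs: float) -> float:
    """Lung stress of the non-dependent lung: Paw_ei scaled by E_l/E_rs."""
    if e_rs == 0:
        raise ValueError("E_rs must be non-zero")
    return paw_ei * e_l / e_rs


def peak_lung_pressure(ppeak_rs: float, ppeak_cw: float) -> float:
    """Peak pressure across the lung: Ppeak_rs - Ppeak_cw."""
    return ppeak_rs - ppeak_cw


def mechanical_power(h: HoldMeasurement, tpp_ei: float, tpp_ee: float,
                     tpp_elast: float, ppeak_l: float) -> tuple[float, float, float]:
    """Mechanical power of the respiratory system and of the dependent /
    non-dependent lung, J/min.  Uses the measured end-expiratory hold pressure
    for Paw_ee when no separate value is available."""
    paw_ee = h.paw_ee if h.paw_ee is not None else h.peep_tot
    base = POWER_FACTOR * h.vt_l * h.rr
    mp_rs = base * (h.ppeak_rs - (h.paw_ei - paw_ee) / 2.0)
    mp_ldep = base * (ppeak_l - (tpp_ei - tpp_ee) / 2.0)
    mp_lnondep = base * (ppeak_l - (tpp_elast - tpp_ee) / 2.0)
    for name, v in (("MP_rs", mp_rs), ("MP_lDep", mp_ldep), ("MP_lnonDep", mp_lnondep)):
        if v < 0:
            warnings.warn(f"{name} is negative: physically implausible inputs",
                          stacklevel=2)
    return mp_rs, mp_ldep, mp_lnondep


def compute_mechanics(h: HoldMeasurement) -> MechanicsResult:
    """All derived quantities for one hold measurement."""
    e_rs, e_cw, e_l = elastances(h)
    tpp_ei, tpp_ee = transpulmonary(h)
    tpp_el = tpp_elastance_method(h.paw_ei, e_l, e_rs)
    ppeak_l = peak_lung_pressure(h.ppeak_rs, h.ppeak_cw)
    mp_rs, mp_ldep, mp_lnondep = mechanical_power(h, tpp_ei, tpp_ee, tpp_el, ppeak_l)
    occ_ratio = occ_pass = None
    if h.d_pes is not None and h.d_paw:
        occ = validate_occlusion(h.d_pes, h.d_paw)
        occ_ratio, occ_pass = occ.ratio, occ.passed
    return MechanicsResult(
        e_rs=e_rs, e_cw=e_cw, e_l=e_l, tpp_ei=tpp_ei, tpp_ee=tpp_ee,
        tpp_elast=tpp_el, ppeak_l=ppeak_l, mp_rs=mp_rs, mp_ldep=mp_ldep,
        mp_lnondep=mp_lnondep, occlusion_ratio=occ_ratio, occlusion_pass=occ_pass,
    )


def compute_mechanics_table(holds: pd.DataFrame) -> pd.DataFrame:
    """Append MechanicsResult columns to a per-period holds table.

    Expects the documented holds CSV schema (``vt_ml`` in millilitres); other
    columns (blood gases, thermodilution values) pass through untouched.
    """
    required = {"paw_ei", "peep_tot", "pes_ei", "pes_ee",
                "ppeak_rs", "ppeak_cw", "vt_ml", "rr"}
    missing = required - set(holds.columns)
    if missing:
        raise KeyError(f"holds table missing columns: {sorted(missing)}")
    out = holds.copy()
    results = [compute_mechanics(HoldMeasurement.from_row(row))
               for _, row in holds.iterrows()]
    for col in ("e_rs", "e_cw", "e_l", "tpp_ei", "tpp_ee", "tpp_elast",
                "ppeak_l", "mp_rs", "mp_ldep", "mp_lnondep",
                "occlusion_ratio", "occlusion_pass"):
        out[col] = [getattr(r, col) for r in results]
    return out
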