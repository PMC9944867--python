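"""Perpetrator interaction-site concentrations from dose and plasma PK.

A static drug-drug-interaction assessment needs an inhibitor concentration
[I] at each site where a victim-drug transporter operates:

* intestinal lumen  — I_gut = dose / 250 mL, the regulatory screening
  concentration for apical efflux transporters such as BCRP;
* enterocyte        — I_g = F_aF_g · k_a · dose / Q_ent, the maximum
  enterocyte concentration used as [I] in the mechanistic intestinal model;
* hepatic inlet     — I_in,max = C_max + (F_aF_g · k_a · dose / Q_h) / R_B,
  whose unbound value I_in,max,u = f_u · I_in,max drives sinusoidal uptake
  transporters (OATP1B1/1B3, NTCP);
* systemic plasma   — C_max,u = f_u · C_max for renal basolateral uptake
  (OAT3).

Physiological defaults: hepatic blood flow Q_h = 1617 mL/min, enterocyte
blood flow Q_ent = 300 mL/min, intestinal fluid volume 250 mL.
"""

from __future__ import annotations

from dataclasses import dataclass

from .util import InvalidInputError, mg_to_umol, round_sig, umol_per_ml_to_um

__all__ = [
    "PerpetratorPK",
    "PhysiologyConstants",
    "ExposureSet",
    "dose_micromol",
    "igut",
    "ig_enterocyte",
    "iin_max_unbound",
    "cmax_unbound",
    "exposure_set",
    "report_exposure_cells",
    "exposure_table",
]


@dataclass(frozen=True)
class PerpetratorPK:
    """Dose and steady-state plasma PK of one perpetrator (inhibitor) drug.

    Attributes
    ----------
    name : str
        Drug name.
    dose_mg : float
        Oral dose in mg.
    mw : float
        Molar mass in g/mol.
    cmax_total : float
        Total (bound + unbound) steady-state maximum plasma concentration, μM.
    fu : float
        Unbound fraction in plasma, in (0, 1].
    ka : float
        First-order absorption rate constant, min⁻¹.
    fafg : float
        Fraction absorbed × gut availability, in (0, 1].
    rb : float
        Blood-to-plasma concentration ratio (default 1.0).
    """

    name: str
    dose_mg: float
    mw: float
    cmax_total: float
    fu: float
    ka: float
    fafg: float = 1.0
    rb: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise InvalidInputError(f"{self.name}: dose_mg must be > 0")
        if self.mw <= 0:
            raise InvalidInputError(f"{self.name}: mw must be > 0")
        if not 0 < self.fu <= 1:
            raise InvalidInputError(f"{self.name}: fu must be in (0, 1]")
        if not 0 < self.fafg <= 1:
            raise InvalidInputError(f"{self.name}: fafg must be in (0, 1]")
        if self.ka < 0:
            raise InvalidInputError(f"{self.name}: ka must be >= 0")
        if self.rb <= 0:
            raise InvalidInputError(f"{self.name}: rb must be > 0")
        if self.cmax_total < 0:
            raise InvalidInputError(f"{self.name}: cmax_total must be >= 0")


@dataclass(frozen=True)
class PhysiologyConstants:
    """System parameters of the static exposure model.

    qh: hepatic blood flow (mL/min); qent: enterocyte blood flow (mL/min);
    v_lumen: nominal intestinal fluid volume (mL).
    """

    qh: float = 1617.0
    qent: float = 300.0
    v_lumen: float = 250.0

    def __post_init__(self) -> None:
        if min(self.qh, self.qent, self.v_lumen) <= 0:
            raise InvalidInputError("physiology constants must be strictly positive")


@dataclass(frozen=True)
class ExposureSet:
    """All interaction-site concentrations (μM) for one perpetrator."""

    igut: float
    ig: float
    iin_max: float
    iin_max_u: float
    cmax_u: float


def dose_micromol(pk: PerpetratorPK) -> float:
    """Oral dose converted to μmol."""
    return mg_to_umol(pk.dose_mg, pk.mw)


def igut(pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()) -> float:
    """Theoretical intestinal lumen concentration, dose / 250 mL, in μM."""
    return dose_micromol(pk) / (constants.v_lumen / 1000.0)


def ig_enterocyte(
    pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()
) -> float:
    """Maximum enterocyte concentration I_g = F_aF_g·k_a·dose / Q_ent, μM."""
    return umol_per_ml_to_um(pk.fafg * pk.ka * dose_micromol(pk) / constants.qent)


def iin_max_unbound(
    pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()
) -> tuple[float, float]:
    """Maximum hepatic inlet concentration (total, unbound), both μM.

    I_in,max = C_max + (F_aF_g·k_a·dose / Q_h) / R_B; unbound = f_u·I_in,max.
    """
    inlet = pk.cmax_total + umol_per_ml_to_um(
        (pk.fafg * pk.ka * dose_micromol(pk) / constants.qh) / pk.rb
    )
    return inlet, pk.fu * inlet


def cmax_unbound(pk: PerpetratorPK) -> float:
    """Unbound steady-state maximum plasma concentration f_u·C_max, μM."""
    return pk.fu * pk.cmax_total


def exposure_set(
    pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()
) -> ExposureSet:
    """Compute every interaction-site concentration for one perpetrator."""
    inlet, inlet_u = iin_max_unbound(pk, constants)
    return ExposureSet(
        igut=igut(pk, constants),
        ig=ig_enterocyte(pk, constants),
        iin_max=inlet,
        iin_max_u=inlet_u,
        cmax_u=cmax_unbound(pk),
    )


def report_exposure_cells(
    pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()
) -> ExposureSet:
    """Interaction-site concentrations at report (display) precision.

    The report convention mirrors a summary table assembled column by
    column from display-precision intermediates: the first-pass hepatic
    increment F_aF_g·k_a·dose/Q_h/R_B is held at 4 significant figures
    before C_max is added, each printed cell is rounded to 3 significant
    figures (half away from zero), and the unbound inlet cell is
    f_u × the printed inlet cell.  I_gut is left unrounded (it is reported
    only inside a ratio).  Full-precision values come from
    :func:`exposure_set`.
    """
    ex = exposure_set(pk, constants)
    increment = round_sig(ex.iin_max - pk.cmax_total, 4)
    inlet_cell = round_sig(pk.cmax_total + increment)
    return ExposureSet(
        igut=ex.igut,
        ig=round_sig(ex.ig),
        iin_max=inlet_cell,
        iin_max_u=round_sig(pk.fu * inlet_cell),
        cmax_u=round_sig(ex.cmax_u),
    )


def exposure_table(pks, constants: PhysiologyConstants = PhysiologyConstants()):
    """Exposure summary for several perpetrators as a DataFrame.

    Columns mirror a PK summary table (dose, MW, I_g, C_max, f_u, I_in,max,
    I_in,max,u) with cells at report precision per
    :func:`report_exposure_cells`; I_gut is printed to the nearest μM.
    """
    import pandas as pd

    from .util import round_half_up

    rows = []
    for pk in pks:
        ex = report_exposure_cells(pk, constants)
        rows.append(
            {
                "drug": pk.name,
                "dose_mg": pk.dose_mg,
                "mw": pk.mw,
                "ig_uM": ex.ig,
                "cmax_uM": pk.cmax_total,
                "fu": pk.fu,
                "iin_max_uM": ex.iin_max,
                "iin_max_u_uM": ex.iin_max_u,
                "igut_uM": round_half_up(ex.igut, 0),
                "cmax_u_uM": ex.cmax_u,
            }
        )
    return pd.DataFrame(rows)
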