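"""Reduce raw well-level transporter-assay measurements to percent-control activity.

Two assay formats are supported:

* **Transwell flux** (polarised Caco-2 monolayers, basolateral→apical
  efflux): the amount of probe substrate appearing in the receiver
  compartment gives an apparent permeability
  P_app = amount / (area · time · C₀).  The passive (carrier-independent)
  component — measured under a saturating concentration of the positive
  control inhibitor — is subtracted, and the carrier-mediated remainder is
  expressed as a percentage of the vehicle-control mean within the same
  occasion.  Monolayer integrity is checked with co-incubated lucifer
  yellow (fail if its P_app ≥ 1.0 × 10⁻⁶ cm/s; failed wells are dropped).

* **Uptake** (transporter-transfected vs vector-control cells): probe
  amount per well is normalised to protein content (pmol/mg), the matched
  vector-cell background is subtracted, and the transporter-mediated
  remainder is expressed as percent of vehicle control per occasion.

Reduction is strictly per-occasion: reference means (vehicle, passive,
vector) never mix occasions.  Negative corrected activities clip to zero
(a transport component cannot be negative); percent-control values above
100% are retained unclipped so curve fitting is not biased at the top
plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .util import InvalidInputError, um_to_pmol_per_cm3

__all__ = [
    "FluxWell",
    "UptakeWell",
    "ActivityPoint",
    "LY_DONOR_CONC_UM",
    "LY_PAPP_LIMIT",
    "papp",
    "corrected_carrier_papp",
    "lucifer_yellow_qc",
    "uptake_activity",
    "vector_corrected_uptake",
    "percent_control",
    "positive_control_qc",
    "reduce_flux",
    "reduce_uptake",
    "aggregate_activity",
]

logger = logging.getLogger(__name__)

#: Lucifer yellow donor concentration (μM) and integrity limit (cm/s).
LY_DONOR_CONC_UM = 100.0
LY_PAPP_LIMIT = 1.0e-6

FLUX_COLUMNS = [
    "occasion", "well", "condition_type", "inhibitor_conc_uM",
    "receiver_amount_pmol", "donor_conc_uM", "receiver_volume_mL",
    "time_s", "area_cm2", "ly_amount_pmol",
]
UPTAKE_COLUMNS = [
    "occasion", "well", "cell_line", "condition_type", "inhibitor_conc_uM",
    "amount_pmol", "protein_mg",
]


@dataclass(frozen=True)
class FluxWell:
    """One transwell flux measurement."""

    occasion: str
    condition: str                 # vehicle | test | positive_control | passive_reference
    receiver_amount: float         # pmol
    donor_conc0: float             # μM
    receiver_volume: float         # mL
    time: float                    # s
    area: float = 0.11             # cm²
    inhibitor_conc: float = 0.0    # μM
    ly_receiver_amount: Optional[float] = None  # pmol

    def __post_init__(self) -> None:
        if self.receiver_amount < 0:
            raise InvalidInputError("receiver_amount must be >= 0")
        if self.time <= 0 or self.area <= 0 or self.donor_conc0 <= 0:
            raise InvalidInputError("time, area and donor_conc0 must be > 0")


@dataclass(frozen=True)
class UptakeWell:
    """One uptake measurement (transporter- or vector-cell well)."""

    occasion: str
    cell_line: str                 # transporter | vector
    condition: str
    amount: float                  # pmol
    protein: float                 # mg
    inhibitor_conc: float = 0.0    # μM

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise InvalidInputError("amount must be >= 0")
        if self.protein <= 0:
            raise InvalidInputError("protein must be > 0")


@dataclass(frozen=True)
class ActivityPoint:
    """Percent-of-vehicle-control transport activity at one inhibitor concentration."""

    concentration: float   # μM, 0 for vehicle
    percent_control: float
    occasion: str


def papp(well: FluxWell) -> float:
    """Apparent permeability (cm/s): amount / (area · time · donor concentration)."""
    return well.receiver_amount / (
        well.area * well.time * um_to_pmol_per_cm3(well.donor_conc0)
    )


def corrected_carrier_papp(papp_condition: float, papp_passive: float) -> float:
    """Carrier-mediated P_app after passive subtraction, clipped at zero."""
    diff = papp_condition - papp_passive
    if diff < 0:
        logger.warning(
            "condition P_app %.3g below passive reference %.3g; clipping to 0",
            papp_condition, papp_passive,
        )
        return 0.0
    return diff


def lucifer_yellow_qc(well: FluxWell) -> bool:
    """Monolayer-integrity check: lucifer yellow P_app strictly below the limit.

    Returns True (pass) when LY data are absent, with a warning — the well
    cannot be excluded on missing evidence.
    """
    if well.ly_receiver_amount is None or not np.isfinite(well.ly_receiver_amount):
        logger.warning("no lucifer yellow data for occasion %s; QC skipped", well.occasion)
        return True
    ly_papp = well.ly_receiver_amount / (
        well.area * well.time * um_to_pmol_per_cm3(LY_DONOR_CONC_UM)
    )
    return ly_papp < LY_PAPP_LIMIT


def uptake_activity(well: UptakeWell) -> float:
    """Protein-normalised uptake (pmol/mg)."""
    return well.amount / well.protein


def vector_corrected_uptake(transporter_activity: float, vector_activity: float) -> float:
    """Transporter-mediated uptake after vector-background subtraction, clipped at zero."""
    diff = transporter_activity - vector_activity
    if diff < 0:
        logger.warning(
            "transporter activity %.3g below vector background %.3g; clipping to 0",
            transporter_activity, vector_activity,
        )
        return 0.0
    return diff


def percent_control(corrected_condition: float, corrected_vehicle: float) -> float:
    """Activity as a percentage of the occasion's vehicle-control mean."""
    if corrected_vehicle <= 0:
        raise InvalidInputError(
            "vehicle-control corrected activity is zero; occasion unusable"
        )
    return 100.0 * corrected_condition / corrected_vehicle


def positive_control_qc(percent_inhibition_mean: float, threshold: float = 70.0) -> bool:
    """Assay acceptance: mean positive-control inhibition must reach the threshold (%)."""
    return percent_inhibition_mean >= threshold


def _check_columns(df: pd.DataFrame, required: list[str], optional: tuple[str, ...] = ()) -> None:
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise InvalidInputError(f"missing required column(s): {', '.join(missing)}")


def reduce_flux(wells: pd.DataFrame) -> pd.DataFrame:
    """Reduce a table of transwell flux wells to per-well percent-control activity.

    Parameters
    ----------
    wells : DataFrame
        Columns as in ``wells_flux.csv``: occasion, well, condition_type,
        inhibitor_conc_uM, receiver_amount_pmol, donor_conc_uM,
        receiver_volume_mL, time_s, area_cm2, ly_amount_pmol (optional).

    Returns
    -------
    DataFrame with one row per retained well: occasion, well,
    condition_type, inhibitor_conc_uM, percent_control, n_wells (=1),
    qc_flags.  Lucifer-yellow failures are excluded (flagged rows removed,
    exclusion logged); occasions whose vehicle carrier component is zero
    are dropped with a warning.
    """
    _check_columns(wells, FLUX_COLUMNS, optional=("ly_amount_pmol",))
    out_rows = []
    for occasion, grp in wells.groupby("occasion", sort=False):
        grp = grp.copy()
        grp["papp"] = grp["receiver_amount_pmol"] / (
            grp["area_cm2"] * grp["time_s"] * um_to_pmol_per_cm3(grp["donor_conc_uM"])
        )
        # lucifer-yellow integrity: drop failing wells only, keep the occasion
        if "ly_amount_pmol" in grp.columns and grp["ly_amount_pmol"].notna().any():
            ly_papp = grp["ly_amount_pmol"] / (
                grp["area_cm2"] * grp["time_s"] * um_to_pmol_per_cm3(LY_DONOR_CONC_UM)
            )
            failed = ly_papp.notna() & (ly_papp >= LY_PAPP_LIMIT)
            if failed.any():
                logger.warning(
                    "occasion %s: excluding %d well(s) failing lucifer yellow QC",
                    occasion, int(failed.sum()),
                )
            grp = grp[~failed]
        else:
            logger.warning("occasion %s: no lucifer yellow data; integrity QC skipped", occasion)

        passive_wells = grp[grp["condition_type"] == "passive_reference"]
        if passive_wells.empty:
            logger.warning(
                "occasion %s: no passive-reference wells; no passive subtraction applied",
                occasion,
            )
            passive = 0.0
        else:
            passive = passive_wells["papp"].mean()
        grp["corrected"] = (grp["papp"] - passive).clip(lower=0.0)

        vehicle = grp.loc[grp["condition_type"] == "vehicle", "corrected"].mean()
        if not np.isfinite(vehicle) or vehicle <= 0:
            logger.warning("occasion %s: vehicle carrier component is zero; occasion dropped", occasion)
            continue
        for _, row in grp.iterrows():
            if row["condition_type"] == "passive_reference":
                continue
            out_rows.append(
                {
                    "occasion": occasion,
                    "well": row["well"],
                    "condition_type": row["condition_type"],
                    "inhibitor_conc_uM": row["inhibitor_conc_uM"],
                    "percent_control": 100.0 * row["corrected"] / vehicle,
                    "n_wells": 1,
                    "qc_flags": "",
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["occasion", "well", "condition_type", "inhibitor_conc_uM",
                 "percent_control", "n_wells", "qc_flags"],
    )


def reduce_uptake(wells: pd.DataFrame) -> pd.DataFrame:
    """Reduce a table of uptake wells to per-well percent-control activity.

    Vector-cell background is subtracted condition-matched within the
    occasion (falling back to the occasion's overall vector mean when a
    condition has no vector wells); percent control is relative to the
    vehicle mean of the transporter cells.
    """
    _check_columns(wells, UPTAKE_COLUMNS)
    out_rows = []
    for occasion, grp in wells.groupby("occasion", sort=False):
        grp = grp.copy()
        if (grp["protein_mg"] <= 0).any():
            raise InvalidInputError(f"occasion {occasion}: non-positive protein mass")
        grp["activity"] = grp["amount_pmol"] / grp["protein_mg"]

        vec = grp[grp["cell_line"] == "vector"]
        vec_by_cond = vec.groupby(["condition_type", "inhibitor_conc_uM"])["activity"].mean()
        vec_overall = vec["activity"].mean() if not vec.empty else 0.0
        if vec.empty:
            logger.warning("occasion %s: no vector-control wells; background taken as 0", occasion)

        trans = grp[grp["cell_line"] == "transporter"].copy()

        def background(row):
            key = (row["condition_type"], row["inhibitor_conc_uM"])
            if key in vec_by_cond.index:
                return vec_by_cond.loc[key]
            return vec_overall

        trans["corrected"] = (
            trans["activity"] - trans.apply(background, axis=1)
        ).clip(lower=0.0)
        vehicle = trans.loc[trans["condition_type"] == "vehicle", "corrected"].mean()
        if not np.isfinite(vehicle) or vehicle <= 0:
            logger.warning("occasion %s: vehicle transporter component is zero; occasion dropped", occasion)
            continue
        for _, row in trans.iterrows():
            out_rows.append(
                {
                    "occasion": occasion,
                    "well": row["well"],
                    "condition_type": row["condition_type"],
                    "inhibitor_conc_uM": row["inhibitor_conc_uM"],
                    "percent_control": 100.0 * row["corrected"] / vehicle,
                    "n_wells": 1,
                    "qc_flags": "",
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["occasion", "well", "condition_type", "inhibitor_conc_uM",
                 "percent_control", "n_wells", "qc_flags"],
    )


def aggregate_activity(activity: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary of a per-well activity table (mean %, well count)."""
    agg = (
        activity.groupby(["occasion", "condition_type", "inhibitor_conc_uM"], sort=False)
        .agg(percent_control=("percent_control", "mean"), n_wells=("percent_control", "size"))
        .reset_index()
    )
    return agg
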