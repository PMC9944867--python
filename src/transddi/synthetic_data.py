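"""Seeded generator of well-level assay fixtures with known ground truth.

Emulates the structure of the two assay formats consumed by
:mod:`transddi.assay_reduction` so that reduction, 4PL fitting and
prediction can be exercised end-to-end without external data:

* triplicate wells per condition over a handful of independent occasions;
* 6–7 inhibitor concentrations plus vehicle and positive-control wells;
* a transporter-mediated signal that follows a 4PL of the inhibitor
  concentration, superimposed on a passive (flux) or vector-background
  (uptake) component;
* multiplicative lognormal well noise (assay activities are positive and
  their dispersion is scale-free) and lognormal occasion-to-occasion
  variability applied to the IC50 only.

Defaults mirror the regime of real transporter-inhibition studies:
triplicates, 3 occasions, 10% well CV, 15% inter-occasion IC50 CV.
Determinism: each occasion draws from its own child of a
``numpy.random.SeedSequence``, so occasion blocks are independent and the
whole dataset is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import InvalidInputError, um_to_pmol_per_cm3

__all__ = ["GroundTruth", "generate_flux_dataset", "generate_uptake_dataset"]

#: geometry/time of the flux assay wells emitted by the generator
FLUX_AREA_CM2 = 0.11
FLUX_TIME_S = 5400.0
FLUX_RECEIVER_VOLUME_ML = 0.09
FLUX_DONOR_CONC_UM = 1.0
#: lucifer-yellow permeability of an intact monolayer (cm/s), well below the QC limit
LY_PAPP_INTACT = 0.3e-6
POSITIVE_CONTROL_CONC_UM = 100.0


@dataclass(frozen=True)
class GroundTruth:
    """True data-generating parameters of a synthetic inhibition assay.

    ``carrier_component`` is the transporter-mediated vehicle-control
    activity (P_app in cm/s for flux, pmol/mg for uptake);
    ``passive_component`` is the carrier-independent background in the same
    units.  ``top``/``bottom`` are the 4PL plateaus in percent control.
    """

    ic50: float                    # μM
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    carrier_component: float = 2.0e-6
    passive_component: float = 0.5e-6
    noise_cv: float = 0.10
    occasion_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise InvalidInputError("ic50 must be > 0")
        if not 0 <= self.noise_cv < 1 or not 0 <= self.occasion_cv < 1:
            raise InvalidInputError("noise_cv and occasion_cv must be in [0, 1)")
        if not self.top > self.bottom:
            raise InvalidInputError("top must exceed bottom")
        if self.hill <= 0:
            raise InvalidInputError("hill must be > 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _occasion_rngs(seed: int, n_occasions: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_occasions)]


def _fourpl_fraction(conc: float, truth: GroundTruth, occ_ic50: float) -> float:
    """Fraction of the carrier component remaining at an inhibitor concentration."""
    pct = truth.bottom + (truth.top - truth.bottom) / (
        1.0 + (conc / occ_ic50) ** truth.hill if conc > 0 else 1.0
    )
    return pct / 100.0


def generate_flux_dataset(
    truth: GroundTruth,
    conc_series,
    n_wells: int = 3,
    n_occasions: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic transwell flux wells (schema of ``wells_flux.csv``).

    Per occasion: ``n_wells`` vehicle wells, ``n_wells`` per test
    concentration, and ``n_wells`` passive-reference wells (saturating
    positive control, carrier fully inhibited).  Receiver amounts are
    P_app · area · time · C₀ with multiplicative well noise; every well
    carries an intact-monolayer lucifer-yellow amount.
    """
    conc_series = [float(c) for c in conc_series]
    if not conc_series:
        raise InvalidInputError("concentration series is empty")
    if any(c <= 0 for c in conc_series):
        raise InvalidInputError("test concentrations must be > 0")

    rows = []
    scale = FLUX_AREA_CM2 * FLUX_TIME_S * um_to_pmol_per_cm3(FLUX_DONOR_CONC_UM)
    ly_amount = LY_PAPP_INTACT * FLUX_AREA_CM2 * FLUX_TIME_S * um_to_pmol_per_cm3(100.0)
    for occ_idx, rng in enumerate(_occasion_rngs(seed, n_occasions), start=1):
        occ_ic50 = truth.ic50 * _lognormal_factor(rng, truth.occasion_cv)
        conditions = (
            [("vehicle", 0.0)]
            + [("test", c) for c in conc_series]
            + [("passive_reference", POSITIVE_CONTROL_CONC_UM)]
        )
        well_no = 0
        for cond, conc in conditions:
            if cond == "vehicle":
                papp_true = truth.passive_component + truth.carrier_component * (
                    truth.top / 100.0
                )
            elif cond == "passive_reference":
                papp_true = truth.passive_component
            else:
                papp_true = truth.passive_component + truth.carrier_component * (
                    _fourpl_fraction(conc, truth, occ_ic50)
                )
            noise = _lognormal_factor(rng, truth.noise_cv, size=n_wells)
            for w in range(n_wells):
                well_no += 1
                rows.append(
                    {
                        "occasion": f"occ{occ_idx}",
                        "well": f"occ{occ_idx}-w{well_no}",
                        "condition_type": cond,
                        "inhibitor_conc_uM": conc,
                        "receiver_amount_pmol": papp_true * scale * noise[w],
                        "donor_conc_uM": FLUX_DONOR_CONC_UM,
                        "receiver_volume_mL": FLUX_RECEIVER_VOLUME_ML,
                        "time_s": FLUX_TIME_S,
                        "area_cm2": FLUX_AREA_CM2,
                        "ly_amount_pmol": ly_amount,
                    }
                )
    return pd.DataFrame(rows)


def generate_uptake_dataset(
    truth: GroundTruth,
    conc_series,
    n_wells: int = 3,
    n_occasions: int = 3,
    seed: int = 0,
    protein_mg: float = 0.2,
    protein_cv: float = 0.10,
) -> pd.DataFrame:
    """Synthetic uptake wells (schema of ``wells_uptake.csv``).

    Transporter-cell amounts are (background + carrier·4PL-fraction) ×
    protein × noise; matched vector-cell wells carry background only.
    Protein per well is lognormal around ``protein_mg``.  For a
    single-concentration screen pass ``conc_series`` of length one.
    """
    conc_series = [float(c) for c in conc_series]
    if not conc_series:
        raise InvalidInputError("concentration series is empty")

    rows = []
    for occ_idx, rng in enumerate(_occasion_rngs(seed, n_occasions), start=1):
        occ_ic50 = truth.ic50 * _lognormal_factor(rng, truth.occasion_cv)
        conditions = [("vehicle", 0.0)] + [("test", c) for c in conc_series]
        well_no = 0
        for cell_line in ("transporter", "vector"):
            for cond, conc in conditions:
                if cell_line == "vector":
                    activity_true = truth.passive_component
                elif cond == "vehicle":
                    activity_true = truth.passive_component + truth.carrier_component * (
                        truth.top / 100.0
                    )
                else:
                    activity_true = truth.passive_component + truth.carrier_component * (
                        _fourpl_fraction(conc, truth, occ_ic50)
                    )
                protein = protein_mg * _lognormal_factor(rng, protein_cv, size=n_wells)
                noise = _lognormal_factor(rng, truth.noise_cv, size=n_wells)
                for w in range(n_wells):
                    well_no += 1
                    rows.append(
                        {
                            "occasion": f"occ{occ_idx}",
                            "well": f"occ{occ_idx}-w{well_no}",
                            "cell_line": cell_line,
                            "condition_type": cond,
                            "inhibitor_conc_uM": conc,
                            "amount_pmol": activity_true * protein[w] * noise[w],
                            "protein_mg": protein[w],
                        }
                    )
    return pd.DataFrame(rows)
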