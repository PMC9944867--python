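"""Shared helpers: error type, significant-figure rounding, unit conversions.

Internal unit convention (used throughout the package): concentrations in
μM, amounts in μmol (assay amounts in pmol), volumes in mL, flows in
mL/min, time in min for pharmacokinetic quantities and s for flux assays.
All conversions live here; modules never convert inline.
"""

from __future__ import annotations

import decimal
import math

__all__ = [
    "InvalidInputError",
    "round_sig",
    "round_half_up",
    "mg_to_umol",
    "umol_per_ml_to_um",
    "um_to_pmol_per_cm3",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures, half away from zero.

    Report formatting only — full precision is always retained internally.
    The value is first quantised to 12 significant digits to absorb binary
    floating-point noise (so e.g. an accumulated 25.349999999999998 rounds
    to 25.4, as the decimal arithmetic it stands for would).
    """
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    d = decimal.Decimal(repr(x))
    for places in (12, sig):
        exp = d.adjusted() - places + 1
        d = d.quantize(decimal.Decimal(1).scaleb(exp), rounding=decimal.ROUND_HALF_UP)
    return float(d)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-away-from-zero at a fixed number of decimals."""
    x = float(x)
    if not math.isfinite(x):
        return x
    d = decimal.Decimal(repr(x))
    exp = d.adjusted() - 12 + 1
    d = d.quantize(decimal.Decimal(1).scaleb(exp), rounding=decimal.ROUND_HALF_UP)
    d = d.quantize(decimal.Decimal(1).scaleb(-decimals), rounding=decimal.ROUND_HALF_UP)
    return float(d)


def mg_to_umol(mass_mg: float, mw_g_per_mol: float) -> float:
    """Convert a mass in mg to an amount in μmol given molar mass in g/mol."""
    if mw_g_per_mol <= 0:
        raise InvalidInputError(f"molar mass must be positive, got {mw_g_per_mol}")
    return mass_mg * 1000.0 / mw_g_per_mol


def umol_per_ml_to_um(conc_umol_per_ml: float) -> float:
    """Convert μmol/mL to μM (1 μmol/mL = 1 mM = 1000 μM)."""
    return conc_umol_per_ml * 1000.0


def um_to_pmol_per_cm3(conc_um: float) -> float:
    """Convert μM to pmol/cm³ (1 μM = 1 nmol/mL = 1000 pmol/cm³)."""
    return conc_um * 1000.0
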