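"""Mechanistic static prediction of victim-drug AUC ratios from Ki and exposure.

The victim drug's disposition is decomposed into pathways, each a
transporter at an interaction site (intestinal efflux, hepatic sinusoidal
uptake, renal basolateral uptake) with a fraction-excreted contribution
f_e.  Inhibition of a single pathway changes the victim AUC by the
Rowland–Matin static ratio

    AUCR = 1 / ( f_e / (1 + [I]/Ki) + (1 − f_e) ),                    (single)

with [I] the perpetrator concentration at the site: maximum enterocyte
concentration I_g for intestinal transporters, unbound maximum hepatic
inlet concentration I_in,max,u for hepatic transporters, unbound plasma
C_max,u for renal transporters.  Hepatic uptake transporters (OATP1B1,
OATP1B3, NTCP) are not independent clearance routes but parallel
contributors to one hepatic elimination pathway, so their combined effect
uses the pathway-weighted form

    AUCR = 1 / ( Σ_t f_e,t / (1 + [I]/Ki_t) + (1 − Σ_t f_e,t) ),     (combined)

which reduces to the single form when all [I]/Ki are equal.  The overall
AUCR across sites is the product of the site AUCRs, bounded above by the
product of theoretical maxima Π 1/(1 − f_e).

Regulatory basic static screens are also computed: intestinal
I_gut/Ki ≥ 10 (I_gut = dose/250 mL), hepatic R = 1 + I_in,max,u/Ki ≥ 1.1,
renal C_max,u/Ki ≥ 0.1.

Confidence intervals on Ki propagate anti-monotonically (AUCR falls as Ki
rises): the upper AUCR bound uses the lower Ki bounds and vice versa.

Two rounding conventions are exposed.  Under ``"table"`` each site AUCR is
rounded to two decimals before multiplication (the convention of a report
table whose overall column is the product of its printed site columns);
``"full"`` keeps full precision throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .exposure import ExposureSet
from .inhibition_kinetics import ScreenResult
from .util import InvalidInputError, round_half_up

__all__ = [
    "VictimPathway",
    "VictimModel",
    "KiInput",
    "InteractionAssessment",
    "DDIPrediction",
    "aucr_single",
    "aucr_combined",
    "overall_aucr",
    "theoretical_max_aucr",
    "fraction_of_max_effect",
    "propagate_ci",
    "basic_static_flags",
    "predict",
]

logger = logging.getLogger(__name__)

SITES = ("intestinal", "hepatic", "renal")

#: Regulatory basic static thresholds (compared with >=, on unrounded values).
IGUT_RATIO_THRESHOLD = 10.0
R_VALUE_THRESHOLD = 1.1
CMAXU_RATIO_THRESHOLD = 0.1


@dataclass(frozen=True)
class VictimPathway:
    """One disposition pathway of the victim drug."""

    site: str          # intestinal | hepatic | renal
    transporter: str
    fe: float          # fraction excreted / contribution, 0 <= fe < 1

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise InvalidInputError(f"unknown site {self.site!r}")
        if not 0 <= self.fe < 1:
            raise InvalidInputError("fe must satisfy 0 <= fe < 1")


@dataclass(frozen=True)
class VictimModel:
    """Victim drug disposition model: named pathways plus optional clinical AUCRs."""

    name: str
    pathways: tuple[VictimPathway, ...]
    clinical_aucr: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise InvalidInputError("victim model must declare at least one pathway")
        # intestinal pathways are absorption barriers, not clearance routes,
        # so only hepatic + renal contributions share the unit budget
        clearance_fe = sum(p.fe for p in self.pathways if p.site != "intestinal")
        if clearance_fe > 1 + 1e-12:
            raise InvalidInputError("sum of clearance-site fe values exceeds 1")

    def site_pathways(self, site: str) -> tuple[VictimPathway, ...]:
        return tuple(p for p in self.pathways if p.site == site)


@dataclass(frozen=True)
class KiInput:
    """Inhibition constant for one transporter, with optional 95% CI (μM)."""

    ki: float
    ci95: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise InvalidInputError("ki must be > 0")
        if self.ci95 is not None and not 0 < self.ci95[0] <= self.ci95[1]:
            raise InvalidInputError("ki CI bounds must be positive and ordered")


@dataclass(frozen=True)
class InteractionAssessment:
    """Per-transporter basic-static metrics and mechanistic AUCR."""

    transporter: str
    site: str
    i_used: float
    ki: Optional[float]
    i_over_ki: Optional[float]
    r_value: Optional[float]          # hepatic basic static metric
    intestinal_ratio: Optional[float] # I_gut/Ki, intestinal only
    cmaxu_ratio: Optional[float]      # C_max,u/Ki, renal only
    flagged: bool
    aucr: float
    aucr_ci: Optional[tuple[float, float]]
    no_inhibition: bool = False       # screen-negative, annotated N.A.


@dataclass(frozen=True)
class DDIPrediction:
    """Full static DDI prediction for one perpetrator against one victim."""

    perpetrator: str
    victim: str
    assessments: tuple[InteractionAssessment, ...]
    site_aucrs: Mapping[str, float]
    site_aucr_cis: Mapping[str, tuple[float, float]]
    hepatic_combined_aucr: Optional[float]
    hepatic_combined_ci: Optional[tuple[float, float]]
    overall_aucr: float
    overall_ci: Optional[tuple[float, float]]
    clinical_aucr: Optional[float]
    fold_accuracy: Optional[float]
    convention: str


def aucr_single(fe: float, i: float, ki: float) -> float:
    """Static AUC ratio for inhibition of a single pathway."""
    if not 0 <= fe < 1:
        raise InvalidInputError("fe must satisfy 0 <= fe < 1")
    if i < 0:
        raise InvalidInputError("inhibitor concentration must be >= 0")
    if ki <= 0:
        raise InvalidInputError("ki must be > 0")
    return 1.0 / (fe / (1.0 + i / ki) + (1.0 - fe))


def aucr_combined(
    fe_list: Sequence[float],
    i: float,
    ki_list: Sequence[float],
    form: str = "pathway_weighted",
) -> float:
    """Static AUC ratio for joint inhibition of parallel pathways sharing one [I].

    ``form="pathway_weighted"`` (default) attenuates each pathway by its own
    1 + [I]/Ki before summing the f_e weights.  ``form="shared_denominator"``
    divides the total f_e by 1 + Σ [I]/Ki instead; it is retained for
    comparison only, as it overstates the interaction whenever potencies
    differ across pathways.
    """
    if len(fe_list) != len(ki_list):
        raise InvalidInputError("fe_list and ki_list lengths differ")
    fes = np.asarray(fe_list, dtype=float)
    kis = np.asarray(ki_list, dtype=float)
    if np.any(kis <= 0):
        raise InvalidInputError("all ki must be > 0")
    if np.any((fes < 0) | (fes >= 1)) or fes.sum() >= 1:
        raise InvalidInputError("fe values must be in [0, 1) with sum < 1")
    if i < 0:
        raise InvalidInputError("inhibitor concentration must be >= 0")
    fe_total = fes.sum()
    if form == "pathway_weighted":
        inhibited = float(np.sum(fes / (1.0 + i / kis)))
    elif form == "shared_denominator":
        inhibited = fe_total / (1.0 + float(np.sum(i / kis)))
    else:
        raise InvalidInputError(f"unknown form {form!r}")
    return 1.0 / (inhibited + (1.0 - fe_total))


def overall_aucr(site_aucrs: Sequence[float], convention: str = "table") -> float:
    """Product of site AUCRs.

    Under ``"table"`` each site AUCR is rounded to two decimals before
    multiplying (and the product is left unrounded for the caller to
    format); under ``"full"`` no intermediate rounding is applied.
    """
    if convention == "table":
        vals = [round_half_up(a, 2) for a in site_aucrs]
    elif convention == "full":
        vals = list(site_aucrs)
    else:
        raise InvalidInputError(f"unknown rounding convention {convention!r}")
    return float(np.prod(vals))


def theoretical_max_aucr(fe: float) -> float:
    """Limit of the static AUCR as [I] → ∞: 1/(1 − f_e)."""
    if not 0 <= fe <= 1:
        raise InvalidInputError("fe must be in [0, 1]")
    if fe == 1:
        raise InvalidInputError("fe = 1 gives an unbounded AUCR")
    return 1.0 / (1.0 - fe)


def fraction_of_max_effect(aucr: float, aucr_max: float) -> float:
    """Achieved fraction of a pathway's maximal AUC effect, (AUCR−1)/(AUCR_max−1)."""
    if aucr < 1:
        raise InvalidInputError("aucr must be >= 1")
    if aucr_max <= 1:
        raise InvalidInputError("aucr_max must exceed 1")
    return float(np.clip((aucr - 1.0) / (aucr_max - 1.0), 0.0, 1.0))


def propagate_ci(fe_structure, i: float, ki_ci_per_transporter) -> tuple[float, float]:
    """AUCR interval from Ki confidence intervals.

    AUCR is anti-monotone in Ki, so the lower AUCR bound uses the upper Ki
    bounds and the upper AUCR bound the lower Ki bounds.  ``fe_structure``
    is a single f_e (single-pathway form, ``ki_ci_per_transporter`` a
    (lo, hi) pair) or a sequence of f_e values (combined form, a matching
    sequence of (lo, hi) pairs).
    """
    if np.isscalar(fe_structure):
        lo_ki, hi_ki = ki_ci_per_transporter
        if lo_ki <= 0 or hi_ki < lo_ki:
            raise InvalidInputError("ki CI bounds must be positive and ordered")
        return (aucr_single(fe_structure, i, hi_ki), aucr_single(fe_structure, i, lo_ki))
    fes = list(fe_structure)
    cis = list(ki_ci_per_transporter)
    if len(fes) != len(cis):
        raise InvalidInputError("fe and ki-CI lists differ in length")
    lo = aucr_combined(fes, i, [hi for _, hi in cis])
    hi = aucr_combined(fes, i, [lo for lo, _ in cis])
    return (lo, hi)


def basic_static_flags(
    transporter: str, site: str, exposures: ExposureSet, ki: float
) -> dict:
    """Regulatory basic static metrics for one transporter.

    Intestinal: I_gut/Ki ≥ 10; hepatic: R = 1 + I_in,max,u/Ki ≥ 1.1;
    renal: C_max,u/Ki ≥ 0.1.  Comparisons use unrounded values.
    """
    if ki <= 0:
        raise InvalidInputError("ki must be > 0")
    out = {
        "transporter": transporter,
        "site": site,
        "intestinal_ratio": None,
        "r_value": None,
        "cmaxu_ratio": None,
    }
    if site == "intestinal":
        out["intestinal_ratio"] = exposures.igut / ki
        out["flagged"] = out["intestinal_ratio"] >= IGUT_RATIO_THRESHOLD
    elif site == "hepatic":
        out["r_value"] = 1.0 + exposures.iin_max_u / ki
        out["flagged"] = out["r_value"] >= R_VALUE_THRESHOLD
    elif site == "renal":
        out["cmaxu_ratio"] = exposures.cmax_u / ki
        out["flagged"] = out["cmaxu_ratio"] >= CMAXU_RATIO_THRESHOLD
    else:
        raise InvalidInputError(f"unknown site {site!r}")
    return out


def _site_concentration(site: str, exposures: ExposureSet) -> float:
    return {
        "intestinal": exposures.ig,
        "hepatic": exposures.iin_max_u,
        "renal": exposures.cmax_u,
    }[site]


def predict(
    perpetrator: str,
    victim_model: VictimModel,
    ki_table: Mapping[str, KiInput],
    exposures: ExposureSet,
    screen_results: Mapping[str, ScreenResult] | None = None,
    convention: str = "table",
    combined_form: str = "pathway_weighted",
) -> DDIPrediction:
    """Predict the victim AUC ratio for one perpetrator.

    Every victim pathway must be covered either by a Ki (``ki_table``,
    keyed by transporter) or by a screen-based no-inhibition verdict
    (``screen_results``).  Screen-negative transporters contribute
    [I]/Ki = 0 — they stay in the f_e bookkeeping with AUCR 1.0 rather
    than being dropped.  Hepatic pathways combine through the
    pathway-weighted form; the overall AUCR is the product over sites
    (two-decimal intermediate rounding under the ``"table"`` convention).
    """
    screen_results = screen_results or {}
    assessments: list[InteractionAssessment] = []
    site_aucrs: dict[str, float] = {}
    site_cis: dict[str, tuple[float, float]] = {}
    hepatic_combined = None
    hepatic_combined_ci = None

    # i/ki (with CI) per pathway, validating evidence coverage
    def pathway_inputs(p: VictimPathway):
        if p.transporter in ki_table:
            k = ki_table[p.transporter]
            return k.ki, k.ci95, False
        if p.transporter in screen_results:
            s = screen_results[p.transporter]
            if s.inhibitor:
                raise InvalidInputError(
                    f"{perpetrator}: screen marks {p.transporter} an inhibitor; "
                    "an IC50 determination is required"
                )
            return None, None, True
        raise InvalidInputError(
            f"{perpetrator}: no Ki and no screen verdict for transporter {p.transporter}"
        )

    for site in SITES:
        pathways = victim_model.site_pathways(site)
        if not pathways:
            continue
        i_site = _site_concentration(site, exposures)
        per_path = []
        for p in pathways:
            ki, ci, negative = pathway_inputs(p)
            if negative:
                aucr, aucr_ci = 1.0, None
                flags = {"intestinal_ratio": None, "r_value": None,
                         "cmaxu_ratio": None, "flagged": False}
            else:
                aucr = aucr_single(p.fe, i_site, ki)
                aucr_ci = propagate_ci(p.fe, i_site, ci) if ci else None
                flags = basic_static_flags(p.transporter, site, exposures, ki)
            assessments.append(
                InteractionAssessment(
                    transporter=p.transporter,
                    site=site,
                    i_used=i_site,
                    ki=ki,
                    i_over_ki=(i_site / ki) if ki else None,
                    r_value=flags["r_value"],
                    intestinal_ratio=flags["intestinal_ratio"],
                    cmaxu_ratio=flags["cmaxu_ratio"],
                    flagged=flags["flagged"],
                    aucr=aucr,
                    aucr_ci=aucr_ci,
                    no_inhibition=negative,
                )
            )
            per_path.append((p, ki, ci, negative))

        if site == "hepatic" and len(per_path) > 1:
            fes = [p.fe for p, *_ in per_path]
            # screen-negative pathways enter with an effectively infinite Ki
            kis = [ki if ki is not None else np.inf for _, ki, _, _ in per_path]
            site_aucr = aucr_combined(fes, i_site, kis, form=combined_form)
            cis = [
                ci if ci is not None else (np.inf, np.inf)
                for _, ki, ci, _ in per_path
            ]
            site_ci = propagate_ci(fes, i_site, cis)
            hepatic_combined = site_aucr
            hepatic_combined_ci = site_ci
        else:
            # independent pathways at one site: product of single-pathway AUCRs
            site_aucr = float(np.prod([a.aucr for a in assessments if a.site == site]))
            lo = float(np.prod([a.aucr_ci[0] if a.aucr_ci else a.aucr
                                for a in assessments if a.site == site]))
            hi = float(np.prod([a.aucr_ci[1] if a.aucr_ci else a.aucr
                                for a in assessments if a.site == site]))
            site_ci = (lo, hi)
        site_aucrs[site] = site_aucr
        site_cis[site] = site_ci

    overall = overall_aucr(list(site_aucrs.values()), convention)
    overall_ci = (
        overall_aucr([site_cis[s][0] for s in site_aucrs], convention),
        overall_aucr([site_cis[s][1] for s in site_aucrs], convention),
    )
    clinical = victim_model.clinical_aucr.get(perpetrator)
    fold = (overall / clinical) if clinical else None
    return DDIPrediction(
        perpetrator=perpetrator,
        victim=victim_model.name,
        assessments=tuple(assessments),
        site_aucrs=site_aucrs,
        site_aucr_cis=site_cis,
        hepatic_combined_aucr=hepatic_combined,
        hepatic_combined_ci=hepatic_combined_ci,
        overall_aucr=overall,
        overall_ci=overall_ci,
        clinical_aucr=clinical,
        fold_accuracy=fold,
        convention=convention,
    )
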