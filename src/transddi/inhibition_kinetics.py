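"""Concentration–inhibition fitting and occasion-level IC50 statistics.

Percent-control activity y versus inhibitor concentration c is described by
the four-parameter logistic (4PL)

    y(c) = bottom + (top − bottom) / (1 + (c / IC50)^h),

fitted per occasion by ordinary least squares on the pooled replicate
wells.  IC50 is parameterised as log10(IC50) to enforce positivity; the
Hill slope h is constrained to (0, 10] and top > bottom.

Occasion IC50s are aggregated into mean, sample SD, CV% and a two-sided
95% confidence interval mean ± t_{0.975, n−1} · SD/√n.

Because each assay uses a probe substrate concentration far below its
Michaelis constant (S ≪ Km), the Cheng–Prusoff relation for competitive
inhibition, Ki = IC50 / (1 + S/Km), collapses to Ki ≈ IC50; the mean IC50
is therefore reported as the inhibition constant.  Single-concentration
screens run at ≥10× the relevant unbound exposure support a "no DDI
potential" verdict when activity stays at or above 50% of control: that
implies Ki above the tested concentration and hence [I]/Ki < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .util import InvalidInputError, round_half_up, round_sig

__all__ = [
    "ProbeAssayDesign",
    "FourPLFit",
    "InhibitionSummary",
    "ScreenResult",
    "KiEstimate",
    "FitError",
    "fourpl",
    "fit_4pl",
    "fit_occasions",
    "ic50_as_ki",
    "aggregate_occasions",
    "t_quantile_975",
    "interpret_screen",
    "report_rounded",
    "summary_table",
]

logger = logging.getLogger(__name__)

#: Hill slope upper bound and screen "no inhibition" cutoff (% control).
HILL_MAX = 10.0
SCREEN_CUTOFF_PERCENT = 50.0


@dataclass(frozen=True)
class ProbeAssayDesign:
    """Probe-substrate design of one transporter inhibition assay."""

    transporter: str
    probe: str
    probe_conc: float          # μM
    probe_km: float            # μM
    incubation_min: float = 0.0
    positive_control: str = ""
    positive_control_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.probe_conc <= 0 or self.probe_km <= 0:
            raise InvalidInputError("probe_conc and probe_km must be > 0")


@dataclass(frozen=True)
class FourPLFit:
    """Result of one 4PL fit (one occasion)."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    extrapolated: bool


@dataclass(frozen=True)
class KiEstimate:
    """IC50 interpreted as an inhibition constant.

    ``ki`` is the mean IC50; when the probe concentration is not far below
    Km the Cheng–Prusoff-adjusted value IC50/(1 + S/Km) is attached as
    ``cheng_prusoff_adjusted`` and ``condition_ok`` is False.
    """

    ki: float
    condition_ok: bool
    cheng_prusoff_adjusted: float


@dataclass(frozen=True)
class InhibitionSummary:
    """Occasion-level IC50 statistics for one drug × transporter pair."""

    transporter: str
    occasion_ic50s: tuple[float, ...]
    n: int
    mean: float
    sd: Optional[float]
    cv_percent: Optional[float]
    ci95: Optional[tuple[float, float]]
    t_quantile: Optional[float]

    @property
    def ki(self) -> float:
        """Mean IC50 taken as the inhibition constant (S ≪ Km)."""
        return self.mean


@dataclass(frozen=True)
class ScreenResult:
    """Verdict of a single-concentration inhibition screen."""

    transporter: str
    tested_conc: float
    mean_percent_control: float
    inhibitor: bool
    ki_lower_bound: Optional[float]
    no_ddi_potential: bool


class FitError(RuntimeError):
    """4PL fit failed to converge; carries initialization and data summary."""


def fourpl(conc, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the four-parameter logistic at concentration(s) ``conc`` (μM)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("concentration must be >= 0")
    if ic50 <= 0 or hill <= 0 or not top > bottom:
        raise InvalidInputError("require ic50 > 0, hill > 0, top > bottom")
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / ic50) ** hill, 0.0)
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


def _init_ic50(conc: np.ndarray, y: np.ndarray, top: float, bottom: float) -> float:
    """Initial IC50: concentration nearest half-maximal activity, log-interpolated."""
    pos = conc > 0
    cs = np.unique(conc[pos])
    means = np.array([y[conc == c].mean() for c in cs])
    mid = 0.5 * (top + bottom)
    # find adjacent pair bracketing the midpoint (activity decreases with conc)
    for i in range(len(cs) - 1):
        y0, y1 = means[i], means[i + 1]
        if (y0 - mid) * (y1 - mid) <= 0 and y0 != y1:
            f = (y0 - mid) / (y0 - y1)
            return float(10 ** (np.log10(cs[i]) + f * (np.log10(cs[i + 1]) - np.log10(cs[i]))))
    # no crossing: nearest concentration, else geometric mid-range
    if len(cs):
        return float(cs[np.argmin(np.abs(means - mid))])
    return float(np.sqrt(conc[pos].min() * conc[pos].max()))


def fit_4pl(points) -> FourPLFit:
    """Fit the 4PL to pooled activity points of one occasion.

    Parameters
    ----------
    points : sequence of ActivityPoint, or DataFrame with columns
        ``inhibitor_conc_uM``/``concentration`` and ``percent_control``.

    Requires at least four distinct non-zero concentrations plus vehicle
    coverage of the top plateau (vehicle points are included at c = 0).
    """
    if isinstance(points, pd.DataFrame):
        cc = "inhibitor_conc_uM" if "inhibitor_conc_uM" in points.columns else "concentration"
        conc = points[cc].to_numpy(dtype=float)
        y = points["percent_control"].to_numpy(dtype=float)
    else:
        conc = np.array([p.concentration for p in points], dtype=float)
        y = np.array([p.percent_control for p in points], dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("negative inhibitor concentration")
    n_distinct = len(np.unique(conc[conc > 0]))
    if n_distinct < 4:
        raise InvalidInputError(
            f"need >= 4 distinct non-zero concentrations, got {n_distinct}"
        )

    top0 = float(y.max())
    bottom0 = float(y.min())
    span0 = max(top0 - bottom0, 1e-6)
    ic50_0 = _init_ic50(conc, y, top0, bottom0)
    x0 = np.array([top0, span0, np.log10(ic50_0), 1.0])

    def residuals(x):
        top, span, log_ic50, hill = x
        bottom = top - span
        ic50 = 10.0 ** log_ic50
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(conc > 0, (conc / ic50) ** hill, 0.0)
        return bottom + span / (1.0 + ratio) - y

    lo = [-np.inf, 1e-9, -12.0, 1e-3]
    hi = [np.inf, np.inf, 12.0, HILL_MAX]
    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    if not res.success:
        raise FitError(
            f"4PL fit did not converge (status {res.status}): init top={top0:.3g}, "
            f"bottom={bottom0:.3g}, ic50={ic50_0:.3g}, hill=1; "
            f"{len(y)} points, {n_distinct} concentrations, "
            f"activity range [{y.min():.3g}, {y.max():.3g}]%"
        )
    top, span, log_ic50, hill = res.x
    ic50 = float(10.0 ** log_ic50)
    extrapolated = bool(ic50 > conc.max() or y[conc > 0].min() > 50.0)
    if extrapolated:
        logger.warning("fitted IC50 %.3g uM extrapolates beyond the tested range", ic50)
    return FourPLFit(
        top=float(top), bottom=float(top - span), ic50=ic50, hill=float(hill),
        rss=float(2.0 * res.cost), converged=True, extrapolated=extrapolated,
    )


def fit_occasions(activity: pd.DataFrame) -> dict[str, FourPLFit]:
    """One pooled-replicate 4PL fit per occasion of a reduced activity table."""
    fits: dict[str, FourPLFit] = {}
    for occasion, grp in activity.groupby("occasion", sort=False):
        fits[str(occasion)] = fit_4pl(grp)
    return fits


def ic50_as_ki(fit_mean: float, design: ProbeAssayDesign) -> KiEstimate:
    """Interpret a mean IC50 as the inhibition constant Ki.

    Accepted outright when probe concentration S ≤ Km/5 (competitive
    inhibition, Cheng–Prusoff correction ≤ 20%); otherwise the adjusted
    value IC50/(1 + S/Km) is annotated and a substrate-depletion warning
    logged.
    """
    adjusted = fit_mean / (1.0 + design.probe_conc / design.probe_km)
    ok = design.probe_conc <= design.probe_km / 5.0
    if not ok:
        logger.warning(
            "%s: probe S=%.3g uM not << Km=%.3g uM; IC50 ≈ Ki questionable "
            "(Cheng–Prusoff adjusted value %.3g uM)",
            design.transporter, design.probe_conc, design.probe_km, adjusted,
        )
    return KiEstimate(ki=fit_mean, condition_ok=ok, cheng_prusoff_adjusted=adjusted)


def t_quantile_975(df: float) -> float:
    """Two-sided 95% Student-t quantile (0.975 upper point) at ``df`` degrees of freedom."""
    if df < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    return float(stats.t.ppf(0.975, df))


def aggregate_occasions(
    occasion_ic50s: Sequence[float], transporter: str = ""
) -> InhibitionSummary:
    """Mean / SD / CV% / 95% CI of per-occasion IC50s.

    CI = mean ± t_{0.975, n−1} · SD/√n with the sample SD.  With a single
    occasion only the mean is defined.
    """
    vals = tuple(float(v) for v in occasion_ic50s)
    if len(vals) < 1:
        raise InvalidInputError("need at least one occasion IC50")
    n = len(vals)
    mean = float(np.mean(vals))
    if n == 1:
        return InhibitionSummary(transporter, vals, 1, mean, None, None, None, None)
    sd = float(np.std(vals, ddof=1))
    cv = 100.0 * sd / mean
    t = t_quantile_975(n - 1)
    half = t * sd / np.sqrt(n)
    return InhibitionSummary(
        transporter, vals, n, mean, sd, cv, (mean - half, mean + half), t
    )


def interpret_screen(
    mean_percent_control: float, tested_conc: float, transporter: str = ""
) -> ScreenResult:
    """Verdict of a single-concentration screen run at ≥10× the relevant [I].

    Percent control strictly below 50% marks the drug an inhibitor of the
    transporter (a full IC50 series is warranted).  Otherwise the tested
    concentration is a lower bound on Ki, so [I]/Ki < 0.1 and the
    transporter carries no DDI potential for this drug.
    """
    if tested_conc <= 0:
        raise InvalidInputError("tested_conc must be > 0")
    inhibitor = mean_percent_control < SCREEN_CUTOFF_PERCENT
    return ScreenResult(
        transporter=transporter,
        tested_conc=tested_conc,
        mean_percent_control=mean_percent_control,
        inhibitor=inhibitor,
        ki_lower_bound=None if inhibitor else tested_conc,
        no_ddi_potential=not inhibitor,
    )


def report_rounded(s: InhibitionSummary) -> dict:
    """Summary statistics under the report (printed-table) convention.

    Mean and SD are rounded to 3 significant figures; CV% and the CI are
    then derived *from the rounded values* (CV to one decimal place, CI
    half-width t·SD/√n rounded to 3 significant figures before being
    applied), all rounding half away from zero.  This is the convention of
    a summary table prepared at fixed display precision, and downstream
    predictions made "from the table" consume exactly these numbers.
    """
    mean_r = round_sig(s.mean)
    out = {"n": s.n, "mean": mean_r, "sd": None, "cv_percent": None, "ci95": None}
    if s.sd is not None:
        sd_r = round_sig(s.sd)
        half_r = round_sig(s.t_quantile * sd_r / np.sqrt(s.n))
        out["sd"] = sd_r
        out["cv_percent"] = round_half_up(100.0 * sd_r / mean_r, 1)
        out["ci95"] = (round_sig(mean_r - half_r), round_sig(mean_r + half_r))
    return out


def summary_table(summaries: dict[tuple[str, str], InhibitionSummary]) -> pd.DataFrame:
    """IC50 summary table, one row per (drug, transporter), report-convention cells."""
    rows = []
    for (drug, transporter), s in summaries.items():
        r = report_rounded(s)
        rows.append(
            {
                "drug": drug,
                "transporter": transporter,
                "occasion_ic50s": ";".join(f"{v:g}" for v in s.occasion_ic50s),
                "n": s.n,
                "mean": r["mean"],
                "sd": r["sd"] if r["sd"] is not None else "",
                "cv_percent": r["cv_percent"] if r["cv_percent"] is not None else "",
                "ci_lo": r["ci95"][0] if r["ci95"] else "",
                "ci_hi": r["ci95"][1] if r["ci95"] else "",
            }
        )
    return pd.DataFrame(rows)
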