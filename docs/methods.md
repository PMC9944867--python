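# Methods

## Scope and model

`transddi` predicts the fold change in a victim drug's plasma AUC caused by
a perpetrator inhibiting the victim's disposition transporters. The model
is static: each interaction site sees one theoretical maximum perpetrator
concentration, time courses are not simulated, and induction, metabolism
and time-dependent inhibition are out of scope. The victim is described by
pathways `(site, transporter, f_e)` where f_e is the fraction of the
absorption barrier (intestinal site) or of clearance (hepatic, renal)
attributable to that transporter. Intestinal pathways are absorption
barriers, so only hepatic + renal f_e values share the unit budget; the
packaged rosuvastatin model uses BCRP 0.5 (intestinal), OATP1B1 0.38,
OATP1B3 0.11, NTCP 0.21 (hepatic, totalling 0.70), OAT3 0.25 (renal).

Single-pathway inhibition follows the Rowland–Matin ratio
`AUCR = 1/(f_e/(1+[I]/Ki) + 1−f_e)`, monotone in [I], anti-monotone in Ki,
bounded by `1/(1−f_e)`. The hepatic uptake transporters are parallel
contributors to one elimination pathway, so multiplying their individual
AUCRs is not meaningful; the combined form weights each pathway's f_e by
its own attenuation: `AUCR = 1/(Σ f_e,t/(1+[I]/Ki,t) + 1−Σ f_e,t)`. An
alternative sometimes written with a shared denominator,
`1/(f_e,tot/(1+Σ[I]/Ki,t) + 1−f_e,tot)`, is exposed behind
`form="shared_denominator"` for comparison only: it treats potencies as
additive across pathways and overstates the interaction whenever they
differ (for atazanavir's hepatic pathways it gives 2.72 versus 1.74 for
the pathway-weighted form, and only the latter is consistent with the
single-pathway limits). The overall AUCR is the product of site AUCRs.

Interaction-site concentrations: enterocyte `I_g = F_aF_g·k_a·dose/Q_ent`
for intestinal transporters (the mechanistic model's [I]; the regulatory
screen instead uses lumen `I_gut = dose/250 mL`), unbound hepatic inlet
`I_in,max,u = f_u·(C_max + (F_aF_g·k_a·dose/Q_h)/R_B)` for hepatic uptake,
and unbound systemic `C_max,u = f_u·C_max` for renal uptake. Defaults:
Q_h = 1617 mL/min, Q_ent = 300 mL/min, lumen volume 250 mL, R_B = 1 when
unknown. Internal units are μM, μmol, mL, mL/min and minutes; conversions
are centralized in `util`. Packaged PK: the atazanavir absorption rate
constant is not tabulated in its source, so k_a = 0.1 min⁻¹ is used — the
value that exactly back-reproduces the packaged enterocyte (142 μM) and
inlet (35.0 μM) concentrations when the I_g formula is inverted by hand;
darunavir/lopinavir use k_a = 0.02, ritonavir 0.003. F_aF_g = 1 for all
four. Ritonavir is modelled at its 100 mg booster dose, the dose from
which all its packaged exposure values derive.

## Assay reduction

Flux wells: `P_app = amount/(area·time·C₀)` (cm/s), single-timepoint under
sink conditions (no cumulative-sampling correction). The passive component
is the occasion's mean P_app under the saturating positive-control
concentration; it is subtracted and the remainder clipped at zero — a
transport component cannot be negative, and the 4PL tolerates a zero
floor. Uptake wells: pmol/mg after protein normalisation, with the
condition-matched vector-cell mean subtracted (falling back to the
occasion's overall vector mean when a condition lacks vector wells).
Percent control is relative to the occasion's vehicle mean; values above
100% are deliberately left unclipped so the fitted top plateau is not
biased. All reference means are arithmetic means of the replicate wells
within one occasion; occasions never mix, and reference pooling across
occasions (a defensible alternative) is not implemented. Monolayer
integrity: wells whose lucifer-yellow P_app is not strictly below
1.0 × 10⁻⁶ cm/s are excluded individually (the occasion survives); missing
LY data passes with a warning. Positive-control inhibition below a
configurable threshold (default 70%) fails assay QC. Radioactivity inputs
must arrive as pmol via a declared specific-activity conversion; because
that factor cancels in percent control, reduction is invariant to it
(tested).

## 4PL fitting and occasion statistics

Per occasion, ordinary unweighted least squares on the pooled replicate
points fits `y = bottom + (top−bottom)/(1+(c/IC50)^h)`. Parameterisation:
free parameters are top, span = top−bottom (≥ 0, enforcing top > bottom),
log10 IC50 (enforcing positivity, bounded ±12) and Hill slope h ∈
(10⁻³, 10]. Initialisation: top/bottom from the observed extremes, IC50
from log-interpolating the half-maximal crossing of per-concentration
means, h = 1. Optimiser: bounded trust-region least squares
(`scipy.optimize.least_squares`); non-convergence raises a diagnostic
error carrying the initialisation and a data summary. Fits are flagged
`extrapolated` when the fitted IC50 exceeds the highest tested
concentration or no tested concentration drove activity below 50%. A
brute-force (IC50, Hill) grid search with exact linear solves for the
plateaus serves as an independent oracle in the tests; at least four
distinct non-zero concentrations plus vehicle are required.

Occasion IC50s aggregate to mean, sample SD, CV% = 100·SD/mean and the
two-sided 95% CI `mean ± t₀.₉₇₅,n−1·SD/√n` (t = 4.303 at n = 3, 3.182 at
n = 4). IC50 is reported as Ki outright when the probe concentration S ≤
Km/5 (the packaged BCRP assay's 7.4-fold margin passes); otherwise the
Cheng–Prusoff-adjusted `IC50/(1+S/Km)` is annotated alongside a warning.
Screens run at ≥10× the relevant unbound exposure: mean percent control
strictly below 50% marks an inhibitor (escalate to a full IC50 series);
at or above 50%, Ki must exceed the tested concentration for any Hill
slope ≥ 1, hence [I]/Ki < 0.1 and the pathway carries no DDI potential.
The 50% cutoff is this package's rule; no numeric criterion is standard.

## Rounding and report conventions

Full precision is kept programmatically everywhere. Report output follows
the conventions of summary tables assembled at display precision, which
the packaged defaults require for cell-exact self-consistency:

* summary cells at 3 significant figures, half away from zero;
* CV% and CI cells derived from the *rounded* mean and SD, the CI
  half-width itself rounded to 3 significant figures before being applied;
* the hepatic inlet's first-pass increment held at 4 significant figures
  before C_max is added; the unbound inlet cell is f_u × the printed inlet
  cell;
* under the default `"table"` convention, site AUCRs round to two decimals
  before multiplying into the overall AUCR (`"full"` suppresses all
  intermediate rounding; the two can differ in the final digit, e.g.
  1.25 vs 1.26 for darunavir).

The default prediction pipeline feeds report-precision Ki values and
exposures into the model — the same numbers a reader of the summary tables
would use — so its output is reproducible from the printed inputs alone.
Threshold comparisons (≥10, ≥1.1, ≥0.1) always use unrounded values.

CI propagation uses anti-monotonicity: the upper AUCR bound from the lower
Ki bounds and vice versa, for the single, combined and overall forms;
screen-negative pathways enter both bounds with [I]/Ki = 0. The bounds
always bracket the point estimate (tested). Note these are not true
confidence intervals for the AUCR — they ignore correlation between
pathway Ki estimates — but a deterministic sensitivity range, which is how
the field reports them.

## Synthetic data

The generator emulates the assay designs end to end: triplicate wells,
6–7 inhibitor concentrations plus vehicle, passive-reference wells at a
saturating positive-control concentration (flux) or matched vector-cell
wells (uptake), intact-monolayer lucifer-yellow amounts, and per-well
multiplicative lognormal noise (mean-one, CV-parameterised — activities
are positive and observed inter-assay CVs are scale-free, roughly 2–37%).
Occasion-to-occasion variability multiplies the IC50 only, lognormally.
Defaults: noise CV 10%, occasion CV 15%, 3 occasions. Each occasion draws
from its own `SeedSequence` child, so datasets are byte-reproducible under
a seed and occasion blocks are independent (adding occasions never changes
earlier ones). Not emulated: counting statistics and radioactive decay,
protein-assay chemistry, monolayer biology, adsorption losses and
concentration-dependent solubility limits — so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to every artefact of real plates.

Test problem sizes: parameter-recovery checks use 200 single-occasion
datasets (truth IC50 log-uniform over 0.1–100 μM, triplicates at 7
concentrations spanning 0.01–100× the IC50, 10% CV), where the median
relative IC50 error is required below 10% and the 95th percentile below
50%; the full flux pipeline (which adds passive-subtraction noise) is
checked at a 15% tolerance on a 3-occasion mean. The grid-search oracle
uses a 400 × 50 log grid.

## Known limitations

* The static model ignores perpetrator time courses; it is deliberately
  conservative for first-pass-driven DDIs.
* Combined-pathway prediction assumes one shared [I] per site and
  independent, competitive inhibition.
* Ki confidence intervals propagate as worst-case ranges, not distributions.
* The victim model's f_e values are treated as exact constants; their
  uncertainty is not propagated.
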