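"""Packaged default inputs and the default prediction pipeline.

The package ships, as plain-text data files, everything needed to run a
complete rosuvastatin DDI assessment for the four protease-inhibitor
perpetrators:

* ``perpetrators.csv`` — dose, molar mass and steady-state plasma PK;
* ``ki_occasions.csv`` — per-occasion IC50 determinations for every
  drug × transporter pair with a measurable concentration–inhibition
  curve (summary statistics are derived by
  :func:`transddi.inhibition_kinetics.aggregate_occasions`);
* ``screens.csv`` — single-concentration screen outcomes where no
  inhibition was observed at ≥10× the relevant unbound exposure (the
  percent-control entry 100.0 encodes the qualitative no-inhibition
  outcome; any value at or above the 50% cutoff yields the same verdict);
* ``victim_rosuvastatin.yaml`` — the rosuvastatin disposition model;
* ``assay_design.yaml`` — probe substrates, concentrations and Km values.

:func:`predict_all` chains these through exposure computation, occasion
aggregation and the mechanistic static model.  Predictions are made at
report precision: Ki means and confidence bounds enter at 3 significant
figures and site concentrations as the 3-significant-figure table cells,
i.e. exactly the numbers a reader of the summary tables would use.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .ddi_prediction import DDIPrediction, KiInput, VictimModel, VictimPathway, predict
from .exposure import (
    ExposureSet,
    PerpetratorPK,
    PhysiologyConstants,
    exposure_set,
    report_exposure_cells,
)
from .inhibition_kinetics import (
    InhibitionSummary,
    ProbeAssayDesign,
    ScreenResult,
    aggregate_occasions,
    interpret_screen,
    report_rounded,
)
from .util import round_sig

__all__ = [
    "load_perpetrators",
    "load_ki_occasions",
    "load_ki_summaries",
    "load_screens",
    "load_victim_model",
    "load_assay_designs",
    "report_exposure_set",
    "default_ki_inputs",
    "predict_all",
]


def _data_path(name: str):
    return resources.files("transddi").joinpath("data", name)


def load_perpetrators(path=None) -> dict[str, PerpetratorPK]:
    """Perpetrator PK table keyed by drug name."""
    df = pd.read_csv(path if path is not None else _data_path("perpetrators.csv"))
    return {
        row["name"]: PerpetratorPK(
            name=row["name"],
            dose_mg=float(row["dose_mg"]),
            mw=float(row["mw"]),
            cmax_total=float(row["cmax_uM"]),
            fu=float(row["fu"]),
            ka=float(row["ka_per_min"]),
            fafg=float(row["fafg"]),
            rb=float(row["rb"]),
        )
        for _, row in df.iterrows()
    }


def load_ki_occasions(path=None) -> dict[tuple[str, str], tuple[float, ...]]:
    """Per-occasion IC50s (μM) keyed by (drug, transporter)."""
    df = pd.read_csv(path if path is not None else _data_path("ki_occasions.csv"))
    return {
        (row["drug"], row["transporter"]): tuple(
            float(v) for v in str(row["occasion_ic50s_uM"]).split(";")
        )
        for _, row in df.iterrows()
    }


def load_ki_summaries(path=None) -> dict[tuple[str, str], InhibitionSummary]:
    """Occasion IC50s aggregated into mean/SD/CV/CI summaries."""
    return {
        (drug, transporter): aggregate_occasions(vals, transporter)
        for (drug, transporter), vals in load_ki_occasions(path).items()
    }


def load_screens(path=None) -> dict[str, dict[str, ScreenResult]]:
    """No-inhibition screen verdicts keyed by drug then transporter."""
    df = pd.read_csv(path if path is not None else _data_path("screens.csv"))
    out: dict[str, dict[str, ScreenResult]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["drug"], {})[row["transporter"]] = interpret_screen(
            float(row["mean_percent_control"]),
            float(row["tested_conc_uM"]),
            row["transporter"],
        )
    return out


def load_victim_model(path=None) -> VictimModel:
    """Victim disposition model from YAML (packaged rosuvastatin by default)."""
    src = path if path is not None else _data_path("victim_rosuvastatin.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        raw = yaml.safe_load(fh)
    return VictimModel(
        name=raw["name"],
        pathways=tuple(
            VictimPathway(site=p["site"], transporter=p["transporter"], fe=float(p["fe"]))
            for p in raw["pathways"]
        ),
        clinical_aucr={k: float(v) for k, v in (raw.get("clinical_aucr") or {}).items()},
    )


def load_assay_designs(path=None) -> dict[str, ProbeAssayDesign]:
    """Probe-assay designs keyed by transporter."""
    src = path if path is not None else _data_path("assay_design.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        raw = yaml.safe_load(fh)
    return {
        transporter: ProbeAssayDesign(
            transporter=transporter,
            probe=d["probe"],
            probe_conc=float(d["probe_conc_uM"]),
            probe_km=float(d["probe_km_uM"]),
            incubation_min=float(d.get("incubation_min", 0)),
            positive_control=d.get("positive_control", ""),
            positive_control_conc=float(d.get("positive_control_conc_uM", 0)),
        )
        for transporter, d in raw.items()
    }


def report_exposure_set(
    pk: PerpetratorPK, constants: PhysiologyConstants = PhysiologyConstants()
) -> ExposureSet:
    """Interaction-site concentrations at report precision (see exposure module)."""
    return report_exposure_cells(pk, constants)


def default_ki_inputs(
    drug: str, summaries: Optional[dict[tuple[str, str], InhibitionSummary]] = None
) -> dict[str, KiInput]:
    """Report-precision Ki inputs (mean + 95% CI) for one drug."""
    summaries = summaries if summaries is not None else load_ki_summaries()
    out = {}
    for (d, transporter), s in summaries.items():
        if d != drug:
            continue
        r = report_rounded(s)
        out[transporter] = KiInput(ki=r["mean"], ci95=r["ci95"])
    return out


def predict_all(
    convention: str = "table",
    perpetrators: Optional[dict[str, PerpetratorPK]] = None,
    victim: Optional[VictimModel] = None,
    constants: PhysiologyConstants = PhysiologyConstants(),
) -> dict[str, DDIPrediction]:
    """Full default pipeline: one DDI prediction per packaged perpetrator."""
    perpetrators = perpetrators if perpetrators is not None else load_perpetrators()
    victim = victim if victim is not None else load_victim_model()
    summaries = load_ki_summaries()
    screens = load_screens()
    out = {}
    for name, pk in perpetrators.items():
        out[name] = predict(
            perpetrator=name,
            victim_model=victim,
            ki_table=default_ki_inputs(name, summaries),
            exposures=report_exposure_set(pk, constants),
            screen_results=screens.get(name, {}),
            convention=convention,
        )
    return out
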