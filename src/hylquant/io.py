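"""Readers, writers and the pipeline configuration/orchestration layer.

All tables are plain CSV with explicit headers; chains enter as FASTA (an
``offset=<int>`` token in the record description sets the reported
numbering offset). ``run_pipeline`` ties the stages together: digest →
quantify → report, culture kinetics + deconvolution, dose-response fitting
and knockout attribution, as configured.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import kinetics, peptide_core, quant, response
from .kinetics import CultureTimeSeries
from .response import DoseResponsePanel, KOPanel

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_culture_csv",
    "write_culture_csv",
    "read_dose_csv",
    "write_dose_csv",
    "read_ko_csv",
    "write_ko_csv",
    "run_pipeline",
]

CULTURE_COLUMNS = ["day", "vcd_cells_per_ml", "product_mg_per_l", "iron_um",
                   "hyl_fraction"]
DOSE_COLUMNS = ["peptide_id", "iron_um", "replicate", "hyl_fraction"]
KO_COLUMNS = ["condition", "ko_plod1", "ko_plod2", "ko_plod3", "hyl_fraction"]


def read_culture_csv(path) -> CultureTimeSeries:
    df = pd.read_csv(path)
    for col in ("day", "vcd_cells_per_ml"):
        if col not in df.columns:
            raise ValueError(f"culture table {path}: missing column {col!r}")

    def opt(col):
        return df[col].to_numpy(float) if col in df.columns else None

    return CultureTimeSeries(
        t=df["day"].to_numpy(float),
        vcd=df["vcd_cells_per_ml"].to_numpy(float),
        product=opt("product_mg_per_l"),
        iron=opt("iron_um"),
        f_mod=opt("hyl_fraction"),
    )


def write_culture_csv(series: CultureTimeSeries, path) -> None:
    data = {"day": series.t, "vcd_cells_per_ml": series.vcd}
    if series.product is not None:
        data["product_mg_per_l"] = series.product
    if series.iron is not None:
        data["iron_um"] = series.iron
    if series.f_mod is not None:
        data["hyl_fraction"] = series.f_mod
    pd.DataFrame(data).to_csv(path, index=False)


def read_dose_csv(path) -> dict[str, DoseResponsePanel]:
    df = pd.read_csv(path)
    missing = set(DOSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dose table {path}: missing columns {sorted(missing)}")
    panels = {}
    for pid, grp in df.groupby("peptide_id"):
        panels[str(pid)] = DoseResponsePanel(
            concentrations=grp["iron_um"].to_numpy(float),
            responses=grp["hyl_fraction"].to_numpy(float),
            peptide_id=str(pid),
        )
    return panels


def write_dose_csv(panel: DoseResponsePanel, path) -> None:
    reps = {}
    rows = []
    for c, y in zip(panel.concentrations, panel.responses):
        reps[c] = reps.get(c, 0) + 1
        rows.append(dict(peptide_id=panel.peptide_id, iron_um=c,
                         replicate=reps[c], hyl_fraction=y))
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def read_ko_csv(path) -> KOPanel:
    df = pd.read_csv(path)
    missing = set(KO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"KO table {path}: missing columns {sorted(missing)}")
    return KOPanel(
        design=df[["ko_plod1", "ko_plod2", "ko_plod3"]],
        hyl_level=df["hyl_fraction"].to_numpy(float),
        conditions=list(df["condition"].astype(str)),
    )


def write_ko_csv(panel: KOPanel, path) -> None:
    df = panel.design.copy()
    df.insert(0, "condition", list(panel.conditions) if panel.conditions
              else [""] * len(df))
    df["hyl_fraction"] = panel.hyl_level
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML."""

    outdir: str = "hylquant_out"
    fasta: Optional[str] = None
    evidence: Optional[str] = None
    evidence_ko: Optional[str] = None
    culture: Optional[str] = None
    dose_response: Optional[str] = None
    ko_panel: Optional[str] = None

    mod_name: str = "Oxidation"
    mod_delta_mass: float = peptide_core.OXYGEN_MONO
    mod_target_residue: str = "K"
    max_missed_cleavages: int = 1
    quant_floor_pct: float = 0.1
    strict_mc: bool = False
    deconvolution_model: str = "sigmoid"
    ec50_free_hill: bool = False
    ec50_n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not np.isfinite(cfg.mod_delta_mass):
            raise ValueError("mod_delta_mass must be finite")
        for name in ("fasta", "evidence", "evidence_ko", "culture",
                     "dose_response", "ko_panel"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name}: no such file {p!r}")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; write reports and a summary JSON.

    Returns the machine-readable summary (also written to
    ``<outdir>/summary.json``). Any stage failure raises StageError naming
    the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("hylquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("run_pipeline seed=%d outdir=%s", config.seed, out)

    try:
        if config.evidence is not None:
            stage = "quant"
            try:
                evidence = quant.read_evidence_csv(config.evidence)
                report = quant.locus_report(
                    evidence, quant_floor_pct=config.quant_floor_pct,
                    strict_mc=config.strict_mc,
                )
                report.to_csv(out / "locus_report.csv", index=False)
                loci = {}
                for (cid, site), grp in report.groupby(["chain_id", "site"]):
                    loci[f"{cid}:K{site}"] = float(
                        grp.loc[grp.cleaved == "sum", "value"].iloc[0]
                    )
                summary["locus_pct"] = loci
                if config.evidence_ko is not None:
                    ko_evidence = quant.read_evidence_csv(config.evidence_ko)
                    reductions = {}
                    for key in loci:
                        cid, s = key.rsplit(":K", 1)
                        try:
                            wt = quant.quantify_locus(evidence, cid, int(s))
                            ko = quant.quantify_locus(ko_evidence, cid, int(s))
                            reductions[key] = quant.reduction(wt, ko).reduction_pct_rounded
                        except ValueError:
                            reductions[key] = None
                    summary["hyl_reduction_pct"] = reductions
                summary["stages"].append(stage)
            except StageError:
                raise
            except Exception as e:
                raise StageError(stage, e) from e

        if config.culture is not None:
            stage = "kinetics"
            try:
                series = read_culture_csv(config.culture)
                rates = kinetics.rate_report(series)
                df = pd.DataFrame({"day": rates.t, "ivcd_cell_day_per_ml": rates.ivcd})
                if rates.iron_per_cell is not None:
                    df["iron_fmol_per_cell"] = rates.iron_per_cell
                df.to_csv(out / "culture_per_sample.csv", index=False)
                dfi = pd.DataFrame({"t_mid": rates.t_mid})
                if rates.qp is not None:
                    dfi["qp_pg_per_cell_day"] = rates.qp
                    dfi["dp_mg_per_l"] = rates.dp
                if rates.qs_iron is not None:
                    dfi["qs_iron_fmol_per_cell_day"] = rates.qs_iron
                dfi.to_csv(out / "culture_per_interval.csv", index=False)
                summary["ivcd_final"] = float(rates.ivcd[-1])
                summary["stages"].append(stage)

                if series.f_mod is not None and series.product is not None:
                    stage = "deconvolve"
                    nf = kinetics.newly_formed_fraction(series)
                    fit = kinetics.fit_newly_formed(
                        series, model=config.deconvolution_model
                    )
                    pd.DataFrame(
                        {"t_mid": nf.t_mid, "g_exact": nf.g, "g_fitted": fit.g}
                    ).to_csv(out / "newly_formed.csv", index=False)
                    summary["newly_formed_params"] = {
                        k: float(v) for k, v in fit.params.items()
                    }
                    summary["stages"].append(stage)
            except StageError:
                raise
            except Exception as e:
                raise StageError(stage, e) from e

        if config.dose_response is not None:
            stage = "dose-response"
            try:
                panels = read_dose_csv(config.dose_response)
                rows = []
                for pid, panel in sorted(panels.items()):
                    fit = response.fit_ec50(
                        response.normalize_panel(panel),
                        free_hill=config.ec50_free_hill,
                        n_boot=config.ec50_n_boot,
                        seed=config.seed,
                    )
                    rows.append(dict(peptide_id=pid, ec50_um=fit.ec50,
                                     baseline=fit.baseline,
                                     ci95_lo=fit.ci95[0], ci95_hi=fit.ci95[1],
                                     sse=fit.residual_sse))
                pd.DataFrame(rows).to_csv(out / "ec50_fits.csv", index=False)
                summary["ec50_um"] = {r["peptide_id"]: r["ec50_um"] for r in rows}
                summary["stages"].append(stage)
            except StageError:
                raise
            except Exception as e:
                raise StageError(stage, e) from e

        if config.ko_panel is not None:
            stage = "attribute"
            try:
                panel = read_ko_csv(config.ko_panel)
                est = response.plod_contribution(panel)
                pd.DataFrame(
                    [
                        dict(term=k, coefficient=est.coefficients[k],
                             share_pct=est.shares_pct[k])
                        for k in est.coefficients
                    ]
                ).to_csv(out / "plod_contribution.csv", index=False)
                summary["plod_shares_pct"] = est.shares_pct
                summary["plod_wt_level"] = est.intercept
                if est.flags:
                    summary["plod_flags"] = est.flags
                summary["stages"].append(stage)
            except StageError:
                raise
            except Exception as e:
                raise StageError(stage, e) from e
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
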