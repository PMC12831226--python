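"""End-to-end orchestration: simulate/load two tissues, QC, discovery EWAS,
trans-tissue scoring and association in both directions, GWS-locus subsets,
and the confounder-MRS battery."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

import transmrs
from transmrs import io as tio
from transmrs.covariates import (
    build_covariate_set,
    compare_cell_proportions,
    estimate_cell_proportions,
    estimate_surrogate_variables,
    slide_associated_pcs,
)
from transmrs.datasets import MethylationDataset
from transmrs.ewas import run_ewas
from transmrs.qc import QcThresholds, beta_to_m, run_qc
from transmrs.scoring import (
    PT_THRESHOLDS,
    comeback_prune,
    compute_mrs,
    intersect_sites,
    subset_by_loci,
)
from transmrs.assoc import mrs_association
from transmrs.synthdata import (
    SimulationConfig,
    generate_gws_loci,
    generate_paired_datasets,
    generate_reference_panel,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

SUBSET_MODES = ("all", "exclude-gws", "include-gws")


class QcOptions(BaseModel):
    beadnum_samples: float = 0.1
    detectionp_samples: float = 0.1
    beadnum_cpgs: float = 0.1
    detectionp_cpgs: float = 0.1
    sex_outlier_sd: float = 10.0
    probe_detection_p: float = 0.01
    min_beads: int = 3
    samples_first: bool = True
    check_sex: bool = True

    def thresholds(self) -> QcThresholds:
        return QcThresholds(
            beadnum_samples=self.beadnum_samples,
            detectionp_samples=self.detectionp_samples,
            beadnum_cpgs=self.beadnum_cpgs,
            detectionp_cpgs=self.detectionp_cpgs,
            sex_outlier_sd=self.sex_outlier_sd,
            probe_detection_p=self.probe_detection_p,
            min_beads=self.min_beads,
        )


class CovariateOptions(BaseModel):
    enabled: bool = True
    max_pcs: int = 10
    pc_alpha: float = 0.05
    cell_alpha: float = 0.05
    always_admit_cells: list[str] = Field(default_factory=list)
    n_sv: int | Literal["auto"] = 0
    use_age: bool = True
    use_sex: bool = True


class RunConfig(BaseModel):
    """Single-file configuration of the whole trans-tissue experiment."""

    mode: Literal["simulate", "load"] = "simulate"
    seed: int = 0
    sim: SimulationConfig = Field(default_factory=SimulationConfig)
    dir_a: Optional[str] = None
    dir_b: Optional[str] = None
    panel_path: Optional[str] = None
    loci_path: Optional[str] = None
    n_loci: int = Field(8, ge=0)
    thresholds: list[float] = Field(default_factory=lambda: list(PT_THRESHOLDS))
    prune_window: int = Field(2000, gt=0)
    prune_rho: float = Field(0.3, ge=0, le=1)
    subset_modes: list[str] = Field(default_factory=lambda: list(SUBSET_MODES))
    confounder_phenotypes: list[str] = Field(default_factory=list)
    confounder_discovery: str = "tissueB"
    adjust_diagnosis_in_confounder_ewas: bool = True
    qc: QcOptions = Field(default_factory=QcOptions)
    covariates: CovariateOptions = Field(default_factory=CovariateOptions)
    mrs_scale: Literal["m", "beta"] = "m"
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if sorted(self.thresholds) != list(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if self.thresholds[-1] != 1:
            raise ValueError("the last threshold must be 1")
        bad = set(self.subset_modes) - set(SUBSET_MODES)
        if bad:
            raise ValueError(f"unknown subset modes: {sorted(bad)}")
        if self.mode == "load" and not (self.dir_a and self.dir_b):
            raise ValueError("load mode requires dir_a and dir_b")
        return self

    def config_hash(self) -> str:
        # the output location does not affect results
        payload = self.model_dump(exclude={"out_dir"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class RunReport:
    """Structured result: association rows plus QC summaries and provenance."""

    def __init__(self, rows: list[dict], qc: dict, provenance: dict):
        self.rows = rows
        self.qc = qc
        self.provenance = provenance

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "qc": self.qc, "rows": self.rows}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        with open(outdir / "report.tsv", "w") as fh:
            fh.write(f"# config_hash={self.provenance['config_hash']}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _tissue_covariates(ds: MethylationDataset, panel, opts: CovariateOptions, seed: int):
    """Cell proportions, admitted cell types, slide PCs, optional SVs."""
    if not opts.enabled:
        return None, {}
    props, _ = estimate_cell_proportions(ds, panel)
    comparison = compare_cell_proportions(
        ds, props, alpha=opts.cell_alpha, always_admit=tuple(opts.always_admit_cells)
    )
    admitted = comparison.loc[comparison["admitted"], "cell_type"].tolist()
    # drop one admitted cell type if all were admitted (proportions sum to 1)
    if len(admitted) == props.shape[1] and len(admitted) > 1:
        admitted = admitted[:-1]
    pcs, pc_table = slide_associated_pcs(
        ds.beta, ds.samples["slide"], alpha=opts.pc_alpha, max_pcs=opts.max_pcs
    )
    svs = None
    if opts.n_sv != 0:
        m = beta_to_m(ds.beta)
        svs = estimate_surrogate_variables(
            m, ds.samples["diagnosis"], covariates=None, n_sv=opts.n_sv, seed=seed
        )
    covset = build_covariate_set(
        ds.samples,
        cell_admitted=props[admitted] if admitted else None,
        pcs=pcs if len(pcs.columns) else None,
        svs=svs if svs is not None and len(svs.columns) else None,
        use_age=opts.use_age,
        use_sex=opts.use_sex,
    )
    info = {
        "cell_admitted": admitted,
        "pcs_selected": list(pcs.columns),
        "n_sv": 0 if svs is None else len(svs.columns),
        "columns": covset.columns,
    }
    return covset, info


def _direction_rows(
    direction: str,
    family: str,
    mode: str,
    assoc_result,
    n_pruned: int,
) -> list[dict]:
    rows = []
    for _, r in assoc_result.table.iterrows():
        skip = r["skip_reason"]
        if not skip and pd.isna(r["p"]) and r["separation"]:
            skip = "separation"
        rows.append(
            {
                "direction": direction,
                "family": family,
                "mode": mode,
                "threshold": float(r["threshold"]),
                "n_sites": None if pd.isna(r["n_sites"]) else int(r["n_sites"]),
                "n_pruned_universe": n_pruned,
                "n": int(r["n"]),
                "p": None if pd.isna(r["p"]) else float(r["p"]),
                "delta_r2": float(r["delta_r2"]),
                "r2_covariates": float(r["r2_covariates"]),
                "r2_full": float(r["r2_full"]),
                "direction_of_effect": r["direction"],
                "separation": bool(r["separation"]),
                "skip_reason": skip,
                "best": bool(r["best"]),
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full two-direction trans-tissue experiment.

    Deterministic for a fixed config + seed.  Partial failures (e.g.
    separation, constant confounders) are recorded as skips.
    """
    if config.mode == "simulate":
        sim = config.sim.model_copy(update={"seed": config.seed})
        ds_a, ds_b, truth = generate_paired_datasets(sim)
        panel = generate_reference_panel(sim)
    else:
        ds_a = tio.load_dataset(config.dir_a, name="tissueA")
        ds_b = tio.load_dataset(config.dir_b, name="tissueB")
        panel = tio.read_table(config.panel_path) if config.panel_path else None
        truth = None

    qc_summaries = {}
    clean = {}
    for ds in (ds_a, ds_b):
        out, rep = run_qc(
            ds,
            config.qc.thresholds(),
            samples_first=config.qc.samples_first,
            check_sex=config.qc.check_sex,
        )
        clean[ds.name] = out
        qc_summaries[ds.name] = rep.to_dict()

    if config.loci_path:
        path = config.loci_path
        loci = (
            tio.read_bed_loci(path) if str(path).endswith(".bed") else tio.read_lead_tsv(path)
        )
    else:
        loci = generate_gws_loci(clean["tissueB"].probes, config.n_loci, seed=config.seed)

    covsets, cov_info = {}, {}
    for name, ds in clean.items():
        covsets[name], cov_info[name] = _tissue_covariates(
            ds, panel, config.covariates, config.seed
        )

    rows: list[dict] = []
    thresholds = tuple(config.thresholds)

    def run_direction(disc_name, targ_name, phenotype_col, family):
        disc, targ = clean[disc_name], clean[targ_name]
        cov = covsets[disc_name]
        cov_table = cov.table if cov is not None else None
        pheno = disc.samples[phenotype_col]
        if phenotype_col != "diagnosis":
            if pd.Series(pheno).nunique() < 2:
                rows.extend(
                    {
                        "direction": f"{disc_name}->{targ_name}", "family": family,
                        "mode": "all", "threshold": float(t), "n_sites": None,
                        "n_pruned_universe": None, "n": 0, "p": None, "delta_r2": None,
                        "r2_covariates": None, "r2_full": None,
                        "direction_of_effect": "none", "separation": False,
                        "skip_reason": f"constant phenotype {phenotype_col}", "best": False,
                    }
                    for t in thresholds
                )
                return
            if config.adjust_diagnosis_in_confounder_ewas:
                diag = disc.samples["diagnosis"].map({"control": 0.0, "case": 1.0})
                cov_table = (
                    pd.concat([cov_table, diag.rename("diagnosis_adj")], axis=1)
                    if cov_table is not None
                    else diag.to_frame("diagnosis_adj")
                )
        m_disc = beta_to_m(disc.beta)
        res = run_ewas(
            m_disc, pheno, covariates=cov_table, probes=disc.probes,
            phenotype_name=f"{disc_name}:{phenotype_col}",
        )
        sites = intersect_sites(res, targ)
        pruned = comeback_prune(
            targ, sites, res, window=config.prune_window, rho=config.prune_rho
        )
        modes = config.subset_modes if family == "diagnosis" else ["all"]
        for mode in modes:
            if mode == "all":
                use_sites = pruned.retained
            else:
                sub_mode = "exclude" if mode == "exclude-gws" else "include"
                use_sites = subset_by_loci(pruned.retained, targ.probes, loci, sub_mode)
            if not use_sites:
                rows.extend(
                    {
                        "direction": f"{disc_name}->{targ_name}", "family": family,
                        "mode": mode, "threshold": float(t), "n_sites": 0,
                        "n_pruned_universe": len(pruned.retained), "n": 0, "p": None,
                        "delta_r2": None, "r2_covariates": None, "r2_full": None,
                        "direction_of_effect": "none", "separation": False,
                        "skip_reason": "no sites in subset", "best": False,
                    }
                    for t in thresholds
                )
                continue
            profile = compute_mrs(
                targ, res, use_sites, thresholds=thresholds, scale=config.mrs_scale
            )
            targ_cov = covsets[targ_name]
            assoc = mrs_association(
                targ.samples["diagnosis"], profile,
                covariates=targ_cov.table if targ_cov is not None else None,
            )
            rows.extend(
                _direction_rows(
                    f"{disc_name}->{targ_name}", family, mode, assoc, len(pruned.retained)
                )
            )

    for disc_name, targ_name in (("tissueA", "tissueB"), ("tissueB", "tissueA")):
        run_direction(disc_name, targ_name, "diagnosis", "diagnosis")

    conf_disc = config.confounder_discovery
    conf_targ = "tissueA" if conf_disc == "tissueB" else "tissueB"
    for conf in config.confounder_phenotypes:
        if conf not in clean[conf_disc].samples.columns:
            rows.append(
                {
                    "direction": f"{conf_disc}->{conf_targ}", "family": conf, "mode": "all",
                    "threshold": None, "n_sites": None, "n_pruned_universe": None, "n": 0,
                    "p": None, "delta_r2": None, "r2_covariates": None, "r2_full": None,
                    "direction_of_effect": "none", "separation": False,
                    "skip_reason": f"phenotype column '{conf}' absent", "best": False,
                }
            )
            continue
        run_direction(conf_disc, conf_targ, conf, conf)

    provenance = {
        "version": transmrs.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "covariates": cov_info,
        "n_loci": len(loci),
    }
    report = RunReport(rows, qc_summaries, provenance)
    if config.out_dir:
        report.save(config.out_dir)
    return report
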