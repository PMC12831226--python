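"""Lean replicate-level experiments used for power / type-I / asymmetry
studies of the trans-tissue analysis (and by the acceptance suite).

These bypass QC (no failures are planted) and run the core chain:
discovery EWAS -> site intersection -> 2-kb pruning -> thresholded MRS ->
logistic association in the target tissue.
"""

from __future__ import annotations

import numpy as np

from transmrs.assoc import mrs_association
from transmrs.ewas import run_ewas
from transmrs.qc import beta_to_m
from transmrs.scoring import comeback_prune, compute_mrs, intersect_sites
from transmrs.synthdata import SimulationConfig, generate_paired_datasets

__all__ = ["trans_tissue_trial", "rejection_rate"]


def trans_tissue_trial(
    config: SimulationConfig,
    directions=(("tissueA", "tissueB"),),
    thresholds=(1.0,),
    prune: bool = True,
):
    """One simulated trans-tissue experiment.

    Returns ``{ "discovery->target": {threshold: (delta_r2, p)} }`` using
    an intercept-only covariate model in the target (the simulated
    cohorts carry no admitted covariates by construction).
    """
    ds_a, ds_b, _ = generate_paired_datasets(config)
    tissues = {"tissueA": ds_a, "tissueB": ds_b}
    out = {}
    for disc_name, targ_name in directions:
        disc, targ = tissues[disc_name], tissues[targ_name]
        m = beta_to_m(disc.beta)
        res = run_ewas(m, disc.samples["diagnosis"], probes=disc.probes)
        sites = intersect_sites(res, targ)
        if prune:
            sites = comeback_prune(targ, sites, res).retained
        profile = compute_mrs(targ, res, sites, thresholds=tuple(thresholds))
        assoc = mrs_association(targ.samples["diagnosis"], profile)
        out[f"{disc_name}->{targ_name}"] = {
            float(r["threshold"]): (float(r["delta_r2"]), float(r["p"]))
            for _, r in assoc.table.iterrows()
        }
    return out


def rejection_rate(
    base_config: SimulationConfig,
    n_reps: int,
    seed: int,
    direction=("tissueA", "tissueB"),
    threshold: float = 1.0,
    alpha: float = 0.05,
    prune: bool = True,
):
    """Fraction of replicates with MRS-term p < alpha at one threshold.

    Replicate r uses simulation seed ``seed * 100000 + r`` so disjoint
    base seeds give disjoint streams.
    """
    hits = 0
    for r in range(n_reps):
        cfg = base_config.model_copy(update={"seed": seed * 100_000 + r})
        trial = trans_tissue_trial(
            cfg, directions=(direction,), thresholds=(threshold,), prune=prune
        )
        _, p = trial[f"{direction[0]}->{direction[1]}"][threshold]
        if np.isfinite(p) and p < alpha:
            hits += 1
    return hits / n_reps
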