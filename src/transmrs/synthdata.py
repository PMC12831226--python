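"""Paired two-tissue methylation simulator with known ground truth.

The generative model per tissue:

1. a bimodal per-CpG baseline defines cell-type reference beta profiles;
2. per-sample cell proportions (Dirichlet) mix the profiles in beta space;
3. the mixture is mapped to the M scale where diagnosis effects, confounder
   effects and slide shifts are added;
4. block-correlated noise (Gaussian copula over latent probe variables)
   gives 2-kb co-methylated CpG blocks with controllable Spearman rho;
5. the result is mapped back to beta and clipped strictly inside (0, 1).

Tissue A's CpG universe can be a random subset of tissue B's, emulating a
450K-within-EPIC platform pair, so that downstream intersection is
exercised.  Detection-p / bead-count failures are planted at configurable
rates; detection failures blank the beta entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from transmrs.datasets import MethylationDataset
from transmrs.qc import BETA_CLIP_EPS, beta_to_m, m_to_beta

__all__ = [
    "ConfounderSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "generate_reference_panel",
    "generate_paired_datasets",
    "generate_gws_loci",
]


class ConfounderSpec(BaseModel):
    """One health-related confounder planted into metadata and methylation."""

    kind: Literal["binary", "continuous"] = "binary"
    prevalence_cases: float = Field(0.5, ge=0, le=1)
    prevalence_controls: float = Field(0.1, ge=0, le=1)
    mean_cases: float = 0.0  # continuous kind, standardized scale
    mean_controls: float = 0.0
    sd: float = Field(1.0, gt=0)
    effect_m: float = 0.0  # M-scale shift per unit of the confounder
    frac_cpgs: float = Field(0.005, ge=0, le=1)


class SimulationConfig(BaseModel):
    """Knobs of the paired-tissue generator.

    ``chrom_layout`` is a list of ``(chromosome, n_probes, spacing_bp)``;
    by default ``n_cpgs`` is split over two autosomes at 800 bp spacing.
    ``cross_tissue_share`` is the fraction of causal CpGs shared between
    the two tissues; ``shared_effect_scale_b`` attenuates the shared
    effect in tissue B (1.0 = fully shared magnitude), which together with
    ``effect_size_m_b`` supports one-way-sharing scenarios.
    """

    seed: int = 0
    n_cases_a: int = Field(30, gt=0)
    n_controls_a: int = Field(30, gt=0)
    n_cases_b: int = Field(30, gt=0)
    n_controls_b: int = Field(30, gt=0)
    n_cpgs: int = Field(2000, gt=0)
    chrom_layout: Optional[list[tuple[str, int, int]]] = None
    frac_causal: float = Field(0.02, ge=0, le=1)
    effect_size_m: float = 1.0
    effect_size_m_b: Optional[float] = None
    shared_effect_scale_b: float = 1.0
    cross_tissue_share: float = Field(0.5, ge=0, le=1)
    block_size: int = Field(5, gt=0)
    block_rho: float = Field(0.6, ge=0, le=1)
    noise_sd: float = Field(0.5, gt=0)
    n_celltypes: int = Field(3, ge=1)
    dirichlet_conc_cases: float | list[float] = 10.0
    dirichlet_conc_controls: float | list[float] = 10.0
    panel_sep_floor: float = Field(0.1, ge=0, lt=1)
    panel_marker_frac: float = Field(0.2, gt=0, le=0.5)
    slide_count: int = Field(2, ge=1)
    slide_sd: float = Field(0.0, ge=0)
    missing_detection_rate: float = Field(0.0, ge=0, le=1)
    missing_bead_rate: float = Field(0.0, ge=0, le=1)
    include_sex_chroms: bool = False
    n_sex_probes: int = Field(40, gt=0)
    tissue_a_fraction: float = Field(1.0, gt=0, le=1)
    confounders: dict[str, ConfounderSpec] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.block_size > self.n_cpgs:
            raise ValueError("block_size may not exceed n_cpgs")
        layout = self.layout()
        if sum(n for _, n, _ in layout) != self.n_cpgs:
            raise ValueError("chrom_layout probe counts must sum to n_cpgs")
        if any(sp <= 0 for _, _, sp in layout):
            raise ValueError("chrom_layout spacing must be positive")
        for conc in (self.dirichlet_conc_cases, self.dirichlet_conc_controls):
            arr = np.atleast_1d(np.asarray(conc, dtype=float))
            if (arr <= 0).any():
                raise ValueError("dirichlet concentrations must be positive")
            if arr.size not in (1, self.n_celltypes):
                raise ValueError("dirichlet concentration length must be 1 or n_celltypes")
        return self

    def layout(self) -> list[tuple[str, int, int]]:
        if self.chrom_layout is not None:
            return [tuple(t) for t in self.chrom_layout]
        half = self.n_cpgs // 2
        return [("chr1", half, 800), ("chr2", self.n_cpgs - half, 800)]

    def dirichlet_conc(self, group: str) -> np.ndarray:
        conc = self.dirichlet_conc_cases if group == "case" else self.dirichlet_conc_controls
        arr = np.atleast_1d(np.asarray(conc, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_celltypes)
        return arr


@dataclass
class GroundTruth:
    """What was planted: causal sites and effects, blocks, mixtures, sex."""

    causal: dict[str, list[str]]  # tissue -> causal CpG ids
    effects: dict[str, pd.Series]  # tissue -> per-CpG true M-scale effect
    blocks: pd.Series  # CpG id -> block id (tissue B universe)
    cell_proportions: dict[str, pd.DataFrame]
    sex: dict[str, pd.Series]
    confounder_sites: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "causal": self.causal,
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "blocks": self.blocks.astype(int).to_dict(),
            "cell_proportions": {
                k: v.round(6).to_dict(orient="index") for k, v in self.cell_proportions.items()
            },
            "sex": {k: v.to_dict() for k, v in self.sex.items()},
            "confounder_sites": self.confounder_sites,
        }


# -- building blocks -------------------------------------------------------


def _rng_for(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=(stream,)))


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Probe annotation for the full (tissue B) universe, 1-based positions."""
    rows = []
    i = 0
    for chrom, n, spacing in config.layout():
        for j in range(n):
            rows.append((f"cg{i:08d}", chrom, (j + 1) * spacing))
            i += 1
    if config.include_sex_chroms:
        for chrom in ("chrX", "chrY"):
            for j in range(config.n_sex_probes):
                rows.append((f"cg{i:08d}", chrom, (j + 1) * 1000))
                i += 1
    df = pd.DataFrame(rows, columns=["cpg", "chrom", "pos"]).set_index("cpg")
    return df


def _autosomal_ids(annotation: pd.DataFrame) -> pd.Index:
    return annotation.index[~annotation["chrom"].isin(("chrX", "chrY"))]


def _baseline_beta(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal baseline: roughly half hypo- (~0.1) and half hyper- (~0.9)."""
    high = rng.random(n) < 0.5
    low_vals = rng.uniform(0.05, 0.15, n)
    high_vals = rng.uniform(0.85, 0.95, n)
    return np.where(high, high_vals, low_vals)


def generate_reference_panel(config: SimulationConfig) -> pd.DataFrame:
    """Cell-type reference beta profiles (cell types x autosomal CpGs).

    Profiles share a bimodal baseline; each cell type flips a disjoint
    marker set of CpGs to the opposite methylation mode, which guarantees
    pairwise mean |delta beta| of about ``2 * panel_marker_frac * 0.8`` —
    checked against ``panel_sep_floor``.
    """
    rng = _rng_for(config.seed, 0)
    annotation = generate_annotation(config)
    auto = _autosomal_ids(annotation)
    m = len(auto)
    base = _baseline_beta(rng, m)
    k = config.n_celltypes
    panel = np.tile(base, (k, 1))
    if k > 1:
        n_marker = max(1, int(round(config.panel_marker_frac * m)))
        perm = rng.permutation(m)
        if n_marker * k > m:
            n_marker = m // k
        for t in range(k):
            markers = perm[t * n_marker : (t + 1) * n_marker]
            panel[t, markers] = np.where(
                base[markers] > 0.5,
                rng.uniform(0.05, 0.15, len(markers)),
                rng.uniform(0.85, 0.95, len(markers)),
            )
        for a in range(k):
            for b in range(a + 1, k):
                sep = float(np.abs(panel[a] - panel[b]).mean())
                if sep < config.panel_sep_floor:
                    raise RuntimeError(
                        f"reference profiles {a} and {b} are not distinguishable "
                        f"(mean |dbeta| {sep:.3f} < floor {config.panel_sep_floor}); "
                        "increase panel_marker_frac"
                    )
    return pd.DataFrame(panel, index=[f"cell{t}" for t in range(k)], columns=auto)


def _block_ids(annotation: pd.DataFrame, block_size: int) -> pd.Series:
    """Assign every CpG (sex probes included) to consecutive per-chromosome blocks."""
    ids = np.empty(len(annotation), dtype=int)
    next_block = 0
    pos = 0
    for chrom, grp in annotation.groupby("chrom", sort=False):
        n = len(grp)
        local = np.arange(n) // block_size
        ids[pos : pos + n] = local + next_block
        next_block += int(local[-1]) + 1
        pos += n
    return pd.Series(ids, index=annotation.index, name="block")


def _block_noise(
    rng: np.random.Generator, n_samples: int, blocks: np.ndarray, rho: float, sd: float
) -> np.ndarray:
    n_blocks = int(blocks.max()) + 1 if blocks.size else 0
    factors = rng.standard_normal((n_samples, n_blocks))
    eps = rng.standard_normal((n_samples, blocks.size))
    z = np.sqrt(rho) * factors[:, blocks] + np.sqrt(1.0 - rho) * eps
    return sd * z


def _simulate_samples(
    rng: np.random.Generator, config: SimulationConfig, prefix: str, n_cases: int, n_controls: int
) -> pd.DataFrame:
    n = n_cases + n_controls
    ids = [f"{prefix}_s{i:03d}" for i in range(n)]
    diagnosis = ["case"] * n_cases + ["control"] * n_controls
    sex = rng.choice(["M", "F"], size=n)
    slide = rng.integers(0, config.slide_count, size=n)
    age = np.round(rng.normal(45, 10, size=n), 1)
    df = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "sex": sex,
            "age": age,
            "slide": [f"slide{s}" for s in slide],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    for name, spec in config.confounders.items():
        is_case = np.asarray([d == "case" for d in diagnosis])
        if spec.kind == "binary":
            p = np.where(is_case, spec.prevalence_cases, spec.prevalence_controls)
            df[name] = (rng.random(n) < p).astype(int)
        else:
            mu = np.where(is_case, spec.mean_cases, spec.mean_controls)
            df[name] = np.round(rng.normal(mu, spec.sd), 4)
    return df


def _select_causal(rng: np.random.Generator, config: SimulationConfig, auto_b: pd.Index,
                   auto_a: pd.Index):
    """Pick shared / tissue-specific causal sites honoring cross_tissue_share."""
    n_causal = int(round(config.frac_causal * config.n_cpgs))
    n_shared = int(round(config.cross_tissue_share * n_causal))
    a_pool = np.asarray(auto_a)
    shared = list(rng.choice(a_pool, size=n_shared, replace=False)) if n_shared else []
    remaining_a = np.setdiff1d(a_pool, shared, assume_unique=False)
    n_spec = n_causal - n_shared
    a_only = list(rng.choice(remaining_a, size=n_spec, replace=False)) if n_spec else []
    remaining_b = np.setdiff1d(np.asarray(auto_b), np.concatenate([shared, a_only]) if shared or a_only else [])
    b_only = list(rng.choice(remaining_b, size=n_spec, replace=False)) if n_spec else []
    return shared, a_only, b_only


def _simulate_tissue(
    rng: np.random.Generator,
    config: SimulationConfig,
    name: str,
    annotation: pd.DataFrame,
    panel: pd.DataFrame,
    blocks: pd.Series,
    effects: pd.Series,
    n_cases: int,
    n_controls: int,
):
    samples = _simulate_samples(rng, config, name, n_cases, n_controls)
    n = len(samples)
    universe = annotation.index
    auto = _autosomal_ids(annotation)
    is_case = (samples["diagnosis"] == "case").to_numpy()

    # cell mixture in beta space
    conc_case = config.dirichlet_conc("case")
    conc_ctrl = config.dirichlet_conc("control")
    props = np.empty((n, config.n_celltypes))
    props[is_case] = rng.dirichlet(conc_case, size=int(is_case.sum()))
    props[~is_case] = rng.dirichlet(conc_ctrl, size=int((~is_case).sum()))
    props_df = pd.DataFrame(props, index=samples.index, columns=panel.index)

    panel_auto = panel[auto].to_numpy()
    mixed_beta = np.clip(props @ panel_auto, BETA_CLIP_EPS, 1 - BETA_CLIP_EPS)
    m_vals = np.log2(mixed_beta / (1 - mixed_beta))
    m_df = pd.DataFrame(m_vals, index=samples.index, columns=auto)

    # diagnosis effect on the M scale
    eff = effects.reindex(auto).fillna(0.0)
    m_df.loc[is_case, :] = m_df.loc[is_case, :].to_numpy() + eff.to_numpy()[None, :]

    # confounder effects
    conf_sites: dict[str, list[str]] = {}
    causal_ids = set(effects.index[effects != 0])
    free = [c for c in auto if c not in causal_ids]
    for cname, spec in config.confounders.items():
        k_sites = int(round(spec.frac_cpgs * len(auto)))
        sites = list(rng.choice(np.asarray(free), size=min(k_sites, len(free)), replace=False))
        conf_sites[cname] = sites
        if sites and spec.effect_m != 0:
            vals = samples[cname].to_numpy(dtype=float)
            m_df.loc[:, sites] = m_df.loc[:, sites].to_numpy() + spec.effect_m * vals[:, None]

    # slide batch shift
    if config.slide_sd > 0:
        shifts = rng.normal(0, config.slide_sd, size=(config.slide_count, len(auto)))
        slide_idx = samples["slide"].str.removeprefix("slide").astype(int).to_numpy()
        m_df.loc[:, :] = m_df.to_numpy() + shifts[slide_idx]

    # sex chromosomes: designed X/Y mean-M contrast (male ~ +2, female ~ -4)
    full_m = pd.DataFrame(0.0, index=samples.index, columns=universe)
    full_m.loc[:, auto] = m_df
    if config.include_sex_chroms:
        is_male = (samples["sex"] == "M").to_numpy()
        x_ids = annotation.index[annotation["chrom"] == "chrX"]
        y_ids = annotation.index[annotation["chrom"] == "chrY"]
        full_m.loc[:, x_ids] = np.where(is_male[:, None], -2.0, 0.0)
        full_m.loc[:, y_ids] = np.where(is_male[:, None], 0.0, -4.0)

    # block-correlated noise on every probe
    block_arr = blocks.reindex(universe).to_numpy()
    full_m.loc[:, :] = full_m.to_numpy() + _block_noise(
        rng, n, block_arr, config.block_rho, config.noise_sd
    )

    beta = m_to_beta(full_m).clip(BETA_CLIP_EPS, 1 - BETA_CLIP_EPS)

    # QC matrices with planted failures
    det = rng.uniform(0, 0.005, size=beta.shape)
    fail = rng.random(beta.shape) < config.missing_detection_rate
    det[fail] = rng.uniform(0.01, 1.0, size=int(fail.sum()))
    beads = rng.poisson(15, size=beta.shape) + 3
    low = rng.random(beta.shape) < config.missing_bead_rate
    beads[low] = rng.integers(0, 3, size=int(low.sum()))
    beta_vals = beta.to_numpy()
    beta_vals[fail] = np.nan

    ds = MethylationDataset(
        beta=pd.DataFrame(beta_vals, index=samples.index, columns=universe),
        detection_p=pd.DataFrame(det, index=samples.index, columns=universe),
        bead_count=pd.DataFrame(beads, index=samples.index, columns=universe),
        samples=samples,
        probes=annotation.copy(),
        name=name,
    )
    return ds, props_df, conf_sites


def generate_paired_datasets(config: SimulationConfig):
    """Generate (tissue A, tissue B, ground truth) under ``config``.

    Deterministic for a fixed seed.  Tissue A's CpG universe is a random
    subset (``tissue_a_fraction``) of tissue B's; sex-chromosome probes, if
    any, are present in both.
    """
    panel = generate_reference_panel(config)
    annotation_b = generate_annotation(config)
    blocks = _block_ids(annotation_b, config.block_size)
    auto_b = _autosomal_ids(annotation_b)

    rng_shared = _rng_for(config.seed, 1)
    n_a = int(round(config.tissue_a_fraction * len(auto_b)))
    auto_a = pd.Index(sorted(rng_shared.choice(np.asarray(auto_b), size=n_a, replace=False)))
    sex_ids = annotation_b.index.difference(auto_b, sort=False)
    annotation_a = annotation_b.loc[annotation_b.index.isin(auto_a.union(sex_ids))]

    shared, a_only, b_only = _select_causal(rng_shared, config, auto_b, auto_a)
    signs = pd.Series(
        rng_shared.choice([-1.0, 1.0], size=len(shared) + len(a_only) + len(b_only)),
        index=shared + a_only + b_only,
    )
    eff_b_size = config.effect_size_m if config.effect_size_m_b is None else config.effect_size_m_b
    effects_a = pd.Series(0.0, index=annotation_a.index)
    effects_b = pd.Series(0.0, index=annotation_b.index)
    for c in shared:
        effects_a[c] = config.effect_size_m * signs[c]
        effects_b[c] = eff_b_size * config.shared_effect_scale_b * signs[c]
    for c in a_only:
        effects_a[c] = config.effect_size_m * signs[c]
    for c in b_only:
        effects_b[c] = eff_b_size * signs[c]

    rng_a = _rng_for(config.seed, 2)
    rng_b = _rng_for(config.seed, 3)
    ds_a, props_a, conf_a = _simulate_tissue(
        rng_a, config, "tissueA", annotation_a, panel, blocks, effects_a,
        config.n_cases_a, config.n_controls_a,
    )
    ds_b, props_b, conf_b = _simulate_tissue(
        rng_b, config, "tissueB", annotation_b, panel, blocks, effects_b,
        config.n_cases_b, config.n_controls_b,
    )
    truth = GroundTruth(
        causal={"tissueA": shared + a_only, "tissueB": shared + b_only},
        effects={"tissueA": effects_a, "tissueB": effects_b},
        blocks=blocks,
        cell_proportions={"tissueA": props_a, "tissueB": props_b},
        sex={"tissueA": ds_a.samples["sex"].copy(), "tissueB": ds_b.samples["sex"].copy()},
        confounder_sites={"tissueA": conf_a, "tissueB": conf_b},  # type: ignore[dict-item]
    )
    return ds_a, ds_b, truth


def generate_gws_loci(annotation: pd.DataFrame, k: int, seed: int, window: int = 100_000):
    """Draw ``k`` lead positions on the annotated chromosomes.

    Returns a :class:`transmrs.scoring.LociSet` with +/- ``window`` bp
    windows clipped at position 1.  Raises if ``k`` exceeds the number of
    distinct available positions.
    """
    from transmrs.scoring import LociSet

    if k < 0:
        raise ValueError("k must be non-negative")
    rng = np.random.default_rng(seed)
    spans = annotation.groupby("chrom", sort=False)["pos"].max()
    choices = []
    for chrom, span in spans.items():
        for pos in range(1, int(span) + 1, 1000):
            choices.append((chrom, pos))
    if k > len(choices):
        raise ValueError(f"cannot place {k} loci on a span of {len(choices)} candidate positions")
    idx = rng.choice(len(choices), size=k, replace=False)
    leads = pd.DataFrame(
        [choices[i] for i in sorted(idx)], columns=["chrom", "pos"]
    )
    return LociSet(leads=leads, window=window)
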