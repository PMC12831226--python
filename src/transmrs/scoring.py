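"""MRS construction: site intersection, 2-kb co-methylation pruning,
p-value-thresholded effect-weighted scoring, and locus subsetting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from transmrs.datasets import MethylationDataset, normalize_chrom
from transmrs.ewas import EwasResult
from transmrs.qc import beta_to_m

__all__ = [
    "PT_THRESHOLDS",
    "IndependentSiteSet",
    "LociSet",
    "MrsProfile",
    "intersect_sites",
    "comeback_prune",
    "compute_mrs",
    "subset_by_loci",
]

#: The seven discovery p-value inclusion thresholds.  Every entry below 1
#: uses a strict ``p < t`` rule; the final 1 uses ``p <= 1`` (all sites).
PT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class IndependentSiteSet:
    """Sites surviving pruning, plus which sites each representative absorbed."""

    retained: list[str]
    clusters: dict[str, list[str]]  # retained id -> pruned ids (excl. itself)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pruned = [c for v in self.clusters.values() for c in v]
        overlap = set(self.retained) & set(pruned)
        if overlap:
            raise ValueError(f"sites both retained and pruned: {sorted(overlap)[:5]}")
        if len(pruned) != len(set(pruned)):
            raise ValueError("a site was pruned into more than one cluster")

    @property
    def all_sites(self) -> list[str]:
        return self.retained + [c for v in self.clusters.values() for c in v]


@dataclass
class LociSet:
    """Lead positions (1-based) with +/- ``window`` bp inclusive windows."""

    leads: pd.DataFrame  # columns chrom, pos
    window: int = 100_000

    def __post_init__(self) -> None:
        if not {"chrom", "pos"} <= set(self.leads.columns):
            raise ValueError("leads must have 'chrom' and 'pos' columns")
        self.leads = self.leads.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.leads)

    def windows(self) -> pd.DataFrame:
        """1-based inclusive windows, clipped at chromosome start (>= 1)."""
        w = self.leads.copy()
        w["start"] = (w["pos"] - self.window).clip(lower=1)
        w["end"] = w["pos"] + self.window
        return w[["chrom", "start", "end", "pos"]]


@dataclass
class MrsProfile:
    """Per-sample scores at each threshold plus per-threshold site counts."""

    scores: pd.DataFrame  # samples x thresholds (columns = float thresholds)
    site_counts: dict[float, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [self.site_counts[t] for t in sorted(self.site_counts)]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("site counts must be non-decreasing in the threshold")

    @property
    def thresholds(self) -> list[float]:
        return list(self.scores.columns)


def intersect_sites(discovery: EwasResult, target: MethylationDataset) -> list[str]:
    """CpGs present in both universes, in target annotation order."""
    disc = set(discovery.cpg_ids)
    out = [c for c in target.cpg_ids if c in disc]
    if not out:
        raise ValueError("discovery and target share no CpG sites")
    return out


def _spearman_columns(beta: pd.DataFrame) -> np.ndarray:
    """Column-standardized average ranks; dot products give Spearman rho."""
    ranks = beta.rank(axis=0, na_option="keep")
    ranks = ranks.fillna(ranks.mean())  # low missingness: mean-rank imputation
    arr = ranks.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    norms = np.sqrt((arr**2).sum(axis=0))
    norms[norms == 0] = np.inf  # constant column correlates with nothing
    return arr / norms


def comeback_prune(
    target: MethylationDataset,
    sites: list[str],
    discovery: EwasResult,
    window: int = 2000,
    rho: float = 0.3,
    chain: bool = True,
) -> IndependentSiteSet:
    """Prune correlated CpGs within ``window`` bp on target beta values.

    Two sites are linked iff they lie on the same chromosome, at most
    ``window`` bp apart, and their target-beta Spearman correlation has
    absolute value >= ``rho``.  With ``chain=True`` linked sites merge by
    transitive closure (connected components); each component keeps the
    site with the smallest discovery p (ties -> smaller position).  With
    ``chain=False`` a greedy clumping by ascending discovery p is used
    instead (each kept site removes only its direct neighbors).
    """
    if target.n_samples < 3:
        raise ValueError("pruning requires at least 3 target samples")
    probes = target.probes.loc[sites]
    if probes[["chrom", "pos"]].isna().any().any():
        missing = probes.index[probes[["chrom", "pos"]].isna().any(axis=1)].tolist()
        raise ValueError(f"sites missing positions: {missing[:5]}")

    order = np.lexsort((probes["pos"].to_numpy(), probes["chrom"].astype(str).to_numpy()))
    ordered = [sites[i] for i in order]
    pos = probes["pos"].to_numpy()[order]
    chrom = probes["chrom"].astype(str).to_numpy()[order]
    std = _spearman_columns(target.beta[ordered])

    pvals = discovery.pvalues().reindex(ordered)
    if pvals.isna().any():
        # sites without a discovery p sort last in representative choice
        pvals = pvals.fillna(np.inf)

    n = len(ordered)
    edges: list[tuple[int, int]] = []
    k = 1
    while True:
        i = np.arange(n - k)
        j = i + k
        near = (chrom[i] == chrom[j]) & (pos[j] - pos[i] <= window)
        if not near.any():
            # positions sorted within chromosome: larger offsets only grow gaps
            break
        ii, jj = i[near], j[near]
        corr = np.abs((std[:, ii] * std[:, jj]).sum(axis=0))
        hit = corr >= rho
        edges.extend(zip(ii[hit].tolist(), jj[hit].tolist()))
        k += 1
        if k >= n:
            break

    if chain:
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        retained, clusters = [], {}
        for members in comps.values():
            rep = min(members, key=lambda i: (pvals.iloc[i], pos[i]))
            retained.append(ordered[rep])
            pruned = [ordered[i] for i in members if i != rep]
            if pruned:
                clusters[ordered[rep]] = pruned
    else:
        neighbors: dict[int, set[int]] = {i: set() for i in range(n)}
        for a, b in edges:
            neighbors[a].add(b)
            neighbors[b].add(a)
        alive = set(range(n))
        retained, clusters = [], {}
        for i in sorted(range(n), key=lambda i: (pvals.iloc[i], pos[i])):
            if i not in alive:
                continue
            alive.discard(i)
            retained.append(ordered[i])
            pruned = [j for j in neighbors[i] if j in alive]
            for j in pruned:
                alive.discard(j)
            if pruned:
                clusters[ordered[i]] = [ordered[j] for j in sorted(pruned)]

    site_pos = {c: i for i, c in enumerate(sites)}
    retained = sorted(retained, key=site_pos.get)
    return IndependentSiteSet(
        retained=retained,
        clusters=clusters,
        params={"window": window, "rho": rho, "correlation": "spearman", "chain": chain},
    )


def threshold_mask(p: pd.Series, t: float) -> pd.Series:
    """Inclusion rule: strict ``p < t`` below 1, ``p <= 1`` at t == 1."""
    return (p <= 1.0) if t >= 1.0 else (p < t)


def compute_mrs(
    target: MethylationDataset,
    discovery: EwasResult,
    sites: IndependentSiteSet | list[str],
    thresholds: tuple[float, ...] = PT_THRESHOLDS,
    scale: str = "m",
) -> MrsProfile:
    """Effect-weighted sums of target methylation at each p threshold.

    ``S_i(t) = sum over sites j with discovery p_j admitted at t of
    effect_j * x_ij`` where ``x`` is the target M-value (default) or beta.
    Missing target methylation is mean-imputed over samples, with the
    number of imputed entries logged in the provenance.
    """
    site_list = sites.retained if isinstance(sites, IndependentSiteSet) else list(sites)
    weights = discovery.weights().reindex(site_list)
    pvals = discovery.pvalues().reindex(site_list)
    missing_w = weights.isna()
    if missing_w.any():
        raise ValueError(
            f"no discovery weights for sites: {list(weights.index[missing_w])[:5]}"
        )
    if scale not in ("m", "beta"):
        raise ValueError("scale must be 'm' or 'beta'")
    x = target.beta[site_list]
    if scale == "m":
        x = beta_to_m(x)
    n_imputed = int(x.isna().to_numpy().sum())
    if n_imputed:
        x = x.fillna(x.mean())

    xv = x.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    scores = {}
    counts = {}
    for t in thresholds:
        mask = threshold_mask(pvals, t).to_numpy()
        counts[float(t)] = int(mask.sum())
        scores[float(t)] = xv[:, mask] @ w[mask]
    if counts[float(thresholds[0])] == 0:
        warnings.warn("no sites pass the smallest threshold; score is 0 with count 0")
    scores_df = pd.DataFrame(scores, index=target.beta.index)
    return MrsProfile(
        scores=scores_df,
        site_counts=counts,
        provenance={
            "discovery": discovery.model,
            "scale": scale,
            "n_sites": len(site_list),
            "n_imputed_entries": n_imputed,
        },
    )


def subset_by_loci(
    sites: list[str],
    probes: pd.DataFrame,
    loci: LociSet,
    mode: str,
) -> list[str]:
    """Sites inside (``mode='include'``) or outside (``'exclude'``) any
    lead +/- window interval (inclusive bounds, 1-based)."""
    if mode not in ("include", "exclude"):
        raise ValueError("mode must be 'include' or 'exclude'")
    ann = probes.loc[sites]
    site_chroms = {normalize_chrom(c) for c in ann["chrom"].unique()}
    if len(loci):
        loci_chroms = {normalize_chrom(c) for c in loci.leads["chrom"].unique()}
        bad = sorted(loci_chroms - site_chroms)
        if bad:
            raise ValueError(
                f"loci chromosomes absent from site annotation: {bad}; "
                f"annotation has {sorted(site_chroms)}"
            )
    pos = ann["pos"].to_numpy()
    chrom = ann["chrom"].map(normalize_chrom).to_numpy()
    inside = np.zeros(len(sites), dtype=bool)
    for _, row in loci.windows().iterrows():
        inside |= (chrom == normalize_chrom(row["chrom"])) & (pos >= row["start"]) & (
            pos <= row["end"]
        )
    chosen = inside if mode == "include" else ~inside
    return [s for s, keep in zip(sites, chosen) if keep]
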