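"""Mass-univariate EWAS: per-CpG OLS of M-values on a phenotype + covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EwasResult",
    "run_ewas",
    "call_genome_wide_significant",
    "genomic_inflation",
    "GWS_THRESHOLD",
]

GWS_THRESHOLD = 9.0e-8


@dataclass
class EwasResult:
    """Per-CpG regression summary: effect of the phenotype term on M-values.

    ``table`` columns: cpg, chrom, pos, effect, se, t, p, n.  Rows are
    sorted by (chrom, pos).  CpGs with zero variance in the fitted subset
    appear as NA rows rather than being dropped.
    """

    table: pd.DataFrame
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["cpg", "chrom", "pos", "effect", "se", "t", "p", "n"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"EwasResult table missing columns: {missing}")
        p = self.table["p"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        se = self.table["se"].dropna()
        if (se <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index(self.table["cpg"])

    def restrict(self, cpgs) -> "EwasResult":
        keep = self.table["cpg"].isin(set(cpgs))
        return EwasResult(self.table.loc[keep].reset_index(drop=True), dict(self.model))

    def weights(self) -> pd.Series:
        return self.table.set_index("cpg")["effect"]

    def pvalues(self) -> pd.Series:
        return self.table.set_index("cpg")["p"]


def _design_matrix(phenotype: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": 1.0, "phenotype": phenotype.astype(float)})
    if covariates is not None and covariates.shape[1] > 0:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # name the offending columns via the near-zero diagonal of R
        _, rmat = np.linalg.qr(mat)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps if diag.size else 0
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] <= tol]
        if not bad:
            bad = list(X.columns)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def run_ewas(
    m: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    probes: pd.DataFrame | None = None,
    phenotype_name: str = "phenotype",
) -> EwasResult:
    """OLS of each CpG's M-values on ``[1, phenotype, covariates]``.

    Samples with a missing phenotype or covariate are dropped listwise;
    samples with missing M at a given CpG are dropped for that CpG only
    (with ``n`` recorded per row).  Two-sided t-test on the phenotype
    coefficient.  ``probes`` supplies chrom/pos for the output and the
    (chrom, pos) row sort; without it rows keep input column order with NA
    coordinates.
    """
    if isinstance(covariates, pd.DataFrame) and covariates.shape[1] == 0:
        covariates = None
    if covariates is not None:
        covariates = covariates.loc[m.index]
    phenotype = phenotype.loc[m.index]
    if phenotype.dtype == object or str(phenotype.dtype) == "category":
        uniq = [u for u in pd.unique(phenotype.dropna())]
        if set(uniq) <= {"case", "control"}:
            phenotype = phenotype.map({"control": 0.0, "case": 1.0})
        else:
            raise ValueError(f"cannot encode non-numeric phenotype values {uniq}")

    keep = ~phenotype.isna()
    if covariates is not None:
        keep &= ~covariates.isna().any(axis=1)
    m_used = m.loc[keep]
    X = _design_matrix(phenotype.loc[keep], None if covariates is None else covariates.loc[keep])
    n, p_design = X.shape
    if phenotype.loc[keep].nunique() < 2:
        raise ValueError("phenotype is constant on the analyzed samples")
    if n <= p_design + 2:
        raise ValueError(f"too few samples (n={n}) for design with {p_design} columns")
    _check_full_rank(X)

    Xv = X.to_numpy(dtype=float)
    Y = m_used.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    pheno_idx = 1  # column order: intercept, phenotype, covariates
    df_resid = n - p_design

    effect = np.full(Y.shape[1], np.nan)
    se = np.full(Y.shape[1], np.nan)
    n_used = np.full(Y.shape[1], n, dtype=int)

    nan_cols = np.isnan(Y).any(axis=0)
    ok = ~nan_cols
    if ok.any():
        Yok = Y[:, ok]
        var_ok = Yok.var(axis=0) > 0
        coefs = xtx_inv @ Xv.T @ Yok
        resid = Yok - Xv @ coefs
        sigma2 = (resid**2).sum(axis=0) / df_resid
        se_ok = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[pheno_idx, pheno_idx])
        eff_ok = coefs[pheno_idx]
        eff_ok[~var_ok] = np.nan
        se_ok[~var_ok] = np.nan
        idx = np.flatnonzero(ok)
        effect[idx] = eff_ok
        se[idx] = se_ok

    for j in np.flatnonzero(nan_cols):  # per-CpG listwise drop, loop is rare
        y = Y[:, j]
        mask = ~np.isnan(y)
        nj = int(mask.sum())
        n_used[j] = nj
        if nj <= p_design + 1 or y[mask].var() == 0:
            continue
        Xj = Xv[mask]
        if np.linalg.matrix_rank(Xj) < p_design:
            continue
        xtxj = np.linalg.inv(Xj.T @ Xj)
        cj = xtxj @ Xj.T @ y[mask]
        rj = y[mask] - Xj @ cj
        s2 = (rj**2).sum() / (nj - p_design)
        effect[j] = cj[pheno_idx]
        se[j] = np.sqrt(s2 * xtxj[pheno_idx, pheno_idx])

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    dfree = n_used - p_design
    pvals = 2 * stats.t.sf(np.abs(tstat), np.maximum(dfree, 1))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvals[np.isnan(tstat)] = np.nan
    se = np.where(se == 0, np.nan, se)

    out = pd.DataFrame(
        {
            "cpg": m.columns,
            "chrom": probes.loc[m.columns, "chrom"].to_numpy() if probes is not None else pd.NA,
            "pos": probes.loc[m.columns, "pos"].to_numpy() if probes is not None else pd.NA,
            "effect": effect,
            "se": se,
            "t": tstat,
            "p": pvals,
            "n": n_used,
        }
    )
    if probes is not None:
        out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    model = {
        "phenotype": phenotype_name,
        "covariates": [] if covariates is None else list(covariates.columns),
        "n_samples": int(n),
    }
    return EwasResult(out, model)


def call_genome_wide_significant(
    res: EwasResult, threshold: float = GWS_THRESHOLD
) -> pd.DataFrame:
    """Rows with p strictly below ``threshold``, sorted ascending by p.

    Adds a ``direction`` column: hyper (effect > 0) / hypo (effect < 0).
    """
    tbl = res.table
    hits = tbl.loc[tbl["p"].notna() & (tbl["p"] < threshold)].copy()
    hits = hits.sort_values("p", kind="mergesort").reset_index(drop=True)
    hits["direction"] = np.where(hits["effect"] > 0, "hyper", "hypo")
    return hits


def genomic_inflation(res: EwasResult) -> float:
    """Genomic inflation factor lambda = median chi2 / chi2(1) median."""
    p = res.table["p"].dropna().to_numpy()
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
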