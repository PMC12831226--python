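"""Covariate construction: reference-based cell deconvolution,
slide-associated principal components, surrogate variables, and the
"admit a cell type only if it differs between groups" rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from transmrs.datasets import MethylationDataset

__all__ = [
    "CovariateSet",
    "estimate_cell_proportions",
    "compare_cell_proportions",
    "slide_associated_pcs",
    "estimate_surrogate_variables",
    "build_covariate_set",
]


@dataclass
class CovariateSet:
    """Design columns per sample with provenance of the admitting rule."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "diagnosis" in self.table.columns:
            raise ValueError("the covariate set must not contain the diagnosis column")
        nun = self.table.nunique()
        constant = list(nun.index[nun <= 1])
        if constant:
            raise ValueError(f"constant covariate columns: {constant}")
        num = self.table.astype(float)
        if num.shape[1] > 1:
            corr = np.corrcoef(num.to_numpy(), rowvar=False)
            iu = np.triu_indices(corr.shape[0], k=1)
            dup = [
                (num.columns[i], num.columns[j])
                for i, j in zip(*iu)
                if abs(corr[i, j]) > 1 - 1e-12
            ]
            if dup:
                raise ValueError(f"perfectly correlated covariate pairs: {dup}")

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)


def _solve_proportions(ata: np.ndarray, atb: np.ndarray, k: int) -> np.ndarray:
    """min 0.5 p'Ap - b'p  s.t.  p >= 0, sum(p) = 1 (SLSQP)."""
    x0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        lambda p: 0.5 * p @ ata @ p - atb @ p,
        x0,
        jac=lambda p: ata @ p - atb,
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0, "jac": lambda p: np.ones(k)}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    p = np.clip(res.x, 0.0, None)
    return p / p.sum()


def estimate_cell_proportions(ds: MethylationDataset, panel: pd.DataFrame):
    """Constrained least-squares deconvolution of each sample on the panel.

    ``panel`` is cell types x CpGs (beta scale).  Per sample, solve for
    non-negative proportions summing to one.  Returns ``(proportions,
    residual_norm)`` where proportions is samples x cell types.
    Requires at least 10 overlapping CpGs.
    """
    overlap = [c for c in panel.columns if c in set(ds.cpg_ids)]
    if len(overlap) < 10:
        raise ValueError(f"only {len(overlap)} CpGs overlap the reference panel (< 10)")
    k = panel.shape[0]
    A = panel[overlap].to_numpy(dtype=float).T  # cpgs x celltypes
    B = ds.beta[overlap].to_numpy(dtype=float)  # samples x cpgs
    props = np.empty((ds.n_samples, k))
    resid = np.empty(ds.n_samples)
    ata_full = A.T @ A
    for i in range(ds.n_samples):
        b = B[i]
        mask = ~np.isnan(b)
        if mask.all():
            ata, atb = ata_full, A.T @ b
        else:
            Am = A[mask]
            ata, atb = Am.T @ Am, Am.T @ b[mask]
        if k == 1:
            p = np.array([1.0])
        else:
            p = _solve_proportions(ata, atb, k)
        props[i] = p
        resid[i] = float(np.linalg.norm(A[mask] @ p - b[mask]))
    props_df = pd.DataFrame(props, index=ds.beta.index, columns=panel.index)
    return props_df, pd.Series(resid, index=ds.beta.index, name="residual_norm")


def compare_cell_proportions(
    ds: MethylationDataset,
    proportions: pd.DataFrame,
    alpha: float = 0.05,
    always_admit: tuple[str, ...] = (),
):
    """Mann-Whitney U per cell type between cases and controls.

    Cell types with p < ``alpha`` are admitted as covariates; names in
    ``always_admit`` (e.g. a NeuN+ fraction for brain data) are admitted
    unconditionally.  Returns a table (cell_type, u, z, p, admitted).
    """
    from transmrs.assoc import mann_whitney

    diag = ds.samples["diagnosis"]
    cases = proportions.loc[diag == "case"]
    controls = proportions.loc[diag == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both diagnostic groups must be non-empty")
    rows = []
    for ct in proportions.columns:
        u, z, p = mann_whitney(controls[ct], cases[ct])
        admitted = bool(p < alpha) or ct in always_admit
        rows.append(dict(cell_type=ct, u=u, z=z, p=p, admitted=admitted))
    return pd.DataFrame(rows)


def _pc_scores(beta: pd.DataFrame, max_pcs: int):
    """Economy PCA scores of the centered sample x CpG matrix via the Gram trick."""
    X = beta.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    X = X - X.mean(axis=0)
    gram = X @ X.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    n_keep = min(max_pcs, (evals > 1e-12).sum())
    scores = evecs[:, :n_keep] * np.sqrt(evals[:n_keep])
    return scores, evals


def slide_associated_pcs(
    beta: pd.DataFrame,
    slides: pd.Series,
    alpha: float = 0.05,
    max_pcs: int = 10,
):
    """PCs of the beta matrix whose scores differ across slides (one-way ANOVA).

    Returns ``(selected_scores, table)``: selected PC scores in variance
    order and the per-PC ANOVA table.  With a single slide the selection
    is empty.
    """
    slides = slides.loc[beta.index]
    groups = slides.unique()
    scores, _ = _pc_scores(beta, max_pcs)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=beta.index, columns=cols)
    if len(groups) < 2:
        return scores_df[[]], pd.DataFrame(columns=["pc", "p", "selected"])
    rows = []
    selected = []
    for col in cols:
        by_slide = [scores_df.loc[slides == g, col].to_numpy() for g in groups]
        if any(len(v) < 2 for v in by_slide):
            p = 1.0
        else:
            p = float(stats.f_oneway(*by_slide).pvalue)
        sel = p < alpha
        rows.append(dict(pc=col, p=p, selected=sel))
        if sel:
            selected.append(col)
    return scores_df[selected], pd.DataFrame(rows)


def estimate_surrogate_variables(
    m: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_sv: int | str = "auto",
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Residual-PCA surrogate variables.

    M is residualized on ``[1, phenotype, covariates]``; SVs are the top
    left singular vectors of the residual matrix (mutually orthogonal).
    ``n_sv='auto'`` selects the count by permutation-based parallel
    analysis (Buja-Eyuboglu style): keep the k-th component while its
    empirical permutation p-value against the k-th eigenvalues of
    column-permuted data is below ``alpha``, stopping at the first failure.
    """
    pheno = pd.Series(phenotype).loc[m.index]
    if pheno.dtype == object:
        pheno = pheno.map({"control": 0.0, "case": 1.0})
    X = pd.DataFrame({"intercept": 1.0, "phenotype": pheno.astype(float)}, index=m.index)
    if covariates is not None and len(pd.DataFrame(covariates).columns):
        X = pd.concat([X, pd.DataFrame(covariates).loc[m.index].astype(float)], axis=1)
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("surrogate-variable model matrix is rank deficient")
    Y = m.to_numpy(dtype=float)
    Y = np.where(np.isnan(Y), np.nanmean(Y, axis=0), Y)
    hat = Xv @ np.linalg.lstsq(Xv, Y, rcond=None)[0]
    R = Y - hat
    max_rank = int(np.linalg.matrix_rank(R))

    gram = R @ R.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    if n_sv == "auto":
        rng = np.random.default_rng(seed)
        k_max = min(max_rank, 10)
        # null: permute raw columns, then residualize, so the permuted
        # matrix carries the identical projection/rank constraint
        proj = Xv @ np.linalg.pinv(Xv)
        perm_evals = np.empty((n_perm, k_max))
        for b in range(n_perm):
            Yp = np.empty_like(Y)
            for j in range(Y.shape[1]):
                Yp[:, j] = Y[rng.permutation(Y.shape[0]), j]
            Rp = Yp - proj @ Yp
            ev = np.linalg.eigvalsh(Rp @ Rp.T)
            perm_evals[b] = np.sort(ev)[::-1][:k_max]
        # empirical permutation p per component: keep while p < alpha
        k = 0
        while k < k_max:
            p_emp = (1 + int((perm_evals[:, k] >= evals[k]).sum())) / (n_perm + 1)
            if p_emp >= alpha:
                break
            k += 1
        n_sv = k
    else:
        n_sv = int(n_sv)
        if n_sv > max_rank:
            raise ValueError(f"n_sv={n_sv} exceeds residual rank {max_rank}")
    if n_sv == 0:
        return pd.DataFrame(index=m.index)
    sv = evecs[:, :n_sv]
    return pd.DataFrame(sv, index=m.index, columns=[f"SV{i + 1}" for i in range(n_sv)])


def build_covariate_set(
    samples: pd.DataFrame,
    cell_admitted: pd.DataFrame | None = None,
    pcs: pd.DataFrame | None = None,
    svs: pd.DataFrame | None = None,
    use_age: bool = True,
    use_sex: bool = True,
) -> CovariateSet:
    """Assemble the covariate design from its admitted pieces.

    Sex is coded M=1/F=0.  Columns that turn out constant on these samples
    are silently dropped (their admitting rule is recorded as 'dropped').
    """
    pieces = {}
    prov = {}
    if use_age and "age" in samples.columns:
        pieces["age"] = samples["age"].astype(float)
        prov["age"] = "age_or_predicted_age"
    if use_sex and "sex" in samples.columns:
        pieces["sex"] = samples["sex"].map({"M": 1.0, "F": 0.0})
        prov["sex"] = "sex"
    table = pd.DataFrame(pieces, index=samples.index)
    for df, rule in ((cell_admitted, "cell_proportion"), (pcs, "slide_pc"), (svs, "surrogate")):
        if df is not None and len(df.columns):
            table = pd.concat([table, df.loc[samples.index]], axis=1)
            prov.update({c: rule for c in df.columns})
    nun = table.nunique()
    for col in list(table.columns):
        if nun[col] <= 1:
            table = table.drop(columns=col)
            prov[col] = "dropped (constant)"
    return CovariateSet(table=table, provenance=prov)
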