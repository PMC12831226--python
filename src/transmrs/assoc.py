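"""Target-tissue association statistics.

Covariate-adjusted logistic regression of diagnosis on MRSs with
Nagelkerke pseudo-R2 and its incremental form, plus the demographic group
tests (Mann-Whitney U, Pearson chi-square without continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from transmrs.scoring import MrsProfile

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "fit_logistic",
    "nagelkerke_r2",
    "mrs_association",
    "standardize_scores",
    "chi_square_2x2",
    "mann_whitney",
]

_ETA_SEPARATION = 25.0  # |linear predictor| beyond this flags (quasi-)separation


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    loglik: float
    loglik_null: float  # intercept-only on the same samples
    n: int
    converged: bool
    separation: bool
    n_iter: int

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.bse[name]
        return float(2 * stats.norm.sf(abs(z)))


@dataclass
class AssociationResult:
    """Per-threshold incremental-R2 summary plus standardized scores."""

    table: pd.DataFrame  # one row per threshold
    z_scores: pd.DataFrame  # samples x thresholds, covariate-corrected z
    best_threshold: float | None
    model: dict = field(default_factory=dict)


def _as_design(X) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    return X


def fit_logistic(y, X, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``X`` must include its intercept column.  Complete or quasi-separation
    (diverging linear predictor) is detected and flagged rather than
    producing spurious estimates; ``bse`` is still reported from the final
    information matrix.
    """
    X = _as_design(X)
    y = np.asarray(pd.Series(y).to_numpy(), dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y contains a single class")
    n, p = X.shape
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xv @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        xtwx = (Xv * w[:, None]).T @ Xv
        grad = Xv.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = Xv @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    pbar = y.mean()
    loglik_null = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    separation = bool(np.max(np.abs(eta)) > _ETA_SEPARATION)
    w = np.maximum(mu * (1 - mu), 1e-12)
    xtwx = (Xv * w[:, None]).T @ Xv
    try:
        cov = np.linalg.inv(xtwx)
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        loglik=loglik,
        loglik_null=loglik_null,
        n=n,
        converged=converged,
        separation=separation,
        n_iter=it,
    )


def nagelkerke_r2(fit: LogisticFit = None, *, ll0: float = None, ll1: float = None,
                  n: int = None) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell R2 rescaled to a [0, 1] maximum.

    ``R2_CS = 1 - exp((2/n)(LL0 - LL1))``;
    ``R2_N = R2_CS / (1 - exp((2/n) LL0))``.
    """
    if fit is not None:
        ll0, ll1, n = fit.loglik_null, fit.loglik, fit.n
    if n is None or n <= 0:
        raise ValueError("n must be positive")
    if ll0 == 0:
        raise ValueError("degenerate null model (LL0 = 0)")
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    r2 = float(r2_cs / denom)
    return min(max(r2, 0.0), 1.0)


def standardize_scores(values, covariates=None) -> pd.Series:
    """Residualize on covariates (intercept always included), then z-scale.

    Residual SD uses ddof = 1.  Raises on zero residual variance.
    """
    s = pd.Series(values).astype(float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    X = np.ones((len(s), 1))
    if covariates is not None:
        C = pd.DataFrame(covariates).astype(float)
        if len(C.columns):
            X = np.column_stack([X, C.to_numpy()])
    coef, *_ = np.linalg.lstsq(X, s.to_numpy(), rcond=None)
    resid = s.to_numpy() - X @ coef
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(1.0, float(s.std(ddof=1))) or not np.isfinite(sd):
        raise ValueError("zero residual variance; score is collinear with covariates")
    return pd.Series(resid / sd, index=s.index)


def mrs_association(
    diagnosis,
    mrs: MrsProfile | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    test: str = "wald",
) -> AssociationResult:
    """Per-threshold nested logistic comparison: covariates vs covariates+MRS.

    Both models use the identical listwise-complete sample set.  Reports the
    MRS-term two-sided p (Wald by default, likelihood-ratio with
    ``test='lrt'``), covariate-only and full Nagelkerke R2, their
    difference, effect direction, and covariate-corrected z-standardized
    scores.  Separation in either model yields an NA p and a flag, not an
    exception.  The threshold with maximal incremental R2 is flagged.
    """
    if test not in ("wald", "lrt"):
        raise ValueError("test must be 'wald' or 'lrt'")
    scores = mrs.scores if isinstance(mrs, MrsProfile) else pd.DataFrame(mrs)
    y = pd.Series(diagnosis)
    if y.dtype == object or str(y.dtype) == "category":
        y = y.map({"control": 0, "case": 1})
    y = y.astype(float)
    y = y.loc[scores.index]

    keep = ~y.isna() & ~scores.isna().any(axis=1)
    if covariates is not None and len(pd.DataFrame(covariates).columns):
        covariates = pd.DataFrame(covariates).loc[scores.index].astype(float)
        keep &= ~covariates.isna().any(axis=1)
    else:
        covariates = None
    yk = y.loc[keep]
    sk = scores.loc[keep]
    ck = covariates.loc[keep] if covariates is not None else None

    X0 = pd.DataFrame({"intercept": 1.0}, index=yk.index)
    if ck is not None:
        X0 = pd.concat([X0, ck], axis=1)
    fit0 = fit_logistic(yk, X0)
    r2_cov = nagelkerke_r2(fit0)

    rows = []
    zcols = {}
    for t in sk.columns:
        score = sk[t]
        if score.std(ddof=0) == 0:
            rows.append(
                dict(threshold=float(t), n_sites=np.nan, n=int(len(yk)), p=1.0,
                     r2_covariates=r2_cov, r2_full=r2_cov, delta_r2=0.0,
                     direction="none", separation=False, skip_reason="constant score")
            )
            zcols[t] = pd.Series(np.nan, index=scores.index)
            continue
        X1 = X0.copy()
        X1["mrs"] = score
        fit1 = fit_logistic(yk, X1)
        sep = fit0.separation or fit1.separation
        r2_full = nagelkerke_r2(fit1)
        if sep:
            p = np.nan
        elif test == "wald":
            p = fit1.wald_p("mrs")
        else:
            lr = 2 * (fit1.loglik - fit0.loglik)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        rows.append(
            dict(
                threshold=float(t),
                n_sites=np.nan,
                n=int(fit1.n),
                p=p,
                r2_covariates=r2_cov,
                r2_full=r2_full,
                delta_r2=r2_full - r2_cov,
                direction="positive" if fit1.params["mrs"] > 0 else "negative",
                separation=sep,
                skip_reason="",
            )
        )
        try:
            z = standardize_scores(score, ck)
        except ValueError:
            z = pd.Series(np.nan, index=yk.index)
        zcols[t] = z.reindex(scores.index)

    table = pd.DataFrame(rows)
    if isinstance(mrs, MrsProfile):
        table["n_sites"] = [mrs.site_counts.get(float(t), np.nan) for t in table["threshold"]]
    valid = table.loc[table["skip_reason"] == ""]
    best = float(valid.loc[valid["delta_r2"].idxmax(), "threshold"]) if len(valid) else None
    table["best"] = table["threshold"] == best
    return AssociationResult(
        table=table,
        z_scores=pd.DataFrame(zcols),
        best_threshold=best,
        model={"test": test, "covariates": [] if ck is None else list(ck.columns)},
    )


def chi_square_2x2(a: float, b: float, c: float, d: float):
    """Pearson chi-square (df = 1, no continuity correction) for a 2x2 table.

    Rows are groups (a, b) and (c, d).  Returns ``(chi2, p, df)``.
    Raises if any marginal total is zero.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mgn == 0 for mgn in margins):
        raise ValueError("all four marginal totals must be positive")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, 1


def mann_whitney(group_a, group_b):
    """Mann-Whitney U: normal approximation, tie-corrected variance,
    continuity correction.

    Returns ``(U, z, p)`` where ``U`` is the U statistic of group B and
    ``z`` is signed so that larger group-B values give positive z.  With
    all values identical across both groups, returns ``(U, 0.0, 1.0)``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_b = ranks[na:].sum()
    u_b = r_b - nb * (nb + 1) / 2.0
    mean_u = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return float(u_b), 0.0, 1.0
    diff = u_b - mean_u
    cc = 0.5 * np.sign(diff)  # continuity correction
    z = (diff - cc) / np.sqrt(var_u) if diff != 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return float(u_b), float(z), min(p, 1.0)
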