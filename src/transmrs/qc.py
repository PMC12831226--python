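"""Sample/probe quality control, sex checks and the beta<->M transform."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from transmrs.datasets import MethylationDataset, normalize_chrom

__all__ = [
    "QcThresholds",
    "QcReport",
    "beta_to_m",
    "m_to_beta",
    "filter_samples",
    "filter_probes",
    "drop_sex_chromosomes",
    "predict_sex_and_flag_outliers",
    "run_qc",
]

BETA_CLIP_EPS = 1e-6


@dataclass(frozen=True)
class QcThresholds:
    """QC cut-offs; defaults follow common array-QC practice.

    ``beadnum_samples``/``detectionp_samples`` are the maximum allowable
    fraction of failing probes per sample; ``beadnum_cpgs``/
    ``detectionp_cpgs`` the maximum fraction of failing samples per probe.
    Fractions strictly greater than the threshold trigger exclusion.
    """

    beadnum_samples: float = 0.1
    detectionp_samples: float = 0.1
    beadnum_cpgs: float = 0.1
    detectionp_cpgs: float = 0.1
    sex_outlier_sd: float = 10.0
    probe_detection_p: float = 0.01
    min_beads: int = 3

    def __post_init__(self) -> None:
        for name in ("beadnum_samples", "detectionp_samples", "beadnum_cpgs", "detectionp_cpgs"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sex_outlier_sd <= 0:
            raise ValueError("sex_outlier_sd must be positive")
        if not 0 < self.probe_detection_p < 1:
            raise ValueError("probe_detection_p must be in (0, 1)")
        if self.min_beads < 0:
            raise ValueError("min_beads must be non-negative")


@dataclass
class QcReport:
    """Exclusions with one primary reason each, plus per-rule counts."""

    excluded_samples: dict = field(default_factory=dict)  # id -> primary reason
    excluded_probes: dict = field(default_factory=dict)  # id -> primary reason
    sample_reasons: dict = field(default_factory=dict)  # id -> all reasons
    probe_reasons: dict = field(default_factory=dict)  # id -> all reasons
    counts: dict = field(default_factory=dict)
    order: tuple = ()

    def merge(self, other: "QcReport") -> "QcReport":
        out = QcReport(
            excluded_samples={**self.excluded_samples, **other.excluded_samples},
            excluded_probes={**self.excluded_probes, **other.excluded_probes},
            sample_reasons={**self.sample_reasons, **other.sample_reasons},
            probe_reasons={**self.probe_reasons, **other.probe_reasons},
            counts={**self.counts},
            order=self.order + other.order,
        )
        for k, v in other.counts.items():
            out.counts[k] = out.counts.get(k, 0) + v
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["order"] = list(d["order"])
        return d

    def summary(self) -> str:
        lines = [f"QC order: {' -> '.join(self.order) or '(none)'}"]
        for k, v in sorted(self.counts.items()):
            lines.append(f"  {k}: {v}")
        lines.append(f"  samples excluded: {len(self.excluded_samples)}")
        lines.append(f"  probes excluded: {len(self.excluded_probes)}")
        return "\n".join(lines)


# -- beta <-> M ------------------------------------------------------------


def beta_to_m(beta, eps: float = BETA_CLIP_EPS):
    """M = log2(beta / (1 - beta)) after clipping beta to [eps, 1 - eps].

    Accepts scalars, arrays, Series or DataFrames; NaN passes through.
    Raises if any value falls outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float) if np.isscalar(beta) else beta
    vals = np.asarray(arr.values if hasattr(arr, "values") else arr, dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and ((finite < 0) | (finite > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(vals, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    m = np.where(np.isnan(vals), np.nan, m)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    vals = np.asarray(m.values if hasattr(m, "values") else m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-vals))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(b)
    return b


# -- filters ---------------------------------------------------------------


def _fail_fractions(ds: MethylationDataset, t: QcThresholds, axis: int):
    """Fractions of bead/detection failures along ``axis`` (1=per sample, 0=per probe)."""
    bead_fail = (ds.bead_count.to_numpy() < t.min_beads).mean(axis=axis)
    det_fail = (ds.detection_p.to_numpy() > t.probe_detection_p).mean(axis=axis)
    return bead_fail, det_fail


def filter_samples(ds: MethylationDataset, t: QcThresholds | None = None):
    """Remove samples whose failing-probe fraction exceeds the thresholds.

    A sample is excluded when its fraction of probes with
    ``bead_count < min_beads`` is strictly greater than ``beadnum_samples``,
    or its fraction with ``detection_p > probe_detection_p`` strictly
    exceeds ``detectionp_samples``.  Retained order is preserved.
    """
    t = t or QcThresholds()
    bead_fail, det_fail = _fail_fractions(ds, t, axis=1)
    bead_bad = bead_fail > t.beadnum_samples
    det_bad = det_fail > t.detectionp_samples
    report = QcReport(order=("samples",))
    for sid, b_bad, d_bad in zip(ds.beta.index, bead_bad, det_bad):
        if not (b_bad or d_bad):
            continue
        reasons = []
        if d_bad:
            reasons.append("detection")
        if b_bad:
            reasons.append("beadcount")
        report.excluded_samples[sid] = reasons[0]
        report.sample_reasons[sid] = reasons
    report.counts["samples_excluded_detection"] = int(
        sum(1 for r in report.excluded_samples.values() if r == "detection")
    )
    report.counts["samples_excluded_beadcount"] = int(
        sum(1 for r in report.excluded_samples.values() if r == "beadcount")
    )
    keep = [s for s in ds.beta.index if s not in report.excluded_samples]
    if not keep:
        raise ValueError(f"{ds.name}: all samples removed by sample QC")
    return ds.select_samples(keep), report


def filter_probes(ds: MethylationDataset, t: QcThresholds | None = None):
    """Remove probes failing detection or bead-count criteria across samples.

    A probe is excluded iff its fraction of samples with
    ``detection_p > probe_detection_p`` strictly exceeds ``detectionp_cpgs``
    or its fraction with ``bead_count < min_beads`` strictly exceeds
    ``beadnum_cpgs``.  When both rules fire the primary reason is detection.
    """
    t = t or QcThresholds()
    bead_fail, det_fail = _fail_fractions(ds, t, axis=0)
    bead_bad = bead_fail > t.beadnum_cpgs
    det_bad = det_fail > t.detectionp_cpgs
    report = QcReport(order=("probes",))
    for cpg, b_bad, d_bad in zip(ds.beta.columns, bead_bad, det_bad):
        if not (b_bad or d_bad):
            continue
        reasons = []
        if d_bad:
            reasons.append("detection")
        if b_bad:
            reasons.append("beadcount")
        report.excluded_probes[cpg] = reasons[0]
        report.probe_reasons[cpg] = reasons
    report.counts["probes_excluded_detection"] = int(
        sum(1 for r in report.excluded_probes.values() if r == "detection")
    )
    report.counts["probes_excluded_beadcount"] = int(
        sum(1 for r in report.excluded_probes.values() if r == "beadcount")
    )
    keep = [c for c in ds.beta.columns if c not in report.excluded_probes]
    if not keep:
        raise ValueError(f"{ds.name}: all probes removed by probe QC")
    return ds.select_probes(keep), report


def drop_sex_chromosomes(ds: MethylationDataset) -> MethylationDataset:
    """Remove probes on chromosomes X/Y (accepting chrX / 23 / X dialects)."""
    chroms = ds.probes["chrom"].map(normalize_chrom)
    keep = ds.probes.index[~chroms.isin(("X", "Y"))]
    if len(keep) == 0:
        warnings.warn(f"{ds.name}: all probes are sex-chromosomal; empty probe set")
    return ds.select_probes(keep)


# -- sex prediction --------------------------------------------------------


def _two_means_1d(values: np.ndarray):
    """Exact 1-d 2-means: split sorted values minimizing within-cluster SS.

    Returns (labels, means) with label 1 = higher cluster.
    """
    order = np.argsort(values)
    v = values[order]
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    best_k, best_ss = 1, np.inf
    for k in range(1, n):  # first k points in cluster 0
        s0, s1 = csum[k - 1], total - csum[k - 1]
        ss = -(s0 * s0) / k - (s1 * s1) / (n - k)
        if ss < best_ss:
            best_ss, best_k = ss, k
    labels = np.zeros(n, dtype=int)
    labels[order[best_k:]] = 1
    means = np.array([values[labels == 0].mean(), values[labels == 1].mean()])
    return labels, means


def predict_sex_and_flag_outliers(
    ds: MethylationDataset,
    t: QcThresholds | None = None,
    min_cluster_gap: float = 1.0,
) -> pd.DataFrame:
    """Predict sex from the X/Y mean-M contrast and flag outliers/mismatches.

    Per sample, ``s = mean(M on Y) - mean(M on X)``.  An exact 1-d 2-means
    split assigns clusters; the higher-``s`` cluster is predicted male.  If
    the between-cluster gap is below ``min_cluster_gap`` (all one sex), no
    sex is predicted from clustering and only |s| outliers relative to the
    single cluster are flagged.  A sample is flagged if it lies more than
    ``sex_outlier_sd`` cluster SDs from its cluster mean or if predicted
    and recorded sex disagree.  Without X and Y probes every sample is
    "not evaluable" (``evaluable = False``) and nothing is flagged.
    """
    t = t or QcThresholds()
    chroms = ds.probes["chrom"].map(normalize_chrom)
    x_probes = ds.probes.index[chroms == "X"]
    y_probes = ds.probes.index[chroms == "Y"]
    out = pd.DataFrame(
        {
            "recorded_sex": ds.samples.get("sex", pd.Series("NA", index=ds.samples.index)),
            "predicted_sex": "NA",
            "evaluable": False,
            "outlier": False,
            "mismatch": False,
            "flagged": False,
            "s": np.nan,
        },
        index=ds.samples.index,
    )
    if len(x_probes) == 0 or len(y_probes) == 0:
        return out
    m = beta_to_m(ds.beta[list(x_probes) + list(y_probes)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(m[y_probes].to_numpy(), axis=1) - np.nanmean(
            m[x_probes].to_numpy(), axis=1
        )
    out["s"] = s
    out["evaluable"] = True
    if len(s) < 2:
        return out
    labels, means = _two_means_1d(s)
    two_clusters = (means[1] - means[0]) > min_cluster_gap
    if two_clusters:
        pred = np.where(labels == 1, "M", "F")
        out["predicted_sex"] = pred
        out["mismatch"] = (out["recorded_sex"].to_numpy() != pred) & np.isin(
            out["recorded_sex"].to_numpy(), ("M", "F")
        )
        for lab in (0, 1):
            grp = labels == lab
            sd = s[grp].std(ddof=1) if grp.sum() > 1 else 0.0
            if sd > 0:
                out.loc[grp, "outlier"] = (
                    np.abs(s[grp] - means[lab]) > t.sex_outlier_sd * sd
                )
    else:
        sd = s.std(ddof=1)
        if sd > 0:
            out["outlier"] = np.abs(s - s.mean()) > t.sex_outlier_sd * sd
    out["flagged"] = out["outlier"] | out["mismatch"]
    return out


# -- combined --------------------------------------------------------------


def run_qc(
    ds: MethylationDataset,
    t: QcThresholds | None = None,
    samples_first: bool = True,
    check_sex: bool = True,
    drop_sex_probes: bool = True,
):
    """Full QC stage: sample/probe filters, sex checks, sex-chromosome drop.

    Returns ``(dataset, report)``.  The report records the filter order.
    """
    t = t or QcThresholds()
    stages = (filter_samples, filter_probes) if samples_first else (filter_probes, filter_samples)
    report = QcReport()
    for stage in stages:
        ds, rep = stage(ds, t)
        report = report.merge(rep)
    if check_sex:
        sex_tbl = predict_sex_and_flag_outliers(ds, t)
        flagged = sex_tbl.index[sex_tbl["flagged"]].tolist()
        if flagged:
            keep = [sid for sid in ds.beta.index if sid not in flagged]
            if not keep:
                raise ValueError(f"{ds.name}: all samples flagged as sex outliers")
            ds = ds.select_samples(keep)
            for sid in flagged:
                reason = "sex_mismatch" if sex_tbl.loc[sid, "mismatch"] else "sex_outlier"
                report.excluded_samples[sid] = reason
                report.sample_reasons[sid] = [reason]
            report.counts["samples_excluded_sex"] = len(flagged)
        report.order = report.order + ("sex_check",)
    if drop_sex_probes:
        before = ds.n_probes
        ds = drop_sex_chromosomes(ds)
        report.counts["probes_excluded_sex_chrom"] = before - ds.n_probes
        report.order = report.order + ("drop_sex_chromosomes",)
    return ds, report
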