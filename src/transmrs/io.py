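"""Readers/writers for the on-disk formats.

Matrices are stored as (optionally gzipped) TSV with CpGs as rows and
samples as columns, first column ``cpg``.  Loci are accepted as 6-column
BED (0-based half-open; converted to 1-based inclusive: start+1, end) or
as a TSV of 1-based lead positions.
"""

from __future__ import annotations

import gzip
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from transmrs.datasets import MethylationDataset
from transmrs.ewas import EwasResult
from transmrs.scoring import LociSet, MrsProfile

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_annotation",
    "write_annotation",
    "read_ewas",
    "write_ewas",
    "read_bed_loci",
    "read_lead_tsv",
    "write_loci",
    "load_dataset",
    "save_dataset",
    "read_yaml",
    "write_json",
]

EWAS_COLUMNS = ["cpg", "chrom", "pos", "effect", "se", "t", "p", "n"]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (EOFError, gzip.BadGzipFile) as exc:
        raise IOError(f"truncated or corrupt gzip file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise IOError(f"malformed TSV {path}: {exc}") from exc


def read_matrix(path) -> pd.DataFrame:
    """Read a CpGs x samples matrix file into samples x CpGs orientation."""
    df = _read_tsv(path, index_col=0)
    return df.T


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a samples x CpGs matrix as CpGs x samples TSV (gzip by suffix)."""
    out = df.T
    out.index.name = "cpg"
    out.to_csv(path, sep="\t")


def read_table(path, index_col=0) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"cpg", "chrom", "pos"}
    if not need <= set(df.columns):
        raise IOError(f"annotation {path} must have columns {sorted(need)}")
    return df.set_index("cpg")


def write_annotation(df: pd.DataFrame, path) -> None:
    out = df.reset_index()
    out.columns = ["cpg"] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False)


def read_ewas(path) -> EwasResult:
    df = _read_tsv(path, comment="#")
    missing = [c for c in EWAS_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"EWAS table {path} missing columns {missing}")
    return EwasResult(df[EWAS_COLUMNS + [c for c in df.columns if c not in EWAS_COLUMNS]])


def write_ewas(res: EwasResult, path, header_comment: str | None = None) -> None:
    path = Path(path)
    body = res.table.to_csv(sep="\t", index=False)
    text = (f"# {header_comment}\n" if header_comment else "") + body
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def read_bed_loci(path, window: int = 100_000) -> LociSet:
    """BED (0-based half-open) -> 1-based inclusive lead positions.

    The lead is taken as the midpoint of the interval converted to 1-based
    coordinates; for a 1-bp interval [p, p+1) this is position p+1.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IOError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise IOError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            start1, end1 = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
            lead = (start1 + end1) // 2
            rows.append((parts[0], lead))
    return LociSet(leads=pd.DataFrame(rows, columns=["chrom", "pos"]), window=window)


def read_lead_tsv(path, window: int = 100_000) -> LociSet:
    df = _read_tsv(path)
    if not {"chrom", "pos"} <= set(df.columns):
        raise IOError(f"lead TSV {path} must have columns chrom, pos")
    return LociSet(leads=df[["chrom", "pos"]], window=window)


def write_loci(loci: LociSet, bed_path, tsv_path) -> None:
    """Emit both a 6-column BED of windows and a TSV of 1-based leads."""
    with open(bed_path, "w") as fh:
        for i, row in loci.windows().iterrows():
            start0 = int(row["start"]) - 1  # 1-based inclusive -> 0-based half-open
            fh.write(
                f"{row['chrom']}\t{start0}\t{int(row['end'])}\tlocus{i + 1}\t0\t+\n"
            )
    loci.leads.to_csv(tsv_path, sep="\t", index=False)


# -- dataset directories ---------------------------------------------------

_DS_FILES = {
    "beta": "beta.tsv.gz",
    "detection_p": "detection_p.tsv.gz",
    "bead_count": "bead_count.tsv.gz",
    "samples": "samples.tsv",
    "probes": "probes.tsv",
}


def save_dataset(ds: MethylationDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.beta, outdir / _DS_FILES["beta"])
    write_matrix(ds.detection_p, outdir / _DS_FILES["detection_p"])
    write_matrix(ds.bead_count, outdir / _DS_FILES["bead_count"])
    ds.samples.to_csv(outdir / _DS_FILES["samples"], sep="\t")
    write_annotation(ds.probes, outdir / _DS_FILES["probes"])


def load_dataset(indir, name: str | None = None) -> MethylationDataset:
    indir = Path(indir)
    beta = read_matrix(indir / _DS_FILES["beta"])
    det = read_matrix(indir / _DS_FILES["detection_p"])
    beads = read_matrix(indir / _DS_FILES["bead_count"]).astype(int)
    samples = _read_tsv(indir / _DS_FILES["samples"], index_col=0)
    probes = read_annotation(indir / _DS_FILES["probes"])
    for mat in (beta, det, beads):
        mat.index.name = samples.index.name
        mat.columns.name = probes.index.name
    return MethylationDataset(
        beta=beta, detection_p=det, bead_count=beads, samples=samples, probes=probes,
        name=name or indir.name,
    )


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def save_mrs(profile: MrsProfile, tsv_path, json_path=None) -> None:
    out = profile.scores.copy()
    out.columns = [f"PT_{c:g}" for c in out.columns]
    out.index.name = "sample_id"
    out.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        write_json(
            {"site_counts": {str(k): v for k, v in profile.site_counts.items()},
             "provenance": profile.provenance},
            json_path,
        )
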