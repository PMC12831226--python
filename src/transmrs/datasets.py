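"""Core data container for one tissue's methylation data.

Matrices are held samples x CpGs in memory (the on-disk orientation is
CpGs x samples, see :mod:`transmrs.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

VALID_SEX = frozenset({"M", "F"})
VALID_DIAGNOSIS = frozenset({"case", "control"})


@dataclass
class MethylationDataset:
    """Beta matrix plus QC matrices, sample metadata and probe annotation.

    Parameters
    ----------
    beta : pd.DataFrame
        Methylation fractions in (0, 1), samples x CpGs.  NaN marks
        missing (failed) measurements.
    detection_p : pd.DataFrame
        Per-entry detection p-values, same shape/labels as ``beta``.
    bead_count : pd.DataFrame
        Per-entry bead counts (integers), same shape/labels as ``beta``.
    samples : pd.DataFrame
        Indexed by sample id.  Expected columns: ``diagnosis`` in
        {"case", "control"}, ``sex`` in {"M", "F"}, ``slide``; ``age`` and
        confounder columns are optional.
    probes : pd.DataFrame
        Indexed by CpG id, columns ``chrom`` and ``pos`` (1-based).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n, m = self.beta.shape
        if len(self.samples) != n:
            raise ValueError(
                f"{self.name}: {len(self.samples)} metadata rows but {n} beta rows"
            )
        if len(self.probes) != m:
            raise ValueError(
                f"{self.name}: {len(self.probes)} annotation rows but {m} beta columns"
            )
        if not self.beta.index.equals(self.samples.index):
            raise ValueError(f"{self.name}: beta row index != sample metadata index")
        if not self.beta.columns.equals(self.probes.index):
            raise ValueError(f"{self.name}: beta columns != probe annotation index")
        if self.probes.index.has_duplicates:
            dups = self.probes.index[self.probes.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.name}: duplicate CpG ids: {dups[:5]}")
        for mat, label in ((self.detection_p, "detection_p"), (self.bead_count, "bead_count")):
            if mat.shape != self.beta.shape:
                raise ValueError(f"{self.name}: {label} shape {mat.shape} != beta {self.beta.shape}")
            if not mat.index.equals(self.beta.index) or not mat.columns.equals(self.beta.columns):
                raise ValueError(f"{self.name}: {label} labels differ from beta labels")
        if (pd.to_numeric(self.probes["pos"]) < 0).any():
            raise ValueError(f"{self.name}: negative probe positions")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite <= 0) | (finite >= 1)).any():
            raise ValueError(f"{self.name}: beta values outside the open interval (0, 1)")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.probes.index

    def select_samples(self, ids: Sequence) -> "MethylationDataset":
        ids = list(ids)
        return replace(
            self,
            beta=self.beta.loc[ids],
            detection_p=self.detection_p.loc[ids],
            bead_count=self.bead_count.loc[ids],
            samples=self.samples.loc[ids],
        )

    def select_probes(self, cpgs: Sequence) -> "MethylationDataset":
        cpgs = list(cpgs)
        return replace(
            self,
            beta=self.beta[cpgs],
            detection_p=self.detection_p[cpgs],
            bead_count=self.bead_count[cpgs],
            probes=self.probes.loc[cpgs],
        )

    @classmethod
    def from_beta(
        cls,
        beta: pd.DataFrame,
        samples: pd.DataFrame,
        probes: pd.DataFrame,
        name: str = "dataset",
    ) -> "MethylationDataset":
        """Build a dataset with perfect QC matrices (all detected, high beads)."""
        detection_p = pd.DataFrame(
            np.full(beta.shape, 1e-4), index=beta.index, columns=beta.columns
        )
        bead_count = pd.DataFrame(
            np.full(beta.shape, 20, dtype=int), index=beta.index, columns=beta.columns
        )
        return cls(beta, detection_p, bead_count, samples, probes, name=name)


def normalize_chrom(label: object) -> str:
    """Map chromosome label dialects onto a canonical short form.

    "chrX"/"X"/"23" -> "X"; "chrY"/"Y"/"24" -> "Y"; "chr1"/"1" -> "1".
    """
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    return s.upper() if s.lower() in ("x", "y") else s
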