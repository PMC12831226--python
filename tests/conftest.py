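import numpy as np
import pandas as pd
import pytest

from transmrs.datasets import MethylationDataset


def make_dataset(
    beta: np.ndarray,
    chroms=None,
    positions=None,
    diagnosis=None,
    sex=None,
    detection_p=None,
    bead_count=None,
    name="fixture",
) -> MethylationDataset:
    """Build a small dataset from raw arrays with sensible defaults."""
    beta = np.asarray(beta, dtype=float)
    n, m = beta.shape
    sample_ids = [f"s{i}" for i in range(n)]
    cpg_ids = [f"cg{j:04d}" for j in range(m)]
    if chroms is None:
        chroms = ["chr1"] * m
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if diagnosis is None:
        diagnosis = ["case" if i < n // 2 else "control" for i in range(n)]
    if sex is None:
        sex = ["M" if i % 2 == 0 else "F" for i in range(n)]
    samples = pd.DataFrame(
        {"diagnosis": diagnosis, "sex": sex, "age": 40.0 + np.arange(n), "slide": "slide0"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probes = pd.DataFrame(
        {"chrom": chroms, "pos": positions}, index=pd.Index(cpg_ids, name="cpg")
    )
    idx, cols = samples.index, probes.index
    kwargs = {}
    if detection_p is not None:
        kwargs["detection_p"] = pd.DataFrame(detection_p, index=idx, columns=cols)
    if bead_count is not None:
        kwargs["bead_count"] = pd.DataFrame(bead_count, index=idx, columns=cols)
    ds = MethylationDataset.from_beta(
        pd.DataFrame(beta, index=idx, columns=cols), samples, probes, name=name
    )
    if "detection_p" in kwargs:
        ds.detection_p = kwargs["detection_p"]
    if "bead_count" in kwargs:
        ds.bead_count = kwargs["bead_count"]
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_dataset(rng):
    """40 samples x 30 autosomal CpGs of unstructured beta noise."""
    beta = np.clip(rng.beta(2, 2, size=(40, 30)), 1e-4, 1 - 1e-4)
    return make_dataset(beta)
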