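import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transmrs.ewas import EwasResult
from transmrs.qc import beta_to_m
from transmrs.scoring import (
    PT_THRESHOLDS,
    IndependentSiteSet,
    LociSet,
    comeback_prune,
    compute_mrs,
    intersect_sites,
    subset_by_loci,
)
from transmrs.synthdata import SimulationConfig, generate_paired_datasets

from conftest import make_dataset


def ewas_fixture(cpgs, pvals, effects=None, chroms=None, positions=None):
    n = len(cpgs)
    effects = effects if effects is not None else np.ones(n)
    tbl = pd.DataFrame(
        {
            "cpg": cpgs,
            "chrom": chroms if chroms is not None else ["chr1"] * n,
            "pos": positions if positions is not None else np.arange(1, n + 1) * 1000,
            "effect": effects,
            "se": 0.1,
            "t": np.asarray(effects) / 0.1,
            "p": pvals,
            "n": 40,
        }
    )
    return EwasResult(tbl)


# -- intersect -------------------------------------------------------------


def test_intersect_set_algebra():
    disc = ewas_fixture(["a", "b", "c"], [0.1, 0.2, 0.3])
    target = make_dataset(np.full((4, 3), 0.5))
    target.probes.index = pd.Index(["b", "c", "d"], name="cpg")
    target.beta.columns = target.probes.index
    target.detection_p.columns = target.probes.index
    target.bead_count.columns = target.probes.index
    assert intersect_sites(disc, target) == ["b", "c"]


def test_intersect_identity_and_empty():
    ds = make_dataset(np.full((3, 4), 0.5))
    disc = ewas_fixture(list(ds.cpg_ids), [0.1] * 4)
    assert intersect_sites(disc, ds) == list(ds.cpg_ids)
    disc2 = ewas_fixture(["zz1", "zz2"], [0.1, 0.1])
    with pytest.raises(ValueError, match="no CpG"):
        intersect_sites(disc2, ds)


def test_intersect_matches_planted_subset():
    cfg = SimulationConfig(seed=31, n_cpgs=300, tissue_a_fraction=0.8,
                           n_cases_a=10, n_controls_a=10, n_cases_b=10, n_controls_b=10)
    a, b, _ = generate_paired_datasets(cfg)
    disc = ewas_fixture(list(a.cpg_ids), [0.5] * a.n_probes)
    assert len(intersect_sites(disc, b)) == round(0.8 * 300)


# -- pruning ---------------------------------------------------------------


def _corr_pair_dataset(gap, identical=True, rng=None):
    rng = rng or np.random.default_rng(0)
    col = np.clip(rng.beta(2, 2, size=12), 0.01, 0.99)
    other = col if identical else np.clip(rng.beta(2, 2, size=12), 0.01, 0.99)
    beta = np.column_stack([col, other])
    return make_dataset(beta, positions=[1000, 1000 + gap])


def test_prune_forced_merge_keeps_smaller_p():
    ds = _corr_pair_dataset(gap=1000)
    disc = ewas_fixture(list(ds.cpg_ids), [0.2, 0.01], positions=[1000, 2000])
    out = comeback_prune(ds, list(ds.cpg_ids), disc)
    assert out.retained == ["cg0001"]
    assert out.clusters == {"cg0001": ["cg0000"]}


def test_prune_window_boundary_2000_vs_2001():
    at_edge = _corr_pair_dataset(gap=2000)
    disc = ewas_fixture(list(at_edge.cpg_ids), [0.2, 0.01], positions=[1000, 3000])
    assert len(comeback_prune(at_edge, list(at_edge.cpg_ids), disc).retained) == 1
    beyond = _corr_pair_dataset(gap=2001)
    disc2 = ewas_fixture(list(beyond.cpg_ids), [0.2, 0.01], positions=[1000, 3001])
    assert len(comeback_prune(beyond, list(beyond.cpg_ids), disc2).retained) == 2


def test_prune_tie_breaks_on_position():
    ds = _corr_pair_dataset(gap=500)
    disc = ewas_fixture(list(ds.cpg_ids), [0.05, 0.05], positions=[1000, 1500])
    out = comeback_prune(ds, list(ds.cpg_ids), disc)
    assert out.retained == ["cg0000"]


def brute_force_prune(beta, probes, pvals, window=2000, rho=0.3):
    """Transitive closure over pairwise (distance, Spearman) edges."""
    sites = list(beta.columns)
    n = len(sites)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = sites[i], sites[j]
        same = probes.loc[ci, "chrom"] == probes.loc[cj, "chrom"]
        close = abs(probes.loc[ci, "pos"] - probes.loc[cj, "pos"]) <= window
        if not (same and close):
            continue
        r = stats.spearmanr(beta[ci], beta[cj]).statistic
        if np.isnan(r):
            continue
        if abs(r) >= rho:
            adj[i].add(j)
            adj[j].add(i)
    seen, retained = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = [], [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k])
        rep = min(comp, key=lambda k: (pvals[sites[k]], probes.loc[sites[k], "pos"]))
        retained.append(sites[rep])
    return sorted(retained)


def test_prune_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for trial in range(50):
        n_sites, n_samp = 20, 15
        base = np.clip(rng.beta(2, 2, size=(n_samp, n_sites)), 0.01, 0.99)
        # induce some duplicated/correlated columns
        for _ in range(6):
            i, j = rng.integers(0, n_sites, 2)
            lam = rng.random()
            base[:, j] = np.clip(lam * base[:, i] + (1 - lam) * base[:, j], 0.01, 0.99)
        positions = np.sort(rng.choice(np.arange(1, 40) * 500, size=n_sites, replace=False))
        chroms = ["chr1" if k < n_sites // 2 else "chr2" for k in range(n_sites)]
        ds = make_dataset(base, chroms=chroms, positions=positions)
        pv = rng.random(n_sites)
        disc = ewas_fixture(list(ds.cpg_ids), pv, chroms=chroms, positions=positions)
        ours = comeback_prune(ds, list(ds.cpg_ids), disc)
        expected = brute_force_prune(ds.beta, ds.probes, dict(zip(ds.cpg_ids, pv)))
        assert sorted(ours.retained) == expected, f"trial {trial}"


def test_prune_order_independent():
    rng = np.random.default_rng(7)
    beta = np.clip(rng.beta(2, 2, size=(15, 12)), 0.01, 0.99)
    ds = make_dataset(beta, positions=np.arange(1, 13) * 700)
    pv = rng.random(12)
    disc = ewas_fixture(list(ds.cpg_ids), pv, positions=np.arange(1, 13) * 700)
    sites = list(ds.cpg_ids)
    r1 = comeback_prune(ds, sites, disc)
    perm = [sites[i] for i in rng.permutation(12)]
    r2 = comeback_prune(ds, perm, disc)
    assert set(r1.retained) == set(r2.retained)


def test_prune_requires_positions_and_samples():
    ds = make_dataset(np.full((2, 3), 0.5))
    disc = ewas_fixture(list(ds.cpg_ids), [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="3 target samples"):
        comeback_prune(ds, list(ds.cpg_ids), disc)


def test_independent_site_set_invariants():
    with pytest.raises(ValueError, match="retained and pruned"):
        IndependentSiteSet(retained=["a"], clusters={"a": ["a"]})


# -- MRS -------------------------------------------------------------------


def _target_from_m(m_row):
    """One-sample target whose M values equal ``m_row``."""
    beta = 2.0**np.asarray(m_row) / (1 + 2.0**np.asarray(m_row))
    beta = np.vstack([beta, beta, beta])  # 3 samples, identical
    return make_dataset(beta, diagnosis=["case", "control", "case"])


def test_mrs_hand_summed_example():
    target = _target_from_m([1.0, 2.0, -1.0])
    disc = ewas_fixture(list(target.cpg_ids), [0.005, 0.03, 0.4], effects=[0.5, -1.0, 2.0])
    prof = compute_mrs(target, disc, list(target.cpg_ids))
    s = prof.scores.iloc[0]
    assert s[0.01] == pytest.approx(0.5, abs=1e-9)
    assert s[0.05] == pytest.approx(-1.5, abs=1e-9)
    assert s[1.0] == pytest.approx(-3.5, abs=1e-9)
    assert prof.site_counts[0.01] == 1
    assert prof.site_counts[0.05] == 2
    assert prof.site_counts[1.0] == 3


def test_mrs_single_site_and_null_weight():
    target = _target_from_m([1.5])
    disc = ewas_fixture(["cg0000"], [0.0004], effects=[0.7])
    prof = compute_mrs(target, disc, ["cg0000"])
    for t in PT_THRESHOLDS:
        assert prof.scores.iloc[0][t] == pytest.approx(0.7 * 1.5, abs=1e-9)
    target2 = _target_from_m([1.5, 2.5])
    disc2 = ewas_fixture(list(target2.cpg_ids), [0.0004, 0.0004], effects=[0.7, 0.0])
    prof2 = compute_mrs(target2, disc2, list(target2.cpg_ids))
    for t in PT_THRESHOLDS:
        assert prof2.scores.iloc[0][t] == pytest.approx(0.7 * 1.5, abs=1e-9)


def test_mrs_pt1_includes_p_equal_one():
    target = _target_from_m([1.0])
    disc = ewas_fixture(["cg0000"], [1.0], effects=[2.0])
    prof = compute_mrs(target, disc, ["cg0000"])
    assert prof.site_counts[1.0] == 1
    assert prof.site_counts[0.5] == 0


def test_mrs_empty_smallest_threshold_warns_not_errors():
    target = _target_from_m([1.0])
    disc = ewas_fixture(["cg0000"], [0.9], effects=[2.0])
    with pytest.warns(UserWarning, match="no sites pass"):
        prof = compute_mrs(target, disc, ["cg0000"])
    assert prof.site_counts[0.001] == 0
    assert prof.scores.iloc[0][0.001] == 0.0


def test_mrs_threshold_nesting_and_additivity(rng):
    n_sites = 50
    beta = np.clip(rng.beta(2, 2, size=(10, n_sites)), 0.01, 0.99)
    target = make_dataset(beta)
    pv = rng.random(n_sites)
    eff = rng.normal(size=n_sites)
    disc = ewas_fixture(list(target.cpg_ids), pv, effects=eff)
    prof = compute_mrs(target, disc, list(target.cpg_ids))
    m = beta_to_m(target.beta)
    counts = [prof.site_counts[t] for t in PT_THRESHOLDS]
    assert counts == sorted(counts)
    for lo, hi in zip(PT_THRESHOLDS, PT_THRESHOLDS[1:]):
        added = (pv >= lo if hi == 1.0 else (pv >= lo) & (pv < hi))
        gap = m.to_numpy()[:, added] @ eff[added]
        np.testing.assert_allclose(
            prof.scores[hi] - prof.scores[lo], gap, atol=1e-9
        )


def test_mrs_linearity_in_weights(rng):
    beta = np.clip(rng.beta(2, 2, size=(8, 20)), 0.01, 0.99)
    target = make_dataset(beta)
    pv = rng.random(20)
    eff = rng.normal(size=20)
    disc1 = ewas_fixture(list(target.cpg_ids), pv, effects=eff)
    disc2 = ewas_fixture(list(target.cpg_ids), pv, effects=2 * eff)
    p1 = compute_mrs(target, disc1, list(target.cpg_ids))
    p2 = compute_mrs(target, disc2, list(target.cpg_ids))
    np.testing.assert_allclose(2 * p1.scores, p2.scores, atol=1e-9)


def test_mrs_missing_values_mean_imputed(rng):
    beta = np.clip(rng.beta(2, 2, size=(6, 3)), 0.01, 0.99)
    target = make_dataset(beta)
    target.beta.iloc[0, 0] = np.nan
    disc = ewas_fixture(list(target.cpg_ids), [0.0001] * 3, effects=[1.0, 1.0, 1.0])
    prof = compute_mrs(target, disc, list(target.cpg_ids))
    assert prof.provenance["n_imputed_entries"] == 1
    assert np.isfinite(prof.scores.to_numpy()).all()


def test_mrs_beta_scale_option():
    target = _target_from_m([2.0])
    disc = ewas_fixture(["cg0000"], [0.0001], effects=[1.0])
    prof = compute_mrs(target, disc, ["cg0000"], scale="beta")
    assert prof.scores.iloc[0][1.0] == pytest.approx(0.8, abs=1e-9)


def test_mrs_requires_weights():
    target = _target_from_m([1.0, 2.0])
    disc = ewas_fixture(["cg0000"], [0.5], effects=[1.0])
    with pytest.raises(ValueError, match="no discovery weights"):
        compute_mrs(target, disc, list(target.cpg_ids))


# -- loci subsetting -------------------------------------------------------


def test_subset_by_loci_inclusive_boundary():
    positions = [200_000, 300_000, 300_001, 99_999]
    beta = np.full((3, 4), 0.5)
    ds = make_dataset(beta, positions=positions)
    loci = LociSet(leads=pd.DataFrame({"chrom": ["chr1"], "pos": [200_000]}))
    inc = subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "include")
    # lead 200k: window [100000, 300000]; 300001 excluded, 99999 excluded
    assert inc == ["cg0000", "cg0001"]
    exc = subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "exclude")
    assert exc == ["cg0002", "cg0003"]


def test_subset_by_loci_empty_lociset():
    ds = make_dataset(np.full((2, 3), 0.5))
    loci = LociSet(leads=pd.DataFrame(columns=["chrom", "pos"]))
    assert subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "include") == []
    assert subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "exclude") == list(ds.cpg_ids)


def test_subset_by_loci_partition_property(rng):
    n = 40
    positions = rng.choice(np.arange(1, 10_000) * 100, size=n, replace=False)
    chroms = rng.choice(["chr1", "chr2"], size=n)
    ds = make_dataset(np.full((2, n), 0.5), chroms=chroms, positions=positions)
    loci = LociSet(
        leads=pd.DataFrame({"chrom": ["chr1", "chr2", "chr2"],
                            "pos": [50_000, 200_000, 700_000]}),
        window=100_000,
    )
    inc = subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "include")
    exc = subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "exclude")
    assert set(inc) | set(exc) == set(ds.cpg_ids)
    assert set(inc) & set(exc) == set()
    for cpg in ds.cpg_ids:  # brute force over all sites
        pos, chrom = ds.probes.loc[cpg, "pos"], ds.probes.loc[cpg, "chrom"]
        inside = any(
            chrom == lc and abs(pos - lp) <= 100_000
            for lc, lp in loci.leads.itertuples(index=False)
        )
        assert (cpg in inc) == inside


def test_subset_by_loci_chrom_mismatch_error():
    ds = make_dataset(np.full((2, 3), 0.5))
    loci = LociSet(leads=pd.DataFrame({"chrom": ["chr9"], "pos": [1000]}))
    with pytest.raises(ValueError, match="chr|9"):
        subset_by_loci(list(ds.cpg_ids), ds.probes, loci, "include")


def test_gws_partition_scores_sum(rng):
    """include-scores + exclude-scores == all-scores per sample/threshold."""
    n = 30
    beta = np.clip(rng.beta(2, 2, size=(10, n)), 0.01, 0.99)
    positions = np.arange(1, n + 1) * 50_000
    ds = make_dataset(beta, positions=positions)
    pv, eff = rng.random(n), rng.normal(size=n)
    disc = ewas_fixture(list(ds.cpg_ids), pv, effects=eff, positions=positions)
    loci = LociSet(leads=pd.DataFrame({"chrom": ["chr1"], "pos": [500_000]}))
    sites = list(ds.cpg_ids)
    inc = subset_by_loci(sites, ds.probes, loci, "include")
    exc = subset_by_loci(sites, ds.probes, loci, "exclude")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p_all = compute_mrs(ds, disc, sites)
        p_inc = compute_mrs(ds, disc, inc)
        p_exc = compute_mrs(ds, disc, exc)
    np.testing.assert_allclose(
        p_inc.scores + p_exc.scores, p_all.scores, atol=1e-9
    )
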