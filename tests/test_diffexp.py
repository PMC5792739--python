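"""Differential-expression unit tests: normalisation, NB Wald, thresholds."""

import numpy as np
import pandas as pd
import pytest

from crossmeta import diffexp as de
from crossmeta import synthetic as syn


def make_matrix(counts, lengths=None, groups=None):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    lengths = lengths if lengths is not None else np.full(counts.shape[0], 1000.0)
    groups = groups if groups is not None else (
        ["A"] * (counts.shape[1] // 2) + ["B"] * (counts.shape[1] // 2))
    return de.CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=genes,
                            columns=samples),
        gene_lengths=pd.Series(lengths, index=genes),
        groups=pd.Series(groups, index=samples),
    )


# ---------------------------------------------------------------------------
# size factors and FPKM

def test_size_factors_exact_doubling():
    c = np.array([[10, 20], [100, 200], [7, 14]])
    f = de.size_factors_median_of_ratios(c)
    assert f[1] / f[0] == pytest.approx(2.0)


def test_size_factors_identical_samples_and_scaling(rng):
    c = rng.integers(1, 500, size=(40, 4))
    c[:, 1:] = c[:, :1]  # identical columns
    f = de.size_factors_median_of_ratios(c)
    np.testing.assert_allclose(f, f[0])
    # the per-gene geometric mean absorbs a global rescaling, so factors are
    # invariant to scaling ALL counts; scaling one sample scales its factor
    f3 = de.size_factors_median_of_ratios(3 * c)
    np.testing.assert_allclose(f3, f, rtol=1e-12)
    c2 = c.astype(float).copy()
    c2[:, 1] *= 2
    f2 = de.size_factors_median_of_ratios(c2)
    assert f2[1] / f2[0] == pytest.approx(2.0, rel=1e-12)


def test_size_factors_need_all_nonzero_gene():
    with pytest.raises(ValueError):
        de.size_factors_median_of_ratios(np.array([[0, 5], [3, 0]]))


def test_fpkm_arithmetic():
    out = de.fpkm(np.array([[100], [0]]), [1000.0, 500.0], [1_000_000.0])
    assert out[0, 0] == pytest.approx(100.0)
    assert out[1, 0] == 0.0
    halved = de.fpkm(np.array([[100]]), [500.0], [1_000_000.0])
    assert halved[0, 0] == pytest.approx(200.0)


def test_fpkm_rejects_zero_length():
    with pytest.raises(ValueError):
        de.fpkm(np.array([[1]]), [0.0], [100.0])


# ---------------------------------------------------------------------------
# NB Wald test

def test_nb_wald_identical_groups_centre():
    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=2000, replicates_per_group=5, baseline_means=200.0,
        dispersions=0.05, seed=10))
    lfc, p, _, _ = de.nb_wald_test(m.columns_for("parental").to_numpy(),
                                   m.columns_for("derivative").to_numpy())
    assert abs(np.nanmean(lfc)) < 0.02
    # type-I error at alpha=.01 within 3 binomial MC standard errors
    alpha = 0.01
    frac = np.nanmean(p < alpha)
    assert abs(frac - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / 2000)


def test_nb_wald_poisson_null_uniform():
    from scipy import stats

    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=3000, replicates_per_group=10, baseline_means=100.0,
        dispersions=0.0, seed=11))
    _, p, _, _ = de.nb_wald_test(m.columns_for("parental").to_numpy(),
                                 m.columns_for("derivative").to_numpy())
    # approximately uniform: KS at a loose bar (discreteness at small counts)
    assert stats.kstest(p[~np.isnan(p)], "uniform").pvalue > 1e-4


def test_nb_wald_planted_lfc_recovery():
    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=500, replicates_per_group=5, baseline_means=200.0,
        dispersions=0.05, planted_log2fc={i: 3.0 for i in range(500)},
        seed=12))
    lfc, p, _, _ = de.nb_wald_test(m.columns_for("parental").to_numpy(),
                                   m.columns_for("derivative").to_numpy())
    assert np.mean(np.abs(lfc - 3.0) < 0.5) >= 0.90


def test_nb_wald_needs_replicates():
    with pytest.raises(ValueError):
        de.nb_wald_test(np.array([[1]]), np.array([[2, 3]]))


# ---------------------------------------------------------------------------
# run_de_comparison thresholds

def test_base_mean_filter_precedence(rng):
    """A hugely significant gene below the base-mean filter is never DE."""
    counts = rng.poisson(300, size=(50, 10))
    counts[0, :5] = 2
    counts[0, 5:] = 16  # strong fold change, base mean ~9 < 10
    m = make_matrix(counts)
    res = de.run_de_comparison(m, "B", "A")
    if res.loc["g0", "base_mean"] < 10:
        assert res.loc["g0", "status"] == "filtered"
        assert not res.loc["g0", "is_de"]


def test_joint_threshold_lfc_and_padj():
    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=800, replicates_per_group=5, baseline_means=300.0,
        dispersions=0.02, planted_log2fc={0: 1.5, 1: 3.0}, seed=13))
    res = de.run_de_comparison(m, "derivative", "parental")
    # |lfc| = 1.5 < 2: significant but not DE
    assert res.iloc[0]["padj"] < 0.01
    assert not res.iloc[0]["is_de"]
    assert res.iloc[1]["is_de"]
    assert res.iloc[1]["direction"] == "over"


def test_de_recovery_with_direction():
    planted = {i: (3.0 if i % 2 else -3.0) for i in range(50)}
    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=2000, replicates_per_group=5, baseline_means=200.0,
        dispersions=0.05, planted_log2fc=planted, seed=14))
    res = de.run_de_comparison(m, "derivative", "parental")
    hit = res.iloc[:50]
    assert hit["is_de"].sum() >= 45
    called = hit[hit["is_de"]]
    expected = ["over" if i % 2 else "under" for i in range(50)]
    assert all(called["direction"][f"m{i:05d}"] == expected[i]
               for i in range(50) if called["is_de"].get(f"m{i:05d}", False))
    # bookkeeping: every gene in exactly one status bucket
    assert res["status"].isin(["tested", "filtered", "non_estimable"]).all()
    assert len(res) == 2000


def test_de_union_set_algebra():
    def tab(genes, direction):
        return pd.DataFrame({
            "is_de": True, "direction": direction,
            "log2fc": 3.0 if direction == "over" else -3.0},
            index=pd.Index(genes, name="gene"))

    u = de.de_union({"c1": tab(list("abcdefghij"), "over"),
                     "c2": tab(list("klmnopqrst"), "under")})
    assert len(u) == 20
    assert (u["n_comparisons_de"] == 1).all()
    assert not u["ambiguous"].any()

    amb = de.de_union({"c1": tab(["x"], "over"), "c2": tab(["x"], "under")})
    assert amb.loc["x", "ambiguous"]
    assert amb.loc["x", "direction"] == ""

    empty = de.de_union({"c1": tab([], "over")})
    assert len(empty) == 0


# ---------------------------------------------------------------------------
# QC and z-scores

def test_replicate_qc_duplicate_sample_and_group_split(rng):
    # abundances span orders of magnitude, as in real libraries; that
    # between-gene spread is what drives high replicate correlation
    baselines = np.exp(rng.normal(np.log(150), 1.5, size=500))
    m = syn.simulate_counts(syn.CountSimSpec(
        n_genes=500, replicates_per_group=4, baseline_means=baselines,
        dispersions=0.02,
        planted_log2fc={i: 2.0 for i in range(100)}, seed=15))
    corr, clusters, flagged = de.replicate_correlation_qc(m)
    # replicates correlate strongly within group
    for g in ("parental", "derivative"):
        cols = m.groups.index[m.groups == g]
        block = corr.loc[cols, cols].to_numpy()
        assert block[np.triu_indices(4, 1)].min() > 0.95
    # clustering separates the groups; nothing flagged
    assert flagged == []
    assert clusters[m.groups == "parental"].nunique() == 1
    assert clusters[m.groups == "derivative"].nunique() == 1
    assert (set(clusters[m.groups == "parental"])
            != set(clusters[m.groups == "derivative"]))


def test_replicate_qc_constant_sample_flagged():
    counts = np.ones((10, 3), dtype=int)
    counts[:, :2] = np.arange(10)[:, None] + 1
    m = make_matrix(counts, groups=["A", "A", "B"])
    with pytest.raises(ValueError):
        de.replicate_correlation_qc(m)


def test_zscores_rows_standardised(rng):
    vals = pd.DataFrame(rng.uniform(1, 100, size=(20, 6)))
    vals.iloc[3] = 7.0  # constant gene dropped
    z = de.expression_zscores(vals)
    assert 3 not in z.index
    np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(np.std(z.to_numpy(), axis=1), 1, rtol=1e-12)


def test_zscores_hand_2x3():
    vals = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
    z = de.expression_zscores(vals)
    # proportional rows give identical z-scores
    np.testing.assert_allclose(z.iloc[0], z.iloc[1])
    np.testing.assert_allclose(z.iloc[0],
                               [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
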