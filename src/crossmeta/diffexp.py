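"""Parental-vs-derivative differential expression for cell-line RNA-seq.

Counts are normalised with median-of-ratios size factors, tested gene-wise
with a negative-binomial Wald test on the group fold change (method-of-
moments dispersion, no shrinkage), filtered on mean normalised count, and
re-adjusted with Benjamini-Hochberg.  A gene is called differentially
expressed when padj < 0.01 and |log2 fold change| >= 2, i.e. a fourfold
change.  Replicate-correlation QC and per-gene z-score matrices support the
downstream cross-species comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .survival import bh_adjust

__all__ = [
    "CountMatrix",
    "DEConfig",
    "size_factors_median_of_ratios",
    "fpkm",
    "nb_wald_test",
    "run_de_comparison",
    "de_union",
    "replicate_correlation_qc",
    "expression_zscores",
]

OVER = "over"
UNDER = "under"

# floor on the method-of-moments dispersion, guarding degenerate Wald SEs
DISPERSION_FLOOR = 1e-8


@dataclass
class DEConfig:
    min_base_mean: float = 10.0
    padj_threshold: float = 0.01
    lfc_threshold: float = 2.0

    def __post_init__(self) -> None:
        if min(self.min_base_mean, self.padj_threshold, self.lfc_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CountMatrix:
    """Integer RNA-seq counts (genes x samples) with lengths and groups.

    counts : genes x samples DataFrame of non-negative integers.
    gene_lengths : per-gene length in bp, aligned with the count index.
    groups : per-sample cell-line label, aligned with the count columns.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.any(np.asarray(self.gene_lengths, float) <= 0):
            raise ValueError("gene lengths must be positive")
        if not self.counts.index.equals(pd.Index(self.gene_lengths.index)):
            raise ValueError("gene_lengths index must match count rows")
        if list(self.groups.index) != list(self.counts.columns):
            raise ValueError("groups index must match count columns")

    def columns_for(self, group: str) -> pd.DataFrame:
        cols = self.groups.index[self.groups == group]
        if cols.empty:
            raise KeyError(f"no samples in group {group!r}")
        return self.counts[cols]


def size_factors_median_of_ratios(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (DESeq-style normalisation).

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count / geometric-mean-across-samples.
    """
    c = np.asarray(counts, float)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    cc = c[all_nonzero]
    log_geo = np.mean(np.log(cc), axis=1)
    return np.exp(np.median(np.log(cc) - log_geo[:, None], axis=0))


def fpkm(counts: pd.DataFrame | np.ndarray, gene_lengths: Sequence[float],
         totals: Sequence[float] | None = None) -> np.ndarray:
    """Fragments per kilobase of gene model per million mapped fragments.

    fpkm_gj = count_gj * 1e9 / (length_g * total_j); totals default to
    column sums of the count matrix.
    """
    c = np.asarray(counts, float)
    lengths = np.asarray(gene_lengths, float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    t = c.sum(axis=0) if totals is None else np.asarray(totals, float)
    if np.any(t <= 0):
        raise ValueError("library totals must be positive")
    return c * 1e9 / (lengths[:, None] * t[None, :])


def _mom_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from normalised counts.

    Pools within-group variances so planted fold changes do not inflate the
    estimate; alpha = (s2 - mu) / mu^2 floored at DISPERSION_FLOOR.
    """
    mu = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for idx in group_idx:
        sub = norm[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        df += len(idx) - 1
    s2 = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    return np.maximum(np.nan_to_num(alpha, nan=0.0), DISPERSION_FLOOR)


def nb_wald_test(group_a: np.ndarray, group_b: np.ndarray,
                 size_factors_a: np.ndarray | None = None,
                 size_factors_b: np.ndarray | None = None):
    """Negative-binomial Wald test of the B-vs-A fold change, per gene.

    Counts (genes x replicates per group) are divided by their size
    factors; the log2 fold change is the ratio of group means of normalised
    counts, and its standard error comes from the NB variance mu + alpha
    mu^2 with a pooled method-of-moments dispersion.  The Wald statistic is
    referred to a t distribution with nA + nB - 2 degrees of freedom, which
    accounts for the dispersion being estimated from few replicates and
    tends to the normal reference as replication grows.

    Returns (log2fc, p, base_mean, alpha); genes with all-zero counts in
    either group get NaN statistics.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    sfa = np.ones(na) if size_factors_a is None else np.asarray(size_factors_a, float)
    sfb = np.ones(nb) if size_factors_b is None else np.asarray(size_factors_b, float)
    norm_a, norm_b = a / sfa, b / sfb
    norm = np.hstack([norm_a, norm_b])
    base_mean = norm.mean(axis=1)
    alpha = _mom_dispersion(norm, [np.arange(na), np.arange(na, na + nb)])

    mu_a, mu_b = norm_a.mean(axis=1), norm_b.mean(axis=1)
    ok = (mu_a > 0) & (mu_b > 0)
    log2fc = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    log2fc[ok] = np.log2(mu_b[ok] / mu_a[ok])
    # delta-method variance of log mean of normalised counts:
    # Var(K_j / s_j) = mu / s_j + alpha mu^2
    var_ma = (mu_a[:, None] / sfa[None, :] + alpha[:, None] * mu_a[:, None] ** 2
              ).sum(axis=1) / na**2
    var_mb = (mu_b[:, None] / sfb[None, :] + alpha[:, None] * mu_b[:, None] ** 2
              ).sum(axis=1) / nb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(var_ma / mu_a**2 + var_mb / mu_b**2)
        z = np.log(mu_b / mu_a) / se_ln
    p[ok] = 2 * stats.t.sf(np.abs(z[ok]), df=na + nb - 2)
    return log2fc, p, base_mean, alpha


def run_de_comparison(matrix: CountMatrix, derivative: str, parental: str,
                      config: DEConfig | None = None) -> pd.DataFrame:
    """One paired derivative-vs-parental DE comparison.

    Size factors are computed on the samples of the two groups; genes with
    mean normalised count below ``min_base_mean`` are filtered out BEFORE
    BH re-adjustment of the survivors.  The DE call requires
    padj < padj_threshold AND |log2fc| >= lfc_threshold.

    Returns a gene-indexed DataFrame with columns base_mean, log2fc, p,
    padj, is_de, direction, status where status is one of
    {"tested", "filtered", "non_estimable"}.
    """
    config = config or DEConfig()
    ca = matrix.columns_for(parental)
    cb = matrix.columns_for(derivative)
    both = pd.concat([ca, cb], axis=1)
    sf = size_factors_median_of_ratios(both)
    sfa, sfb = sf[: ca.shape[1]], sf[ca.shape[1]:]
    log2fc, p, base_mean, _ = nb_wald_test(ca.to_numpy(), cb.to_numpy(), sfa, sfb)

    out = pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "p": p},
        index=matrix.counts.index,
    )
    out["status"] = "tested"
    out.loc[out["p"].isna(), "status"] = "non_estimable"
    out.loc[(out["status"] == "tested")
            & (out["base_mean"] < config.min_base_mean), "status"] = "filtered"
    out["padj"] = np.nan
    tested = out["status"] == "tested"
    out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["is_de"] = tested & (out["padj"] < config.padj_threshold) \
        & (out["log2fc"].abs() >= config.lfc_threshold)
    out["direction"] = np.where(out["log2fc"] > 0, OVER, UNDER)
    out.loc[out["log2fc"].isna(), "direction"] = ""
    return out


def de_union(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of DE calls across paired comparisons.

    Returns a gene-indexed table with one direction column per comparison
    (empty string where not DE), ``n_comparisons_de``, and ``ambiguous``
    flagging genes called over in one comparison and under in another.
    """
    per_gene: dict[str, dict[str, str]] = {}
    for name, tab in tables.items():
        de = tab[tab["is_de"]]
        for gene, row in de.iterrows():
            per_gene.setdefault(gene, {})[name] = row["direction"]
    if not per_gene:
        return pd.DataFrame(
            columns=[*tables, "n_comparisons_de", "direction", "ambiguous"]
        ).astype({"n_comparisons_de": int, "ambiguous": bool}
                 ).rename_axis("gene")
    out = pd.DataFrame.from_dict(per_gene, orient="index").reindex(
        columns=list(tables)).fillna("")
    out.index.name = "gene"
    out["n_comparisons_de"] = (out[list(tables)] != "").sum(axis=1)
    dirs = out[list(tables)].apply(lambda r: set(r) - {""}, axis=1)
    out["ambiguous"] = dirs.apply(lambda s: len(s) > 1)
    out["direction"] = dirs.apply(lambda s: next(iter(s)) if len(s) == 1 else "")
    return out.sort_index()


def replicate_correlation_qc(matrix: CountMatrix, use_fpkm: bool = True):
    """Pearson correlations among samples plus a hierarchical-cluster QC.

    Correlations are computed on log2(FPKM + 1) by default (raw normalised
    counts when ``use_fpkm=False``), samples clustered by average linkage
    on 1 - r, and a replicate is flagged when its nearest neighbour lies
    outside its own group.

    Returns (corr: DataFrame, clusters: Series, flagged: list of sample IDs).
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    if use_fpkm:
        vals = np.log2(fpkm(matrix.counts, matrix.gene_lengths.to_numpy()) + 1)
    else:
        vals = matrix.counts.to_numpy() / size_factors_median_of_ratios(matrix.counts)
    sds = vals.std(axis=0)
    if np.any(sds == 0):
        bad = list(matrix.counts.columns[sds == 0])
        raise ValueError(f"constant samples, correlation undefined: {bad}")
    corr = pd.DataFrame(np.corrcoef(vals.T), index=matrix.counts.columns,
                        columns=matrix.counts.columns)
    dist = squareform(1 - corr.to_numpy(), checks=False)
    labels = fcluster(average(dist), t=matrix.groups.nunique(), criterion="maxclust")
    clusters = pd.Series(labels, index=matrix.counts.columns, name="cluster")
    flagged = []
    cm = corr.to_numpy().copy()
    np.fill_diagonal(cm, -np.inf)
    nearest = corr.columns[np.argmax(cm, axis=1)]
    for sample, nb_sample in zip(corr.index, nearest):
        if matrix.groups[sample] != matrix.groups[nb_sample]:
            flagged.append(sample)
    return corr, clusters, flagged


def expression_zscores(normalized: pd.DataFrame,
                       genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene z-scores of normalised counts across samples.

    Genes with zero standard deviation are dropped.  Each returned row has
    mean 0 and (population) SD 1.
    """
    sub = normalized if genes is None else normalized.loc[list(genes)]
    vals = sub.to_numpy(float)
    sd = vals.std(axis=1)
    keep = sd > 0
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return pd.DataFrame(z, index=sub.index[keep], columns=sub.columns)
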