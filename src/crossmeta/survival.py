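"""Gene-wise Cox proportional-hazards survival screen.

Each gene's log2 expression enters a Cox model as a continuous covariate,
optionally adjusted for patient age and sex.  Per-gene Wald p-values are
corrected with the Benjamini-Hochberg FDR, and two cohorts screened
independently are intersected requiring significance in both, recording
whether the hazard-ratio direction agrees.

The partial-likelihood fitter is implemented here (Newton-Raphson with
Breslow or Efron tie handling) because a cohort screen refits the same
survival data thousands of times with a single changing covariate; the
risk-set structure is precomputed once per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortDataset",
    "GeneSurvivalResult",
    "ScreenConfig",
    "CoxWorkspace",
    "fit_cox_single_gene",
    "bh_adjust",
    "run_cohort_screen",
    "intersect_cohorts",
    "km_median_split",
    "wald_p_from_hr_ci",
]

PROTECTIVE = "protective"
ADVERSE = "adverse"


@dataclass
class ScreenConfig:
    """Configuration of a cohort screen.

    fdr_threshold : BH-adjusted significance cut (default 0.1).
    adjust_covariates : names among {"age", "sex"} entered alongside the gene.
    ties_method : "breslow" (default) or "efron".
    ci_level : confidence level for the hazard-ratio interval.
    """

    fdr_threshold: float = 0.1
    adjust_covariates: tuple[str, ...] = ()
    ties_method: str = "breslow"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.ties_method not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method {self.ties_method!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        unknown = set(self.adjust_covariates) - {"age", "sex"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass
class CohortDataset:
    """One patient cohort: a log2 expression matrix plus survival tables.

    expression : genes x samples DataFrame on the log2 scale.
    survival : per-sample table with columns time, event and optionally
        age (years) and sex (0/1), indexed by sample ID aligned with the
        expression columns.  Events are 1 for death (melanoma-specific or
        overall, depending on the cohort), 0 for censoring.
    """

    expression: pd.DataFrame
    survival: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.survival.index):
            if set(self.expression.columns) != set(self.survival.index):
                raise ValueError("expression columns and survival index disagree")
            self.survival = self.survival.loc[self.expression.columns]
        t = np.asarray(self.survival["time"], float)
        e = np.asarray(self.survival["event"])
        if np.any(t <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]


@dataclass
class GeneSurvivalResult:
    """Per-gene screen outcome: HR per unit log2 expression with Wald CI/p."""

    gene: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    fdr: float = np.nan
    estimable: bool = True

    @property
    def direction(self) -> str:
        return PROTECTIVE if self.hr < 1.0 else ADVERSE


class NonEstimableError(ValueError):
    """Raised when a Cox fit is degenerate (no events, constant covariate)."""


class CoxWorkspace:
    """Precomputed risk-set structure for repeated Cox fits on one cohort.

    Sorting, tie blocks and event bookkeeping depend only on (time, event),
    so a gene screen reuses them across thousands of single-covariate fits.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D and aligned")
        if event.sum() < 1:
            raise NonEstimableError("no events in cohort")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        ts = time[self.order]
        self.event_sorted = event[self.order]
        # block starts of tied times (ascending); risk set at a block is the
        # suffix starting at the block's first index
        is_start = np.ones(self.n, bool)
        is_start[1:] = ts[1:] != ts[:-1]
        starts = np.flatnonzero(is_start)
        ends = np.append(starts[1:], self.n)
        d = np.add.reduceat(self.event_sorted, starts)
        keep = d > 0
        self.block_start = starts[keep]
        self.block_end = ends[keep]
        self.block_d = d[keep]
        self.event_idx = np.flatnonzero(self.event_sorted == 1)
        self.n_events = int(self.event_sorted.sum())

    # ----- partial likelihood, gradient, Hessian -----------------------

    def _derivs(self, X: np.ndarray, beta: np.ndarray, ties: str):
        n, p = X.shape
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = wX[:, :, None] * X[:, None, :]
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        ll = float(eta[self.event_idx].sum())
        g = X[self.event_idx].sum(axis=0)
        H = np.zeros((p, p))

        s0 = S0[self.block_start]
        s1 = S1[self.block_start]
        s2 = S2[self.block_start]
        d = self.block_d

        if ties == "breslow":
            r = s1 / s0[:, None]
            ll -= float(np.sum(d * np.log(s0)))
            g -= (d[:, None] * r).sum(axis=0)
            H -= np.einsum("k,kij->ij", d, s2 / s0[:, None, None]
                           - r[:, :, None] * r[:, None, :])
        else:  # efron
            for k in range(d.size):
                i0, i1, dk = self.block_start[k], self.block_end[k], d[k]
                blk = slice(i0, i1)
                ev = self.event_sorted[blk] == 1
                t0 = w[blk][ev].sum()
                t1 = wX[blk][ev].sum(axis=0)
                t2 = wXX[blk][ev].sum(axis=0)
                for j in range(dk):
                    f = j / dk
                    m0 = s0[k] - f * t0
                    m1 = s1[k] - f * t1
                    m2 = s2[k] - f * t2
                    r = m1 / m0
                    ll -= np.log(m0)
                    g -= r
                    H -= m2 / m0 - np.outer(r, r)
        return ll, g, H

    def fit(self, X: np.ndarray, ties: str = "breslow",
            max_iter: int = 60, tol: float = 1e-9):
        """Newton-Raphson maximisation of the log partial likelihood.

        Returns (beta, se, loglik, converged, score_max).
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != self.n:
            X = X.T
        X = X[self.order]
        n, p = X.shape
        if np.any(np.ptp(X, axis=0) == 0):
            raise NonEstimableError("constant covariate")
        beta = np.zeros(p)
        ll, g, H = self._derivs(X, beta, ties)
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                break
            # step halving on likelihood decrease
            for _ in range(30):
                cand = beta + step
                ll_new, g_new, H_new = self._derivs(X, cand, ties)
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2
            moved = np.max(np.abs(cand - beta))
            beta, ll, g, H = cand, ll_new, g_new, H_new
            if np.max(np.abs(g)) < tol or moved < 1e-12:
                converged = True
                break
        if not converged and np.max(np.abs(g)) < 1e-6:
            converged = True
        if not converged or np.max(np.abs(beta)) > 40:
            raise NonEstimableError("Cox fit did not converge (possible separation)")
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.diag(cov))
        return beta, se, ll, converged, float(np.max(np.abs(g)))


def fit_cox_single_gene(
    expr: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    covariates: np.ndarray | pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
    gene: str = "",
    workspace: CoxWorkspace | None = None,
) -> GeneSurvivalResult:
    """Fit a Cox model with the gene's log2 expression as first covariate.

    Returns a :class:`GeneSurvivalResult` with the FDR field unset.  A gene
    with constant expression, no events, or a separated fit is returned with
    ``estimable=False`` and NaN statistics.
    """
    config = config or ScreenConfig()
    expr = np.asarray(expr, float)
    if workspace is None:
        workspace = CoxWorkspace(np.asarray(time, float), np.asarray(event, int))
    cols = [expr]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        cov = cov[:, None] if cov.ndim == 1 else cov
        cols.extend(cov.T)
    X = np.column_stack(cols)
    try:
        beta, se, _, _, _ = workspace.fit(X, ties=config.ties_method)
    except NonEstimableError:
        return GeneSurvivalResult(gene, np.nan, np.nan, np.nan, np.nan,
                                  estimable=False)
    z = stats.norm.ppf(0.5 + config.ci_level / 2)
    b, s = beta[0], se[0]
    p = 2 * stats.norm.sf(abs(b) / s)
    return GeneSurvivalResult(
        gene=gene,
        hr=float(np.exp(b)),
        ci_low=float(np.exp(b - z * s)),
        ci_high=float(np.exp(b + z * s)),
        p=float(p),
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_cohort_screen(cohort: CohortDataset,
                      config: ScreenConfig | None = None) -> pd.DataFrame:
    """Screen every gene of a cohort; BH-adjust over all estimable genes.

    Returns a DataFrame indexed by gene with columns hr, ci_low, ci_high,
    p, fdr, direction.  Non-estimable genes (constant expression,
    separation) are excluded from the output and from the BH family.
    """
    config = config or ScreenConfig()
    if cohort.n_genes < 2:
        raise ValueError("need at least two genes to screen")
    surv = cohort.survival
    ws = CoxWorkspace(surv["time"].to_numpy(float), surv["event"].to_numpy(int))
    covs = None
    if config.adjust_covariates:
        covs = surv[list(config.adjust_covariates)].to_numpy(float)
    rows = []
    expr_mat = cohort.expression.to_numpy(float)
    for i, gene in enumerate(cohort.expression.index):
        res = fit_cox_single_gene(expr_mat[i], None, None, covariates=covs,
                                  config=config, gene=str(gene), workspace=ws)
        if res.estimable:
            rows.append(res)
    if not rows:
        raise ValueError("no estimable genes in cohort")
    out = pd.DataFrame(
        {
            "hr": [r.hr for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p for r in rows],
        },
        index=pd.Index([r.gene for r in rows], name="gene"),
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["hr"] < 1.0, PROTECTIVE, ADVERSE)
    return out


def intersect_cohorts(res_a: pd.DataFrame, res_b: pd.DataFrame,
                      fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Genes significant in both cohorts, with a direction-agreement flag.

    Returns the joined table (columns suffixed _a/_b) restricted to genes
    with fdr < threshold in BOTH cohorts, plus ``same_direction``; the
    fraction concordant is stored in ``result.attrs['fraction_same_direction']``.
    """
    shared = res_a.index.intersection(res_b.index)
    if shared.empty:
        raise ValueError("cohorts share no genes")
    joined = res_a.loc[shared].join(res_b.loc[shared], lsuffix="_a", rsuffix="_b")
    sig = joined[(joined["fdr_a"] < fdr_threshold)
                 & (joined["fdr_b"] < fdr_threshold)].copy()
    sig["same_direction"] = (sig["hr_a"] < 1.0) == (sig["hr_b"] < 1.0)
    sig.attrs["fraction_same_direction"] = (
        float(sig["same_direction"].mean()) if len(sig) else np.nan
    )
    return sig


def km_median_split(expr: Sequence[float], time: Sequence[float],
                    event: Sequence[int]):
    """Kaplan-Meier curves for a median split of expression, plus the HR.

    Samples with expression strictly above the median form the "high"
    stratum; ties at the median go to "low".  Returns
    ``(km_low, km_high, hr_low_vs_high)`` where the KM tables have columns
    time and survival (product-limit estimate) and the HR compares low to
    high expression from a single binary-covariate Cox fit.
    """
    from lifelines import KaplanMeierFitter

    expr = np.asarray(expr, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    high = expr > np.median(expr)
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty stratum")

    def km_table(mask):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        return pd.DataFrame({"time": sf.index.to_numpy(),
                             "survival": sf.iloc[:, 0].to_numpy()})

    ws = CoxWorkspace(time, event)
    res = fit_cox_single_gene((~high).astype(float), None, None,
                              workspace=ws, gene="low_vs_high")
    return km_table(~high), km_table(high), res


def wald_p_from_hr_ci(hr: float, ci_low: float, ci_high: float,
                      level: float = 0.95) -> float:
    """Two-sided Wald p-value reconstructed from a printed HR and its CI.

    The CI is assumed symmetric on the log scale, so
    SE = (ln ci_high - ln ci_low) / (2 z) and p = 2 Phi(-|ln hr| / SE).
    """
    if not (0 < ci_low <= hr <= ci_high):
        raise ValueError("need 0 < ci_low <= hr <= ci_high")
    z = stats.norm.ppf(0.5 + level / 2)
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * z)
    if se == 0:
        return 0.0 if hr != 1.0 else 1.0
    return float(2 * stats.norm.sf(abs(np.log(hr)) / se))
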