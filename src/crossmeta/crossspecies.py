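"""Mouse-human orthologue resolution, direction concordance and the
randomisation null for the cross-species candidate funnel.

A mouse gene called differentially expressed between a weakly metastatic
line and its metastatic derivative is mapped to its best human orthologue
(highest protein identity; ambiguous many2many pairs discarded), intersected
with the genes significant in both patient cohorts, and kept when the mouse
direction of change is concordant with the expression level associated with
poor outcome (underexpressed <-> low, overexpressed <-> high).  Significance
of the concordant overlap is assessed by drawing random mouse gene sets of
the same size, assigning each gene a random direction with the observed
under/over frequencies, and counting matches against the human list.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import OVER, UNDER

__all__ = [
    "OrthologyRecord",
    "RandomisationConfig",
    "RandomisationResult",
    "resolve_orthologues",
    "human_direction_of_poor_outcome",
    "concordance_intersect",
    "rank_candidates",
    "randomisation_test",
    "analytic_expected_concordant",
]

logger = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"
UNDEFINED = "undefined"

ONE2ONE = "one2one"
ONE2MANY = "one2many"
MANY2MANY = "many2many"


@dataclass(frozen=True)
class OrthologyRecord:
    mouse_gene: str
    human_gene: str
    ortho_class: str
    pct_identity: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.ortho_class not in (ONE2ONE, ONE2MANY, MANY2MANY):
            raise ValueError(f"unknown orthology class {self.ortho_class!r}")


def resolve_orthologues(records: Iterable[OrthologyRecord]) -> dict[str, str]:
    """Resolve each mouse gene to at most one human orthologue.

    many2many mouse genes are dropped entirely; among a one2many gene's
    partners the highest protein identity wins, ties broken
    lexicographically on the human ID (logged).  Duplicate (mouse, human)
    rows with conflicting identities raise.
    """
    by_mouse: dict[str, list[OrthologyRecord]] = {}
    seen: dict[tuple[str, str], float] = {}
    dropped: set[str] = set()
    for rec in records:
        key = (rec.mouse_gene, rec.human_gene)
        if key in seen and seen[key] != rec.pct_identity:
            raise ValueError(f"conflicting identity for pair {key}")
        seen[key] = rec.pct_identity
        if rec.ortho_class == MANY2MANY:
            dropped.add(rec.mouse_gene)
        by_mouse.setdefault(rec.mouse_gene, []).append(rec)
    out: dict[str, str] = {}
    for mouse, recs in by_mouse.items():
        if mouse in dropped:
            continue
        best = min(recs, key=lambda r: (-r.pct_identity, r.human_gene))
        top = [r for r in recs if r.pct_identity == best.pct_identity]
        if len(top) > 1:
            logger.warning("identity tie for mouse gene %s; choosing %s",
                           mouse, best.human_gene)
        out[mouse] = best.human_gene
    return out


def human_direction_of_poor_outcome(hr_a: float, hr_b: float) -> str:
    """Expression level associated with poor outcome, given two cohort HRs.

    HR < 1 per unit log2 expression in both cohorts means high expression is
    protective, so LOW expression marks poor outcome; HR > 1 in both means
    HIGH.  Discordant cohorts (or an HR of exactly 1) are UNDEFINED.
    """
    if hr_a < 1 and hr_b < 1:
        return LOW
    if hr_a > 1 and hr_b > 1:
        return HIGH
    return UNDEFINED


_CONCORDANT = {(UNDER, LOW), (OVER, HIGH)}


def concordance_intersect(mouse_de: Mapping[str, str],
                          ortho_map: Mapping[str, str],
                          human_dual: pd.DataFrame,
                          human_panel: Iterable[str] | None = None):
    """Intersect mouse DE genes with the dual-significant human list.

    mouse_de : mouse gene -> direction ("over"/"under"; ambiguous genes
        should already be excluded).
    ortho_map : resolved mouse -> human map.
    human_dual : output of :func:`survival.intersect_cohorts`, indexed by
        human gene with columns hr_a, hr_b, same_direction.
    human_panel : optionally, the human genes screened in both cohorts; the
        funnel's "intersected with panel" stage counts mapped genes whose
        orthologue is in this panel (defaults to the human_dual index union).

    Returns (table, funnel) where the table has one row per mouse DE gene
    retained to the dual-significant stage, with columns mouse_gene,
    human_gene, mouse_direction, human_poor_outcome_expression, concordant;
    funnel is a dict of stage counts (de -> mapped -> in_panel ->
    dual_significant -> concordant).
    """
    funnel = {"de": len(mouse_de)}
    mapped = {m: ortho_map[m] for m in mouse_de if m in ortho_map}
    funnel["mapped"] = len(mapped)
    panel = set(human_panel) if human_panel is not None else set(human_dual.index)
    in_panel = {m: h for m, h in mapped.items() if h in panel}
    funnel["in_panel"] = len(in_panel)

    rows = []
    for mouse, human in in_panel.items():
        if human not in human_dual.index:
            continue
        hrow = human_dual.loc[human]
        direction = human_direction_of_poor_outcome(hrow["hr_a"], hrow["hr_b"])
        if direction == UNDEFINED:
            continue
        mdir = mouse_de[mouse]
        rows.append({
            "mouse_gene": mouse,
            "human_gene": human,
            "mouse_direction": mdir,
            "human_poor_outcome_expression": direction,
            "concordant": (mdir, direction) in _CONCORDANT,
        })
    table = pd.DataFrame(rows, columns=["mouse_gene", "human_gene",
                                        "mouse_direction",
                                        "human_poor_outcome_expression",
                                        "concordant"])
    funnel["dual_significant"] = len(table)
    funnel["concordant"] = int(table["concordant"].sum()) if len(table) else 0
    return table, funnel


def rank_candidates(candidates: pd.DataFrame, hr_col: str = "hr_a",
                    p_col: str = "p_b") -> pd.DataFrame:
    """Order candidate genes for reporting.

    Protective genes (cohort-A HR < 1) come first in ascending HR order;
    adverse genes (HR > 1) are placed last; ties are broken by the cohort-B
    p-value ascending.
    """
    if candidates.empty:
        raise ValueError("no candidates to rank")
    df = candidates.copy()
    df["_adverse"] = df[hr_col] > 1.0
    df = df.sort_values(["_adverse", hr_col, p_col],
                        ascending=[True, True, True])
    return df.drop(columns="_adverse")


@dataclass
class RandomisationConfig:
    """Parameters of the gene-set overlap randomisation test.

    m random mouse genes are drawn without replacement from the expressed
    universe in each of n_samples iterations; each drawn gene gets an
    independent random direction (under with probability p_under), and the
    null statistic counts drawn genes present in the human poor-outcome
    list whose random direction matches the human gene's direction.
    """

    m: int
    n_samples: int = 1000
    p_under: float = 0.4621429
    p_over: float = 0.5378571
    seed: int = 0
    observed_count: int = 0

    def __post_init__(self) -> None:
        if abs(self.p_under + self.p_over - 1.0) > 1e-9:
            raise ValueError("p_under + p_over must equal 1")
        if self.m < 0 or self.n_samples < 1:
            raise ValueError("m and n_samples must be non-negative/positive")


@dataclass
class RandomisationResult:
    null_counts: np.ndarray
    observed_count: int
    empirical_p: float
    empirical_p_plus_one: float

    def summary(self) -> dict:
        return {
            "observed": self.observed_count,
            "null_mean": float(self.null_counts.mean()),
            "null_sd": float(self.null_counts.std(ddof=1)),
            "empirical_p": self.empirical_p,
            "empirical_p_plus_one": self.empirical_p_plus_one,
            "n_samples": int(self.null_counts.size),
        }


def randomisation_test(universe: Sequence[str],
                       human_directions: Mapping[str, str],
                       config: RandomisationConfig) -> RandomisationResult:
    """Empirical null for the concordant-overlap count.

    universe : mouse genes eligible for drawing (expressed universe).
    human_directions : human-list gene -> poor-outcome expression direction
        ("low"/"high"), keyed on the same IDs as the universe (i.e. already
        mapped through orthology).
    """
    universe = list(universe)
    n = len(universe)
    if config.m > n:
        raise ValueError("sample size m exceeds universe size")
    # per-gene direction the random assignment must match: "low" matches an
    # "under" draw, "high" matches "over"
    in_list = np.zeros(n, bool)
    wants_under = np.zeros(n, bool)
    for i, g in enumerate(universe):
        d = human_directions.get(g)
        if d == LOW:
            in_list[i] = True
            wants_under[i] = True
        elif d == HIGH:
            in_list[i] = True
    rng = np.random.default_rng(config.seed)
    counts = np.empty(config.n_samples, dtype=int)
    for s in range(config.n_samples):
        drawn = rng.choice(n, size=config.m, replace=False)
        under = rng.random(config.m) < config.p_under
        hit = in_list[drawn] & (under == wants_under[drawn])
        counts[s] = int(hit.sum())
    r = int((counts >= config.observed_count).sum())
    return RandomisationResult(
        null_counts=counts,
        observed_count=config.observed_count,
        empirical_p=r / config.n_samples,
        empirical_p_plus_one=(r + 1) / (config.n_samples + 1),
    )


def analytic_expected_concordant(universe: Sequence[str],
                                 human_directions: Mapping[str, str],
                                 m: int, p_under: float):
    """Closed-form mean and variance of the randomisation null count.

    Each human-list gene g in the universe contributes a Bernoulli with
    success probability (m/N) * p_dir(g); inclusion indicators covary under
    sampling without replacement with P(both drawn) = m(m-1)/(N(N-1)).
    """
    n = len(universe)
    if m > n:
        raise ValueError("m exceeds universe size")
    if n == 0 or m == 0:
        return 0.0, 0.0
    probs = []
    for g in universe:
        d = human_directions.get(g)
        if d == LOW:
            probs.append(p_under)
        elif d == HIGH:
            probs.append(1.0 - p_under)
    probs = np.asarray(probs)
    f1 = m / n
    e = f1 * probs.sum()
    f2 = m * (m - 1) / (n * (n - 1)) if n > 1 else 0.0
    var = float(np.sum(f1 * probs * (1 - f1 * probs)))
    cross = probs.sum() ** 2 - np.sum(probs**2)
    var += float((f2 - f1**2) * cross)
    return float(e), var
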