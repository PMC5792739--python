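"""End-to-end orchestration: screens -> DE -> orthology -> concordance ->
randomisation, with a machine-readable funnel report.

The funnel mirrors the candidate-discovery analysis: genes differentially
expressed between weakly and highly metastatic mouse lines are mapped to
human orthologues, intersected with the panel screened in two patient
cohorts, reduced to those significant in both cohorts, and finally to those
whose direction of change is concordant with poor outcome; a randomisation
test quantifies how surprising the concordant count is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field



import pandas as pd

from . import crossspecies as xs
from . import diffexp as de
from . import survival as surv
from .synthetic import EndToEndFixture

__all__ = ["PipelineConfig", "FunnelReport", "run_all", "report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the published analysis values."""

    screen: surv.ScreenConfig = field(
        default_factory=lambda: surv.ScreenConfig(adjust_covariates=("age", "sex")))
    de: de.DEConfig = field(default_factory=de.DEConfig)
    rand_n_samples: int = 1000
    rand_m: int | None = None  # defaults to the orthologue-mapped DE count
    seed: int = 0


@dataclass
class FunnelReport:
    """Stage-by-stage gene counts plus the final candidate table."""

    funnel: dict
    screen_a: pd.DataFrame
    screen_b: pd.DataFrame
    dual_significant: pd.DataFrame
    de_table: pd.DataFrame
    concordance: pd.DataFrame
    candidates: pd.DataFrame
    randomisation: dict

    def to_json(self) -> str:
        payload = {
            "funnel": self.funnel,
            "randomisation": self.randomisation,
            "candidates": self.candidates.reset_index(drop=True).to_dict(
                orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def run_all(fixture: EndToEndFixture,
            config: PipelineConfig | None = None) -> FunnelReport:
    """Run every stage on an in-memory study and assemble the funnel.

    Cohort A is screened with age/sex adjustment (per config), cohort B
    unadjusted; the randomisation null draws from the mouse genes that
    passed the DE expression filter, with direction probabilities taken
    from the observed DE direction frequencies.
    """
    config = config or PipelineConfig()
    screen_a = surv.run_cohort_screen(fixture.cohort_a, config.screen)
    screen_b = surv.run_cohort_screen(
        fixture.cohort_b,
        surv.ScreenConfig(fdr_threshold=config.screen.fdr_threshold,
                          ties_method=config.screen.ties_method))
    dual = surv.intersect_cohorts(screen_a, screen_b,
                                  config.screen.fdr_threshold)
    logger.info("screen: %d/%d dual-significant (FDR < %g)", len(dual),
                len(screen_a), config.screen.fdr_threshold)

    groups = fixture.counts.groups.unique()
    parental = [g for g in groups if "parental" in g] or [groups[0]]
    derivatives = [g for g in groups if g not in parental]
    tables = {
        f"{d}_vs_{parental[0]}": de.run_de_comparison(
            fixture.counts, d, parental[0], config.de)
        for d in derivatives
    }
    union = de.de_union(tables)
    unambiguous = union[~union["ambiguous"]]
    mouse_de: dict[str, str] = dict(zip(unambiguous.index,
                                        unambiguous["direction"]))

    ortho_map = xs.resolve_orthologues(fixture.orthology)
    human_panel = set(screen_a.index) & set(screen_b.index)
    same_dir = dual[dual["same_direction"]]
    conc_table, funnel = xs.concordance_intersect(
        mouse_de, ortho_map, same_dir, human_panel=human_panel)

    # randomisation: universe = mouse genes passing the expression filter in
    # every comparison they appear in; directions keyed on mouse IDs through
    # the orthologue map
    any_tested = pd.concat([t["status"] == "tested" for t in tables.values()],
                           axis=1).any(axis=1)
    universe = list(any_tested.index[any_tested])
    human_dirs: dict[str, str] = {}
    for mg in universe:
        hg = ortho_map.get(mg)
        if hg is not None and hg in same_dir.index:
            row = same_dir.loc[hg]
            d = xs.human_direction_of_poor_outcome(row["hr_a"], row["hr_b"])
            if d != xs.UNDEFINED:
                human_dirs[mg] = d
    n_under = sum(1 for v in mouse_de.values() if v == de.UNDER)
    p_under = n_under / len(mouse_de) if mouse_de else 0.5
    m = config.rand_m if config.rand_m is not None else funnel["mapped"]
    m = min(m, len(universe))
    rand_cfg = xs.RandomisationConfig(
        m=m, n_samples=config.rand_n_samples, p_under=p_under,
        p_over=1 - p_under, seed=config.seed,
        observed_count=funnel["concordant"])
    rand = (xs.randomisation_test(universe, human_dirs, rand_cfg)
            if universe else None)

    concordant = conc_table[conc_table["concordant"]]
    if len(concordant):
        stats = []
        for _, row in concordant.iterrows():
            hg = row["human_gene"]
            stats.append({
                "gene": hg, "mouse_gene": row["mouse_gene"],
                "mouse_direction": row["mouse_direction"],
                "hr_a": screen_a.loc[hg, "hr"], "p_a": screen_a.loc[hg, "p"],
                "fdr_a": screen_a.loc[hg, "fdr"],
                "hr_b": screen_b.loc[hg, "hr"], "p_b": screen_b.loc[hg, "p"],
                "fdr_b": screen_b.loc[hg, "fdr"],
            })
        candidates = xs.rank_candidates(pd.DataFrame(stats))
    else:
        candidates = pd.DataFrame(
            columns=["gene", "mouse_gene", "mouse_direction", "hr_a", "p_a",
                     "fdr_a", "hr_b", "p_b", "fdr_b"])

    funnel_out = {
        "screened_genes": int(len(screen_a)),
        "dual_significant_human": int(len(dual)),
        "same_direction_human": int(len(same_dir)),
        "de": funnel["de"],
        "mapped": funnel["mapped"],
        "in_panel": funnel["in_panel"],
        "dual_significant": funnel["dual_significant"],
        "concordant": funnel["concordant"],
    }
    return FunnelReport(
        funnel=funnel_out,
        screen_a=screen_a,
        screen_b=screen_b,
        dual_significant=dual,
        de_table=union,
        concordance=conc_table,
        candidates=candidates,
        randomisation=(rand.summary() if rand is not None
                       else {"observed": 0, "empirical_p": float("nan")}),
    )


def report(funnel_report: FunnelReport) -> str:
    """Human-readable rendering of a funnel report."""
    f = funnel_report.funnel
    lines = [
        "Cross-species candidate funnel",
        "------------------------------",
        f"genes screened per cohort        {f['screened_genes']}",
        f"dual-significant (both cohorts)  {f['dual_significant_human']}",
        f"  of which same direction        {f['same_direction_human']}",
        f"mouse DE genes                   {f['de']}",
        f"  orthologue-mapped              {f['mapped']}",
        f"  in screened panel              {f['in_panel']}",
        f"  dual-significant orthologue    {f['dual_significant']}",
        f"  direction-concordant           {f['concordant']}",
        "",
    ]
    r = funnel_report.randomisation
    if r.get("n_samples"):
        lines.append(
            f"randomisation null: mean {r['null_mean']:.2f} "
            f"(sd {r['null_sd']:.2f}) over {r['n_samples']} samples; "
            f"P(X >= {r['observed']}) = {r['empirical_p']:.4g} "
            f"[(r+1)/(n+1) = {r['empirical_p_plus_one']:.4g}]")
    if len(funnel_report.candidates):
        lines.append("")
        lines.append("Candidates (protective first, ascending cohort-A HR):")
        cols = ["gene", "mouse_direction", "hr_a", "fdr_a", "hr_b", "fdr_b"]
        lines.append(funnel_report.candidates[cols].to_string(index=False))
    else:
        lines.append("")
        lines.append("Zero candidate genes survived the funnel.")
    return "\n".join(lines)
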