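"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study's data shapes: patient cohorts with
exponential-hazard survival driven log-linearly by log2 expression (so
proportional hazards holds exactly and screen recovery is a fair test),
negative-binomial RNA-seq counts with sample size factors and planted fold
changes, an orthology table with one2one/one2many/many2many classes, VCFs
whose records are engineered to trigger exactly one filter stage each, and
mutation catalogues drawn from known signature mixtures.  One seed governs
all sub-generators through a splittable stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crossspecies import MANY2MANY, ONE2MANY, ONE2ONE, OrthologyRecord
from .diffexp import CountMatrix
from .mutsig import MutationCatalogue
from .survival import CohortDataset
from .variants import SVIntervalSet, VariantRecord

__all__ = [
    "CohortSimSpec",
    "CountSimSpec",
    "VariantSimSpec",
    "simulate_cohort",
    "simulate_counts",
    "simulate_orthology",
    "simulate_variants",
    "simulate_catalogues",
    "simulate_signature_study",
    "EndToEndFixture",
    "make_end_to_end_fixture",
]


# ---------------------------------------------------------------------------
# patient cohorts

@dataclass
class CohortSimSpec:
    """Generative model of one patient cohort.

    Expression is standard normal per gene on the log2 scale; each
    patient's event hazard is ``baseline_hazard * exp(sum_g beta_g x_g +
    age/sex terms)`` (exponential event times, units: per month), censoring
    is an independent exponential.
    """

    n_patients: int = 400
    n_genes: int = 2000
    effect_genes: Mapping[int, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    censor_rate: float = 0.01
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0})
    effect_correlation: float = 0.0
    seed: int = 0
    cohort_label: str = "synthetic"
    gene_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard and censoring rates must be positive")
        if any(not 0 <= g < self.n_genes for g in self.effect_genes):
            raise ValueError("effect gene index out of range")
        if not 0.0 <= self.effect_correlation < 1.0:
            raise ValueError("effect_correlation must lie in [0, 1)")


def simulate_cohort(spec: CohortSimSpec) -> CohortDataset:
    """Draw one cohort with exponential survival and planted gene effects.

    With ``effect_correlation`` rho > 0 the effect genes co-express through
    a single latent programme: each effect gene's expression is
    sign(beta) * (sqrt(rho) f + sqrt(1-rho) eps) with f shared per patient,
    so every effect gene stays marginally standard normal but prognostic
    signal is concentrated in one axis, as in real transcriptional
    programmes, instead of acting as per-gene frailty noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_patients, spec.n_genes
    expr = rng.standard_normal((g, n))
    if spec.effect_correlation > 0 and spec.effect_genes:
        rho = spec.effect_correlation
        f = rng.standard_normal(n)
        for gene_idx, beta in spec.effect_genes.items():
            sign = 1.0 if beta >= 0 else -1.0
            expr[gene_idx] = sign * (np.sqrt(rho) * f
                                     + np.sqrt(1 - rho) * expr[gene_idx])
    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n)
    log_hr = np.zeros(n)
    for gene_idx, beta in spec.effect_genes.items():
        log_hr += beta * expr[gene_idx]
    log_hr += spec.covariate_effects.get("age", 0.0) * (age - age.mean())
    log_hr += spec.covariate_effects.get("sex", 0.0) * sex
    hazard = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / spec.censor_rate, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    genes = (list(spec.gene_names) if spec.gene_names is not None
             else [f"G{i:05d}" for i in range(g)])
    samples = [f"{spec.cohort_label}_s{i:04d}" for i in range(n)]
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    survival = pd.DataFrame(
        {"time": time, "event": event, "age": age, "sex": sex},
        index=pd.Index(samples, name="sample"),
    )
    return CohortDataset(expression=expression, survival=survival,
                         cohort_label=spec.cohort_label)


# ---------------------------------------------------------------------------
# RNA-seq counts

@dataclass
class CountSimSpec:
    """Negative-binomial count model for a parental/derivative pair.

    Counts are NB with mean ``size_factor * baseline * 2**log2fc`` (fold
    change applied to the derivative group only) and variance
    ``mu + alpha * mu^2``.
    """

    n_genes: int = 2000
    replicates_per_group: int = 5
    baseline_means: np.ndarray | float = 100.0
    dispersions: np.ndarray | float = 0.05
    planted_log2fc: Mapping[int, float] = field(default_factory=dict)
    size_factors: Sequence[float] | None = None
    gene_lengths: np.ndarray | float = 1000.0
    seed: int = 0
    parental_label: str = "parental"
    derivative_label: str = "derivative"
    gene_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dispersions) < 0):
            raise ValueError("dispersions must be >= 0")
        if np.any(np.asarray(self.baseline_means) <= 0):
            raise ValueError("baseline means must be positive")
        if any(not 0 <= g < self.n_genes for g in self.planted_log2fc):
            raise ValueError("planted gene index out of range")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2) via gamma-Poisson; Poisson at alpha=0."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha == 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        shape = 1.0 / alpha[~poisson]
        lam = rng.gamma(shape, mu[~poisson] / shape)
        out[~poisson] = rng.poisson(lam)
    return out


def simulate_counts(spec: CountSimSpec) -> CountMatrix:
    """Draw an integer count matrix with planted derivative fold changes."""
    rng = np.random.default_rng(spec.seed)
    g, r = spec.n_genes, spec.replicates_per_group
    mu0 = np.broadcast_to(np.asarray(spec.baseline_means, float), (g,)).copy()
    alpha = np.broadcast_to(np.asarray(spec.dispersions, float), (g,)).copy()
    lengths = np.broadcast_to(np.asarray(spec.gene_lengths, float), (g,)).copy()
    lfc = np.zeros(g)
    for idx, val in spec.planted_log2fc.items():
        lfc[idx] = val
    sf = (np.ones(2 * r) if spec.size_factors is None
          else np.asarray(spec.size_factors, float))
    if sf.shape != (2 * r,):
        raise ValueError("size_factors must have one entry per sample")
    mu = np.empty((g, 2 * r))
    mu[:, :r] = mu0[:, None] * sf[None, :r]
    mu[:, r:] = (mu0 * 2.0**lfc)[:, None] * sf[None, r:]
    counts = _nb_draw(rng, mu, np.broadcast_to(alpha[:, None], mu.shape))

    genes = (list(spec.gene_names) if spec.gene_names is not None
             else [f"m{i:05d}" for i in range(g)])
    samples = ([f"{spec.parental_label}_r{i + 1}" for i in range(r)]
               + [f"{spec.derivative_label}_r{i + 1}" for i in range(r)])
    groups = pd.Series([spec.parental_label] * r + [spec.derivative_label] * r,
                       index=samples, name="group")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# orthology

def simulate_orthology(n_mouse: int, class_mix: Sequence[float] = (0.8, 0.1, 0.1),
                       seed: int = 0,
                       mouse_names: Sequence[str] | None = None,
                       human_names: Sequence[str] | None = None,
                       ) -> list[OrthologyRecord]:
    """Orthology table with one2one / one2many / many2many classes.

    one2one genes get exactly one partner; one2many genes get 2-3 partners
    with distinct identity percentages (so resolution is unambiguous);
    many2many genes are flagged for discarding.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    mouse = (list(mouse_names) if mouse_names is not None
             else [f"m{i:05d}" for i in range(n_mouse)])
    human = (list(human_names) if human_names is not None
             else [f"H{i:05d}" for i in range(n_mouse)])
    classes = rng.choice([ONE2ONE, ONE2MANY, MANY2MANY], size=n_mouse,
                         p=list(class_mix))
    records: list[OrthologyRecord] = []
    for i, (mg, hg, cls) in enumerate(zip(mouse, human, classes)):
        if cls == ONE2ONE:
            records.append(OrthologyRecord(mg, hg, cls,
                                           float(rng.uniform(70, 100))))
        elif cls == ONE2MANY:
            n_partners = int(rng.integers(2, 4))
            idents = rng.choice(np.arange(50, 100), size=n_partners,
                                replace=False).astype(float)
            # the true partner always carries the highest identity
            order = np.argsort(idents)[::-1]
            partners = [hg] + [f"{hg}_alt{j}" for j in range(1, n_partners)]
            for j, pi in enumerate(order):
                records.append(OrthologyRecord(mg, partners[j], cls,
                                               float(idents[pi])))
        else:
            for j in range(2):
                records.append(OrthologyRecord(mg, f"{hg}_mm{j}", cls,
                                               float(rng.uniform(50, 100))))
    return records


# ---------------------------------------------------------------------------
# variants

@dataclass
class VariantSimSpec:
    """Variant fixture: clean records plus per-stage filter triggers.

    Each triggered record violates exactly one filter stage, so per-stage
    removal counts are known by construction.
    """

    n_clean: int = 50
    n_low_qual: int = 10
    n_low_support: int = 10
    n_near_indel: int = 10
    n_in_panel: int = 10
    n_near_sv: int = 10
    contig: str = "chr1"
    contig_length: int = 1_000_000
    seed: int = 0

    def trigger_counts(self) -> dict[str, int]:
        return {
            "low_qual": self.n_low_qual,
            "low_support": self.n_low_support,
            "near_indel": self.n_near_indel,
            "in_panel": self.n_in_panel,
            "near_sv": self.n_near_sv,
        }


def simulate_variants(spec: VariantSimSpec):
    """Build (records, strain panel, SV intervals) for the filter pipeline.

    Clean records (every fifth one an insertion, so the SNV-near-indel
    stage has indels to anchor on) are spaced 1 kb apart; each trigger
    class occupies its own region of the contig.  Returns
    (records, panel, svs, truth) where truth maps each class to its
    record keys.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_near_indel > 0 and spec.n_clean < 5:
        raise ValueError("need clean indels to anchor near-indel triggers")
    records: list[VariantRecord] = []
    truth: dict[str, list] = {k: [] for k in ("clean", *spec.trigger_counts())}

    def base_pair():
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        return str(ref), str(alt)

    regions = {"clean": 10_000, "low_qual": 200_000, "low_support": 300_000,
               "in_panel": 400_000, "near_sv": 500_000}
    if regions["near_sv"] + 1000 * max(spec.n_near_sv, 1) > spec.contig_length:
        raise ValueError("contig too short for requested record counts")

    clean_indels = []
    for i in range(spec.n_clean):
        pos = regions["clean"] + i * 1000
        ref, alt = base_pair()
        if i % 5 == 4:  # insertion
            rec = VariantRecord(spec.contig, pos, ref, ref + alt,
                                qual=float(rng.uniform(40, 90)),
                                support=int(rng.integers(8, 30)))
            clean_indels.append(rec)
        else:
            rec = VariantRecord(spec.contig, pos, ref, alt,
                                qual=float(rng.uniform(40, 90)),
                                support=int(rng.integers(8, 30)))
        records.append(rec)
        truth["clean"].append(rec.key)

    for i in range(spec.n_low_qual):
        ref, alt = base_pair()
        rec = VariantRecord(spec.contig, regions["low_qual"] + i * 1000, ref,
                            alt, qual=float(rng.uniform(1, 19.5)),
                            support=int(rng.integers(8, 30)))
        records.append(rec)
        truth["low_qual"].append(rec.key)

    for i in range(spec.n_low_support):
        ref, alt = base_pair()
        rec = VariantRecord(spec.contig, regions["low_support"] + i * 1000,
                            ref, alt, qual=float(rng.uniform(40, 90)),
                            support=int(rng.integers(1, 5)))
        records.append(rec)
        truth["low_support"].append(rec.key)

    if spec.n_near_indel > 0 and not clean_indels:
        raise ValueError("no clean indels generated to anchor triggers")
    for i in range(spec.n_near_indel):
        anchor = clean_indels[i % len(clean_indels)]
        offset = 2 + (i // len(clean_indels)) % 7  # within gap of 10, distinct pos
        ref, alt = base_pair()
        rec = VariantRecord(spec.contig, anchor.pos + offset, ref, alt,
                            qual=float(rng.uniform(40, 90)),
                            support=int(rng.integers(8, 30)))
        records.append(rec)
        truth["near_indel"].append(rec.key)

    panel: list[tuple[str, int, str]] = []
    for i in range(spec.n_in_panel):
        ref, alt = base_pair()
        pos = regions["in_panel"] + i * 1000
        rec = VariantRecord(spec.contig, pos, ref, alt,
                            qual=float(rng.uniform(40, 90)),
                            support=int(rng.integers(8, 30)))
        records.append(rec)
        panel.append((spec.contig, pos, alt))
        truth["in_panel"].append(rec.key)

    sv_intervals = []
    for i in range(spec.n_near_sv):
        start = regions["near_sv"] + i * 1000
        sv_intervals.append((spec.contig, start, start + 100))
        ref, alt = base_pair()
        rec = VariantRecord(spec.contig, start - int(rng.integers(0, 51)), ref,
                            alt, qual=float(rng.uniform(40, 90)),
                            support=int(rng.integers(8, 30)))
        records.append(rec)
        truth["near_sv"].append(rec.key)
    svs = SVIntervalSet(sv_intervals)
    return records, panel, svs, truth


# ---------------------------------------------------------------------------
# mutation catalogues

def simulate_catalogues(signatures: np.ndarray | pd.DataFrame,
                        exposures: np.ndarray | pd.DataFrame,
                        n_mutations: Sequence[int],
                        seed: int = 0) -> list[MutationCatalogue]:
    """Draw multinomial catalogues from exposure-weighted signature mixtures."""
    sig = np.asarray(signatures, float)
    exp_ = np.atleast_2d(np.asarray(exposures, float))
    if np.any(exp_ < 0):
        raise ValueError("exposures must be non-negative")
    if sig.ndim != 2 or sig.shape[1] != 96:
        raise ValueError("signatures must be k x 96")
    if np.any(np.abs(sig.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("signature rows must sum to 1")
    rng = np.random.default_rng(seed)
    out = []
    for i, (w, n) in enumerate(zip(exp_, n_mutations)):
        if w.sum() == 0:
            probs = np.full(96, 1.0 / 96)
        else:
            probs = (w / w.sum()) @ sig
        counts = (np.zeros(96, int) if n == 0
                  else rng.multinomial(int(n), probs / probs.sum()))
        out.append(MutationCatalogue(sample=f"sample_{i}", counts=counts))
    return out


def simulate_signature_study(k: int = 2, n_samples: int = 10,
                             n_mutations: int = 100_000, seed: int = 0):
    """Synthetic signature study: truth signatures plus mixed catalogues.

    Truth signatures are sparse Dirichlet draws over the 96 classes; samples
    fall into k groups, each dominated by one signature (dominant exposure
    0.7-0.95), mirroring cell-line series whose mutation spectra are each
    driven by a distinct process.  Returns (signatures k x 96, exposures
    n_samples x k, catalogues).
    """
    rng = np.random.default_rng(seed)
    sigs = rng.dirichlet(np.full(96, 0.2), size=k)
    per_group = n_samples // k
    rows = []
    for g in range(k):
        for _ in range(per_group):
            w = rng.uniform(0.05, 0.3, size=k)
            w[g] = rng.uniform(0.7, 0.95)
            rows.append(w)
    while len(rows) < n_samples:
        w = rng.uniform(0.05, 0.3, size=k)
        w[rng.integers(k)] = rng.uniform(0.7, 0.95)
        rows.append(w)
    exposures = np.asarray(rows)
    cats = simulate_catalogues(sigs, exposures, [n_mutations] * n_samples,
                               seed=seed)
    return sigs, exposures, cats


# ---------------------------------------------------------------------------
# end-to-end fixture

@dataclass
class EndToEndFixture:
    """A full mini-study with known planted truth.

    Planted concordant genes have matched human survival direction and
    mouse DE direction; decoy classes (human-only, mouse-only, discordant,
    many2many-DE) populate the other funnel exits.
    """

    cohort_a: CohortDataset
    cohort_b: CohortDataset
    counts: CountMatrix
    orthology: list[OrthologyRecord]
    truth: dict


def make_end_to_end_fixture(seed: int, n_patients: int = 400,
                            n_genes: int = 2000, n_concordant: int = 20,
                            beta: float = 0.7, log2fc: float = 3.0,
                            replicates: int = 5) -> EndToEndFixture:
    """Two cohorts + cell-line counts + orthology with planted concordance.

    Half the planted genes are under in the metastatic derivative and low
    in poor-outcome patients (both-cohort hazard ratio < 1 per unit log2
    expression), half are over/high.  When ``n_concordant`` is zero the
    fixture is a global null.  Mouse gene i maps to human gene i
    (one2one for all genes that matter; decoy one2many/many2many classes
    are planted among null genes).
    """
    if n_concordant > 0 and n_genes < n_concordant + 45:
        raise ValueError("n_genes too small to host planted genes and decoys")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    mouse_names = [f"m{i:05d}" for i in range(n_genes)]
    human_names = [f"H{i:05d}" for i in range(n_genes)]

    effects_human: dict[int, float] = {}
    planted_lfc: dict[int, float] = {}
    truth: dict = {"concordant_mouse": [], "concordant_human": [],
                   "direction": {}, "human_only": [], "mouse_only": [],
                   "discordant": [], "many2many_de": []}
    half = n_concordant // 2
    for i in range(n_concordant):
        under = i < (n_concordant - half)
        sign = -1.0 if under else 1.0
        effects_human[i] = sign * beta
        planted_lfc[i] = sign * log2fc
        truth["concordant_mouse"].append(mouse_names[i])
        truth["concordant_human"].append(human_names[i])
        truth["direction"][mouse_names[i]] = "under" if under else "over"

    decoy_base = n_concordant
    if n_concordant > 0:
        for j in range(10):  # human-significant only
            effects_human[decoy_base + j] = beta if j % 2 else -beta
            truth["human_only"].append(human_names[decoy_base + j])
        for j in range(10):  # mouse-DE only
            planted_lfc[decoy_base + 10 + j] = log2fc if j % 2 else -log2fc
            truth["mouse_only"].append(mouse_names[decoy_base + 10 + j])
        for j in range(10):  # discordant: mouse over while human low (and v.v.)
            idx = decoy_base + 20 + j
            effects_human[idx] = -beta if j % 2 else beta
            planted_lfc[idx] = log2fc if j % 2 else -log2fc
            truth["discordant"].append(mouse_names[idx])
        for j in range(5):  # many2many mouse genes that are DE: dropped at mapping
            idx = decoy_base + 30 + j
            planted_lfc[idx] = log2fc
            truth["many2many_de"].append(mouse_names[idx])

    cohort_a = simulate_cohort(CohortSimSpec(
        n_patients=n_patients, n_genes=n_genes, effect_genes=effects_human,
        covariate_effects={"age": 0.01, "sex": 0.2}, effect_correlation=0.3,
        seed=seeds[0], cohort_label="cohortA", gene_names=human_names))
    cohort_b = simulate_cohort(CohortSimSpec(
        n_patients=n_patients, n_genes=n_genes, effect_genes=effects_human,
        effect_correlation=0.3, seed=seeds[1], cohort_label="cohortB",
        gene_names=human_names))

    rng = np.random.default_rng(seeds[2])
    baselines = np.exp(rng.normal(np.log(150), 0.8, size=n_genes))
    baselines[list(planted_lfc)] = np.maximum(baselines[list(planted_lfc)], 100)
    sf = rng.uniform(0.7, 1.3, size=2 * replicates)
    counts = simulate_counts(CountSimSpec(
        n_genes=n_genes, replicates_per_group=replicates,
        baseline_means=baselines, dispersions=0.05,
        planted_log2fc=planted_lfc, size_factors=sf, seed=seeds[2],
        gene_names=mouse_names))

    # orthology: one2one everywhere except planted decoy classes among nulls
    rng_o = np.random.default_rng(seeds[3])
    records: list[OrthologyRecord] = []
    one2many_start = n_concordant + 40 if n_concordant > 0 else n_genes + 1
    for i in range(n_genes):
        mg, hg = mouse_names[i], human_names[i]
        if n_concordant > 0 and mg in truth["many2many_de"]:
            records.append(OrthologyRecord(mg, f"{hg}_mmA", MANY2MANY,
                                           float(rng_o.uniform(50, 100))))
            records.append(OrthologyRecord(mg, f"{hg}_mmB", MANY2MANY,
                                           float(rng_o.uniform(50, 100))))
        elif one2many_start <= i < one2many_start + 10:
            # one2many decoys: the true partner carries the higher identity
            records.append(OrthologyRecord(mg, hg, ONE2MANY, 90.0))
            records.append(OrthologyRecord(mg, f"{hg}_alt", ONE2MANY, 80.0))
        else:
            records.append(OrthologyRecord(mg, hg, ONE2ONE,
                                           float(rng_o.uniform(70, 100))))
    return EndToEndFixture(cohort_a=cohort_a, cohort_b=cohort_b, counts=counts,
                           orthology=records, truth=truth)
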