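"""96-context mutation catalogues, NMF signature extraction and
cosine-similarity matching to reference signatures.

Single-base substitutions are classified by the six pyrimidine-reference
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) and the flanking 5'/3'
bases; purine-reference calls are reverse-complemented onto the pyrimidine
strand.  Signatures are extracted by non-negative matrix factorisation with
multiplicative updates minimising the generalised Kullback-Leibler
divergence (the convention of the signature-analysis literature; a
Frobenius objective is available), and matched to a reference matrix by
maximal cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXT_CLASSES",
    "MutationCatalogue",
    "build_96_spectrum",
    "nmf_extract",
    "cosine_similarity",
    "match_to_reference",
    "read_signature_table",
    "write_signature_table",
]

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed 96-class ordering: substitution major, then 5' base, then 3' base
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def classify_snv(ref: str, alt: str, context: str) -> str:
    """Map one SNV with its trinucleotide context to a 96-class label.

    ``context`` is the 3-mer centred on the variant; its centre must equal
    ``ref``.  Purine references are folded onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in "AG":
        context = _revcomp(context)
        ref, alt = context[1], _revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalogue:
    """One sample's 96-component substitution-context spectrum."""

    sample: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("catalogue must have exactly 96 components")
        if np.any(self.counts < 0):
            raise ValueError("catalogue counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_CLASSES),
                         name=self.sample)


def build_96_spectrum(snvs: Iterable[tuple[str, str, str]],
                      sample: str = "") -> tuple[MutationCatalogue, list]:
    """Tally (ref, alt, trinucleotide-context) SNVs into a catalogue.

    Returns (catalogue, rejected) where rejected lists (record, reason)
    pairs for context/ref mismatches or non-substitutions.
    """
    counts = np.zeros(96, dtype=int)
    rejected = []
    for rec in snvs:
        try:
            counts[_CLASS_INDEX[classify_snv(*rec)]] += 1
        except ValueError as exc:
            rejected.append((rec, str(exc)))
    return MutationCatalogue(sample=sample, counts=counts), rejected


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    mask = v > 0
    return float(np.sum(v[mask] * np.log(v[mask] / wh[mask])) - v.sum() + wh.sum())


def nmf_extract(catalogues: Sequence[MutationCatalogue] | np.ndarray,
                k: int, n_restarts: int = 10, max_iter: int = 2000,
                tol: float = 1e-7, seed: int = 0,
                objective: str = "kl"):
    """Extract k signatures from a stack of catalogues by multiplicative NMF.

    The samples x 96 matrix V is factorised as E @ S (exposures x
    signatures) by Lee-Seung multiplicative updates minimising the
    generalised KL divergence (or the squared Frobenius norm with
    ``objective="frobenius"``); the best of ``n_restarts`` random
    initialisations by final objective wins.  Signature rows are normalised
    to sum to one, with exposures rescaled to compensate.

    Returns (signatures: DataFrame k x 96, exposures: DataFrame samples x k,
    objective_trace: list of per-iteration objective values for the winning
    restart, non-increasing).
    """
    if isinstance(catalogues, np.ndarray):
        v = np.asarray(catalogues, float)
        samples = [f"sample_{i}" for i in range(v.shape[0])]
    else:
        v = np.stack([c.counts.astype(float) for c in catalogues])
        samples = [c.sample for c in catalogues]
    if v.ndim != 2 or v.shape[1] != 96:
        raise ValueError("catalogue matrix must be samples x 96")
    if np.any(v < 0):
        raise ValueError("catalogues must be non-negative")
    if not 1 <= k <= min(v.shape):
        raise ValueError(f"k={k} infeasible for {v.shape[0]} samples")
    if objective not in ("kl", "frobenius"):
        raise ValueError("objective must be 'kl' or 'frobenius'")

    rng = np.random.default_rng(seed)
    eps = 1e-12
    best = None
    for _ in range(n_restarts):
        e = rng.uniform(0.1, 1.0, size=(v.shape[0], k)) * v.mean()
        s = rng.uniform(0.1, 1.0, size=(k, 96))
        trace = []
        prev = np.inf
        for _ in range(max_iter):
            wh = e @ s + eps
            if objective == "kl":
                s *= (e.T @ (v / wh)) / np.maximum(e.sum(axis=0)[:, None], eps)
                wh = e @ s + eps
                e *= ((v / wh) @ s.T) / np.maximum(s.sum(axis=1)[None, :], eps)
                obj = _kl_divergence(v, e @ s + eps)
            else:
                s *= (e.T @ v) / np.maximum(e.T @ e @ s, eps)
                e *= (v @ s.T) / np.maximum(e @ s @ s.T, eps)
                obj = float(np.sum((v - e @ s) ** 2))
            trace.append(obj)
            if prev - obj < tol * max(prev, 1.0):
                break
            prev = obj
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], e, s, trace)

    _, e, s, trace = best
    row_sums = np.maximum(s.sum(axis=1), eps)
    s = s / row_sums[:, None]
    e = e * row_sums[None, :]
    sig_names = [f"signature_{i + 1}" for i in range(k)]
    signatures = pd.DataFrame(s, index=sig_names, columns=list(CONTEXT_CLASSES))
    exposures = pd.DataFrame(e, index=samples, columns=sig_names)
    return signatures, exposures, trace


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two spectra; scale-invariant, in [0, 1]
    for non-negative inputs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb_ = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb_ == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb_))


def match_to_reference(extracted: pd.DataFrame,
                       reference: pd.DataFrame) -> pd.DataFrame:
    """Best cosine match of each extracted signature against a reference set.

    Both matrices must share the same 96-class column ordering.  Returns a
    table with columns extracted, best_match, cosine.
    """
    if list(extracted.columns) != list(reference.columns):
        raise ValueError("96-class orderings differ between matrices")
    rows = []
    for name, sig in extracted.iterrows():
        sims = reference.apply(lambda r: cosine_similarity(sig, r), axis=1)
        rows.append({"extracted": name, "best_match": sims.idxmax(),
                     "cosine": float(sims.max())})
    return pd.DataFrame(rows)


def read_signature_table(path: str | Path) -> pd.DataFrame:
    """Read the standard 96-row probability text table (classes x signatures)
    into a signatures x 96 DataFrame in the fixed class ordering."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_CLASSES) - set(tab.index)
    if missing:
        raise ValueError(f"signature table missing classes, e.g. {sorted(missing)[:3]}")
    return tab.loc[list(CONTEXT_CLASSES)].T


def write_signature_table(path: str | Path, signatures: pd.DataFrame) -> None:
    """Write signatures (rows) as the 96-row probability text table."""
    signatures.T.rename_axis("class").to_csv(path, sep="\t")
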