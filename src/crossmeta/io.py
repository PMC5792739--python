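"""Plain-text readers and writers for every pipeline input and output.

Expression/survival/count/orthology tables travel as TSV, variants as VCF
v4.2, SV intervals as BED, catalogues as a 96-row TSV in the fixed class
ordering.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crossspecies import OrthologyRecord
from .diffexp import CountMatrix
from .mutsig import CONTEXT_CLASSES, MutationCatalogue
from .survival import CohortDataset

__all__ = [
    "write_cohort", "read_cohort",
    "write_counts", "read_counts",
    "write_orthology", "read_orthology",
    "write_catalogues", "read_catalogues",
    "load_candidate_table",
]


def write_cohort(outdir: str | Path, cohort: CohortDataset,
                 prefix: str = "cohort") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.rename_axis("gene").to_csv(
        outdir / f"{prefix}_expression.tsv", sep="\t")
    cohort.survival.to_csv(outdir / f"{prefix}_survival.tsv", sep="\t")


def read_cohort(expr_path: str | Path, surv_path: str | Path,
                label: str = "") -> CohortDataset:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    survival = pd.read_csv(surv_path, sep="\t", index_col=0)
    return CohortDataset(expression=expr, survival=survival, cohort_label=label)


def write_counts(outdir: str | Path, matrix: CountMatrix,
                 prefix: str = "counts") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tab = matrix.counts.copy()
    tab.insert(0, "length", matrix.gene_lengths.astype(int))
    tab.rename_axis("gene").to_csv(outdir / f"{prefix}.tsv", sep="\t")
    sheet = pd.DataFrame({"group": matrix.groups})
    sheet["replicate"] = sheet.groupby("group").cumcount() + 1
    sheet.rename_axis("sample").to_csv(outdir / f"{prefix}_samples.tsv", sep="\t")


def read_counts(counts_path: str | Path,
                samples_path: str | Path) -> CountMatrix:
    tab = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = tab.pop("length")
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts=tab.astype(np.int64),
                       gene_lengths=lengths.astype(float),
                       groups=sheet["group"].loc[tab.columns])


def write_orthology(path: str | Path,
                    records: Iterable[OrthologyRecord]) -> None:
    df = pd.DataFrame([
        {"mouse_gene": r.mouse_gene, "human_gene": r.human_gene,
         "class": r.ortho_class, "pct_identity": r.pct_identity}
        for r in records
    ])
    df.to_csv(path, sep="\t", index=False)


def read_orthology(path: str | Path) -> list[OrthologyRecord]:
    df = pd.read_csv(path, sep="\t")
    return [OrthologyRecord(row.mouse_gene, row.human_gene, row["class"],
                            float(row.pct_identity))
            for _, row in df.iterrows()]


def write_catalogues(path: str | Path,
                     catalogues: Sequence[MutationCatalogue]) -> None:
    df = pd.DataFrame({c.sample: c.counts for c in catalogues},
                      index=list(CONTEXT_CLASSES)).rename_axis("class")
    df.to_csv(path, sep="\t")


def read_catalogues(path: str | Path) -> list[MutationCatalogue]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CONTEXT_CLASSES):
        df = df.loc[list(CONTEXT_CLASSES)]
    return [MutationCatalogue(sample=col, counts=df[col].to_numpy())
            for col in df.columns]


def load_candidate_table() -> pd.DataFrame:
    """The printed 28-gene candidate table (two-cohort survival statistics).

    Columns: gene, hr_a, ci_low_a, ci_high_a, p_a, fdr_a and the same with
    suffix _b for the second cohort (cohort A: Leeds melanoma-specific
    survival; cohort B: Lund overall survival).  Hazard ratios are per unit
    log2 expression.
    """
    with resources.files("crossmeta").joinpath(
            "data/candidate_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
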