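"""Matched-normal-free somatic variant filtering.

Cell lines derived decades ago have no matched germline sample, so somatic
calls are cleaned by (1) quality/support thresholds (QUAL >= 20, at least 5
variant-supporting reads), (2) removing SNVs within 10 bp of an indel where
alignment artefacts concentrate, (3) subtracting the strain-specific variant
panel of the inbred background, and (4) discarding variants within +/- 50 bp
of known structural variants.  Every input record lands in exactly one
bucket (kept, or one removal reason), and shared/private partitions across
cell-line series are tallied Venn-style.
"""

from __future__ import annotations


from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "SVIntervalSet",
    "quality_support_filter",
    "snp_gap_filter",
    "subtract_strain_panel",
    "exclude_near_sv",
    "run_filter_pipeline",
    "partition_shared",
    "read_vcf",
    "write_vcf",
    "read_bed_intervals",
]

SNV = "snv"
INDEL = "indel"

REASON_QUALITY = "quality"
REASON_SUPPORT = "support"
REASON_UNEVALUABLE = "unevaluable"
REASON_SNP_GAP = "snp_gap"
REASON_STRAIN_PANEL = "strain_panel"
REASON_NEAR_SV = "near_sv"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (single alt allele; multi-allelics are decomposed)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    support: int | None = None  # variant-supporting reads

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    @property
    def vtype(self) -> str:
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def affected_span(self) -> tuple[int, int]:
        """1-based inclusive positions touched by the reference allele."""
        return self.pos, self.pos + max(len(self.ref) - 1, 0)


@dataclass
class FilterConfig:
    qual_min: float = 20.0
    support_min: int = 5
    snp_gap: int = 10
    sv_pad: int = 50

    def __post_init__(self) -> None:
        if min(self.qual_min, self.support_min, self.snp_gap, self.sv_pad) < 0:
            raise ValueError("thresholds must be >= 0")


class SVIntervalSet:
    """Structural-variant intervals, 1-based inclusive, queried per contig."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"interval start > end on {chrom}")
            self._by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        for chrom, ivs in self._by_chrom.items():
            ivs.sort()
            self._max_len[chrom] = max(e - s for s, e in ivs)

    def near(self, chrom: str, pos: int, pad: int) -> bool:
        """True when pos lies within [start - pad, end + pad] of any interval."""
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        # only intervals starting in (pos - pad - max_len, pos + pad] can
        # reach pos once padded
        i = bisect_left(starts, pos + pad + 1)
        lo = bisect_left(starts, pos - pad - self._max_len[chrom])
        return any(s - pad <= pos <= e + pad for s, e in ivs[lo:i])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


def quality_support_filter(records: Sequence[VariantRecord],
                           config: FilterConfig):
    """Partition on QUAL and supporting-read thresholds (boundaries kept).

    Records missing either field are unevaluable and removed with their own
    reason code.
    """
    kept, removed = [], []
    for rec in records:
        if rec.qual is None or rec.support is None:
            removed.append((rec, REASON_UNEVALUABLE))
        elif rec.qual < config.qual_min:
            removed.append((rec, REASON_QUALITY))
        elif rec.support < config.support_min:
            removed.append((rec, REASON_SUPPORT))
        else:
            kept.append(rec)
    return kept, removed


def snp_gap_filter(records: Sequence[VariantRecord], gap: int):
    """Remove SNVs strictly within ``gap`` bp of an indel's affected span.

    Records must be sorted by (chrom, pos); indels are never removed here.
    """
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    spans: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.vtype == INDEL:
            spans.setdefault(rec.chrom, []).append(rec.affected_span())
    kept, removed = [], []
    for rec in records:
        if rec.vtype == SNV and rec.chrom in spans:
            dist = min(
                0 if s <= rec.pos <= e else min(abs(rec.pos - s), abs(rec.pos - e))
                for s, e in spans[rec.chrom]
            )
            if dist < gap:
                removed.append((rec, REASON_SNP_GAP))
                continue
        kept.append(rec)
    return kept, removed


def subtract_strain_panel(records: Sequence[VariantRecord],
                          panel: Iterable[tuple[str, int, str]],
                          position_only: bool = False):
    """Remove variants present in the strain panel.

    The panel is keyed by (chrom, pos, alt); with ``position_only`` any
    variant at a panel position is removed regardless of allele.
    """
    panel = set(panel)
    positions = {(c, p) for c, p, _ in panel}
    kept, removed = [], []
    for rec in records:
        hit = ((rec.chrom, rec.pos) in positions if position_only
               else (rec.chrom, rec.pos, rec.alt) in panel)
        if hit:
            removed.append((rec, REASON_STRAIN_PANEL))
        else:
            kept.append(rec)
    return kept, removed


def exclude_near_sv(records: Sequence[VariantRecord], svs: SVIntervalSet,
                    pad: int):
    """Remove variants within [start - pad, end + pad] of any SV, inclusive."""
    kept, removed = [], []
    for rec in records:
        if svs.near(rec.chrom, rec.pos, pad):
            removed.append((rec, REASON_NEAR_SV))
        else:
            kept.append(rec)
    return kept, removed


def run_filter_pipeline(records: Sequence[VariantRecord],
                        panel: Iterable[tuple[str, int, str]],
                        svs: SVIntervalSet,
                        config: FilterConfig | None = None):
    """Apply the full filtering strategy in order, with per-stage counts.

    Stage order: quality/support -> SNV-near-indel gap -> strain panel ->
    SV proximity.  Returns (kept_records, report) where the report maps
    each removal reason and "kept"/"input" to its count; every input record
    is accounted for exactly once.
    """
    config = config or FilterConfig()
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    report = {"input": len(records)}
    kept, rm_qs = quality_support_filter(records, config)
    kept, rm_gap = snp_gap_filter(kept, config.snp_gap)
    kept, rm_panel = subtract_strain_panel(kept, panel)
    kept, rm_sv = exclude_near_sv(kept, svs, config.sv_pad)
    for reason in (REASON_QUALITY, REASON_SUPPORT, REASON_UNEVALUABLE,
                   REASON_SNP_GAP, REASON_STRAIN_PANEL, REASON_NEAR_SV):
        report[reason] = 0
    for _, reason in (*rm_qs, *rm_gap, *rm_panel, *rm_sv):
        report[reason] += 1
    report["kept"] = len(kept)
    assert report["kept"] + sum(report[r] for r in report
                                if r not in ("kept", "input")) == report["input"]
    return kept, report


def partition_shared(sets: Mapping[str, Iterable[tuple]]) -> dict[str, int]:
    """Venn-region counts of variant keys shared between 2 or 3 call sets.

    Region labels join member names with "&"; the returned dict also holds
    ``total`` (union size).
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("partition_shared supports 2 or 3 sets")
    keyed = {n: set(map(tuple, s)) for n, s in sets.items()}
    universe = set().union(*keyed.values())
    regions: dict[str, int] = {}
    from itertools import combinations
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(keyed[n] for n in combo))
            outside = set().union(*(keyed[n] for n in names if n not in combo),
                                  set())
            regions["&".join(combo)] = len(inside - outside)
    regions["total"] = len(universe)
    return regions


# ---------------------------------------------------------------------------
# VCF / BED I/O

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    '##INFO=<ID=DP4,Number=4,Type=Integer,Description='
    '"Ref fwd, ref rev, alt fwd, alt rev read counts">',
]


def write_vcf(path: str | Path, records: Sequence[VariantRecord],
              contig_lengths: Mapping[str, int]) -> None:
    """Write records as a minimal well-formed VCF v4.2 text file.

    Supporting reads go to INFO/DP4 (split between strands) and total depth
    to INFO/DP (support plus a matching reference depth).
    """
    lines = list(VCF_HEADER_LINES)
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        if rec.pos > contig_lengths.get(rec.chrom, rec.pos):
            raise ValueError(f"position {rec.pos} beyond contig {rec.chrom}")
        qual = "." if rec.qual is None else f"{rec.qual:g}"
        if rec.support is None:
            info = "."
        else:
            fwd = rec.support // 2
            rev = rec.support - fwd
            info = f"DP={rec.support + 10};DP4=5,5,{fwd},{rev}"
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t"
                     f"{qual}\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, decomposing multi-allelic sites.

    Supporting reads are taken from INFO/DP4 (alt fwd + alt rev) when
    present, otherwise INFO/DP, per the convention that "DP < 5" counts
    reads supporting the variant.
    """
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        dp4 = v.INFO.get("DP4")
        dp = v.INFO.get("DP")
        if dp4 is not None:
            support = int(dp4[2]) + int(dp4[3])
        elif dp is not None:
            support = int(dp)
        else:
            support = None
        for alt in v.ALT:
            out.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                qual=None if v.QUAL is None else float(v.QUAL),
                support=support,
            ))
    return out


def read_bed_intervals(path: str | Path) -> SVIntervalSet:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, *_ = line.split("\t")
        intervals.append((chrom, int(start) + 1, int(end)))
    return SVIntervalSet(intervals)
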