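"""Aligned runs of homozygosity (AROH) from haplotype-pair alignments.

The two haplotypes of a phased diploid assembly are aligned pairwise (PAF in,
minimap2 dialect). Aligners frequently split very long collinear alignments
into artificial pieces, so collinear records are first chained back together;
a merged alignment is then classified as an aligned run of homozygosity when
it is longer than 50 kb and its estimated per-base divergence is below 0.01
(both thresholds strict, both configurable). Coverage summaries report the
proportion of the assembly covered by AROH of at least each length threshold.

Coordinates follow the PAF standard: 0-based, half-open. AROH intervals are
reported on the target haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PafRecord",
    "ArohInterval",
    "read_paf",
    "write_paf",
    "estimate_divergence",
    "filter_primary",
    "merge_collinear",
    "classify_aroh",
    "coverage_by_min_length",
]


@dataclass
class PafRecord:
    """One PAF alignment record (12 mandatory columns plus optional tags)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    de: Optional[float] = None  # per-base divergence tag (de:f)
    tags: Dict[str, str] = field(default_factory=dict)
    n_sources: int = 1  # alignments chained into this record

    def validate(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"query coordinates invalid: {self.qstart}-{self.qend}/{self.qlen}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"target coordinates invalid: {self.tstart}-{self.tend}/{self.tlen}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.nmatch > self.alnlen:
            raise ValueError("n_match exceeds alignment block length")

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart

    def to_paf_line(self) -> str:
        fields = [
            self.qname,
            str(self.qlen),
            str(self.qstart),
            str(self.qend),
            self.strand,
            self.tname,
            str(self.tlen),
            str(self.tstart),
            str(self.tend),
            str(self.nmatch),
            str(self.alnlen),
            str(self.mapq),
        ]
        if self.de is not None:
            fields.append(f"de:f:{self.de:.6g}")
        for tag, val in self.tags.items():
            fields.append(f"{tag}:{val}")
        return "\t".join(fields)


def read_paf(path) -> List[PafRecord]:
    """Parse a PAF file; malformed lines are skipped and logged with numbers."""
    records: List[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                logger.warning("PAF line %d: fewer than 12 columns, skipped", lineno)
                continue
            try:
                rec = PafRecord(
                    qname=parts[0],
                    qlen=int(parts[1]),
                    qstart=int(parts[2]),
                    qend=int(parts[3]),
                    strand=parts[4],
                    tname=parts[5],
                    tlen=int(parts[6]),
                    tstart=int(parts[7]),
                    tend=int(parts[8]),
                    nmatch=int(parts[9]),
                    alnlen=int(parts[10]),
                    mapq=int(parts[11]),
                )
                for tag in parts[12:]:
                    if tag.startswith("de:f:"):
                        rec.de = float(tag[5:])
                    else:
                        key, _, rest = tag.partition(":")
                        rec.tags[key] = rest
                rec.validate()
            except ValueError as exc:
                logger.warning("PAF line %d rejected: %s", lineno, exc)
                continue
            records.append(rec)
    return records


def write_paf(records: Sequence[PafRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_paf_line() + "\n")


def estimate_divergence(rec: PafRecord) -> float:
    """Per-base divergence: the de:f tag when present, else 1 - matches/block."""
    if rec.de is not None:
        return rec.de
    if rec.alnlen <= 0:
        raise ValueError("alignment block length must be positive")
    return 1.0 - rec.nmatch / rec.alnlen


def filter_primary(records: Sequence[PafRecord]) -> List[PafRecord]:
    """Drop records flagged as secondary alignments (tp:A:S)."""
    return [r for r in records if r.tags.get("tp") != "A:S"]


def merge_collinear(
    records: Sequence[PafRecord],
    max_gap: int = 100_000,
    gap_diff_tol: int = 20_000,
    min_merged_span: Optional[int] = None,
    max_divergence_delta: Optional[float] = None,
) -> List[PafRecord]:
    """Chain artificially split collinear alignments back together.

    Records sharing a query/target chromosome pair and strand are sorted by
    target start and chained when both the target gap and the query gap are in
    [0, max_gap] and the two gaps agree within gap_diff_tol (consistent
    diagonal; on the minus strand the query runs backwards). Chained matches
    and block lengths are summed; divergence is the alignment-length-weighted
    mean, ignoring inter-block gap bases. With ``min_merged_span`` set, chains
    are only committed when their merged target span reaches it (otherwise the
    original records are returned unmerged). ``max_divergence_delta``
    optionally refuses to chain records whose divergence estimates differ by
    more than the given amount, so that healing artificial breaks cannot fuse
    a homozygous run with flanking diverged alignment.
    """
    groups: Dict[Tuple[str, str, str], List[PafRecord]] = {}
    for rec in records:
        groups.setdefault((rec.qname, rec.tname, rec.strand), []).append(rec)
    merged: List[PafRecord] = []
    for (_q, _t, strand), group in groups.items():
        group = sorted(group, key=lambda r: (r.tstart, r.tend))
        chains: List[List[PafRecord]] = []
        current = [group[0]]
        for rec in group[1:]:
            prev = current[-1]
            tgap = rec.tstart - prev.tend
            if strand == "+":
                qgap = rec.qstart - prev.qend
            else:
                qgap = prev.qstart - rec.qend
            compatible = True
            if max_divergence_delta is not None:
                compatible = abs(estimate_divergence(rec) - estimate_divergence(prev)) <= max_divergence_delta
            if compatible and 0 <= tgap <= max_gap and 0 <= qgap <= max_gap and abs(qgap - tgap) <= gap_diff_tol:
                current.append(rec)
            else:
                chains.append(current)
                current = [rec]
        chains.append(current)
        for chain in chains:
            if len(chain) == 1:
                merged.append(chain[0])
                continue
            span = chain[-1].tend - chain[0].tstart
            if min_merged_span is not None and span < min_merged_span:
                merged.extend(chain)
                continue
            total_aln = sum(r.alnlen for r in chain)
            div = sum(estimate_divergence(r) * r.alnlen for r in chain) / total_aln
            merged.append(
                replace(
                    chain[0],
                    qstart=min(r.qstart for r in chain),
                    qend=max(r.qend for r in chain),
                    tstart=chain[0].tstart,
                    tend=chain[-1].tend,
                    nmatch=sum(r.nmatch for r in chain),
                    alnlen=total_aln,
                    mapq=min(r.mapq for r in chain),
                    de=div,
                    n_sources=sum(r.n_sources for r in chain),
                )
            )
    return sorted(merged, key=lambda r: (r.tname, r.tstart, r.tend))


@dataclass
class ArohInterval:
    """A classified aligned run of homozygosity on the target haplotype."""

    chrom: str
    start: int
    end: int
    divergence: float
    n_sources: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_aroh(
    records: Sequence[PafRecord],
    min_length: int = 50_000,
    max_divergence: float = 0.01,
) -> List[ArohInterval]:
    """Keep merged alignments with target span > min_length and divergence
    < max_divergence (both strict). Overlapping survivors are resolved by
    keeping the longer interval and trimming the shorter (dropped if fully
    contained); trims are logged.
    """
    survivors = [
        ArohInterval(
            chrom=r.tname,
            start=r.tstart,
            end=r.tend,
            divergence=estimate_divergence(r),
            n_sources=r.n_sources,
        )
        for r in records
        if r.target_span > min_length and estimate_divergence(r) < max_divergence
    ]
    out: List[ArohInterval] = []
    by_chrom: Dict[str, List[ArohInterval]] = {}
    for iv in survivors:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        # longest first claims its span; shorter overlappers get trimmed
        claimed: List[ArohInterval] = []
        for iv in sorted(ivs, key=lambda v: (-v.length, v.start)):
            start, end = iv.start, iv.end
            for c in claimed:
                if start < c.end and c.start < end:
                    if start >= c.start and end <= c.end:
                        logger.info("AROH %s:%d-%d contained in longer interval, dropped", chrom, start, end)
                        start = end = 0
                        break
                    if start < c.start:
                        logger.info("AROH %s:%d-%d trimmed at %d", chrom, start, end, c.start)
                        end = min(end, c.start)
                    else:
                        logger.info("AROH %s:%d-%d trimmed at %d", chrom, start, end, c.end)
                        start = max(start, c.end)
            if end > start:
                claimed.append(ArohInterval(chrom, start, end, iv.divergence, iv.n_sources))
        out.extend(claimed)
    return sorted(out, key=lambda v: (v.chrom, v.start))


@dataclass
class ArohSummary:
    """Coverage proportions per minimum-length threshold."""

    table: pd.DataFrame  # columns: threshold, covered_bp, proportion
    total_bp_over_50kb: int


def coverage_by_min_length(
    intervals: Sequence[ArohInterval],
    assembly_length: int,
    thresholds: Sequence[int] = (50_000, 100_000, 1_000_000, 10_000_000, 30_000_000),
) -> ArohSummary:
    """Proportion of the assembly covered by AROH of length >= each threshold.

    Intervals are non-overlapping by construction so the covered proportion is
    a plain length sum; it is non-increasing in the threshold.
    """
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    for iv in intervals:
        if iv.length > assembly_length:
            raise ValueError("interval longer than assembly")
    lengths = sorted((iv.length for iv in intervals), reverse=True)
    rows = []
    for t in thresholds:
        covered = sum(ln for ln in lengths if ln >= t)
        rows.append({"threshold": t, "covered_bp": covered, "proportion": covered / assembly_length})
    total_50kb = sum(ln for ln in lengths if ln > 50_000)
    return ArohSummary(table=pd.DataFrame(rows), total_bp_over_50kb=total_50kb)


def intervals_to_bed(intervals: Sequence[ArohInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\taroh\t{iv.divergence:.6g}\n")
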