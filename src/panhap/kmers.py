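"""Canonical k-mer pangenome index and derived diagnostics.

A panel of genomes is summarized as a presence/absence table mapping each
canonical k-mer (the lexicographic minimum of a k-mer and its reverse
complement) to a bit-vector over genomes. From the index we derive:

* unique k-mers per genome (presence in exactly one genome),
* pairwise Jaccard similarity and an average-linkage dendrogram,
* collector's curves (cumulative distinct k-mers as genomes are added),
* per-genome unique-k-mer density tracks in fixed-width physical bins.

The index stores presence only (no multiplicities) and skips any window
containing a non-ACGT base. Default k is 31.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "KmerIndex",
    "canonicalize",
    "reverse_complement",
    "build_index",
    "unique_kmers",
    "jaccard_matrix",
    "cluster_tree",
    "collectors_curve",
    "unique_kmer_track",
]

_RC = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"[ACGT]+")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent; raises ValueError on any base outside ACGT (callers scanning
    genomes skip such windows instead).
    """
    if not _VALID.fullmatch(kmer):
        raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


GenomeSeqs = Union[str, Mapping[str, str], Sequence[str]]


def _iter_seqs(genome: GenomeSeqs) -> Iterable[Tuple[str, str]]:
    if isinstance(genome, str):
        yield "seq", genome
    elif isinstance(genome, Mapping):
        yield from genome.items()
    else:
        for i, s in enumerate(genome):
            yield f"seq{i}", s


def _scan_canonical(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of a sequence, skipping windows with non-ACGT bases."""
    for chunk in _VALID.findall(seq.upper()):
        rc_chunk = reverse_complement(chunk)
        n = len(chunk)
        for i in range(n - k + 1):
            fwd = chunk[i : i + k]
            rev = rc_chunk[n - k - i : n - i]
            yield fwd if fwd <= rev else rev


@dataclass
class KmerIndex:
    """Presence/absence pangenome index: canonical k-mer -> genome bit-vector."""

    k: int
    genome_names: List[str]
    table: Dict[str, int] = field(default_factory=dict)

    def genome_bit(self, genome: str) -> int:
        try:
            return 1 << self.genome_names.index(genome)
        except ValueError:
            raise KeyError(f"unknown genome {genome!r}") from None

    def kmer_set(self, genome: str) -> Set[str]:
        bit = self.genome_bit(genome)
        return {km for km, mask in self.table.items() if mask & bit}

    def mask_counts(self) -> Counter:
        """Count of k-mers per presence bit-pattern (basis for set algebra)."""
        return Counter(self.table.values())

    def __len__(self) -> int:
        return len(self.table)

    # -- persistence (TSV: kmer <tab> hex bit-vector, sorted by k-mer) -------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tgenomes={','.join(self.genome_names)}\n")
            for km in sorted(self.table):
                fh.write(f"{km}\t{self.table[km]:x}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerIndex":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError("missing index header")
            kpart, gpart = header[1:].split("\t")
            k = int(kpart.split("=")[1])
            names = gpart.split("=")[1].split(",")
            table = {}
            for line in fh:
                km, mask = line.split()
                table[km] = int(mask, 16)
        return cls(k=k, genome_names=names, table=table)


def build_index(
    genomes: Union[Mapping[str, GenomeSeqs], Sequence[Tuple[str, GenomeSeqs]]],
    k: int = 31,
    exclude_seqs: Optional[str] = None,
) -> KmerIndex:
    """Build the canonical k-mer presence index over a named genome panel.

    ``exclude_seqs`` is a regex matched against sequence names; matching
    sequences (e.g. sex chromosomes) are left out of the index, mirroring an
    autosome-only index configuration.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    items = list(genomes.items()) if isinstance(genomes, Mapping) else list(genomes)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate genome names")
    pat = re.compile(exclude_seqs) if exclude_seqs else None
    table: Dict[str, int] = {}
    for gi, (name, seqs) in enumerate(items):
        bit = 1 << gi
        any_seq = False
        for seq_name, seq in _iter_seqs(seqs):
            if pat is not None and pat.search(seq_name):
                continue
            any_seq = True
            for km in _scan_canonical(seq, k):
                table[km] = table.get(km, 0) | bit
        if not any_seq:
            raise ValueError(f"genome {name!r} has no sequences after filtering")
    return KmerIndex(k=k, genome_names=names, table=table)


def unique_kmers(index: KmerIndex, genome: str) -> Set[str]:
    """K-mers whose presence bit-vector has exactly the given genome's bit."""
    bit = index.genome_bit(genome)
    return {km for km, mask in index.table.items() if mask == bit}


@dataclass
class JaccardMatrix:
    genome_names: List[str]
    values: np.ndarray  # symmetric, diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_names, columns=self.genome_names)


def jaccard_matrix(index: KmerIndex, subset: Optional[Sequence[str]] = None) -> JaccardMatrix:
    """Pairwise Jaccard similarity of canonical k-mer sets.

    J(a, b) = |K_a ∩ K_b| / |K_a ∪ K_b|, computed from bit-pattern counts so
    the table is traversed once.
    """
    names = list(subset) if subset is not None else list(index.genome_names)
    bits = [index.genome_bit(n) for n in names]
    counts = index.mask_counts()
    n = len(names)
    sizes = np.zeros(n)
    inter = np.zeros((n, n))
    for mask, c in counts.items():
        present = [i for i, b in enumerate(bits) if mask & b]
        for i in present:
            sizes[i] += c
            for j in present:
                if j > i:
                    inter[i, j] += c
    values = np.eye(n)
    for i in range(n):
        if sizes[i] == 0:
            raise ValueError(f"genome {names[i]!r} has zero valid k-mers")
    for i in range(n):
        for j in range(i + 1, n):
            union = sizes[i] + sizes[j] - inter[i, j]
            values[i, j] = values[j, i] = inter[i, j] / union if union else 0.0
    return JaccardMatrix(genome_names=names, values=values)


def cluster_tree(matrix: JaccardMatrix, linkage: str = "average") -> str:
    """Average-linkage dendrogram on distance 1 - J, as a Newick string.

    Ultrametric node heights are half the linkage merge distance, so two
    genomes form a cherry at height (1 - J) / 2. Ties break deterministically
    by input order (scipy's linkage is deterministic on its input).
    """
    n = len(matrix.genome_names)
    if n < 2:
        raise ValueError("clustering needs at least 2 genomes")
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: matrix.genome_names[i] for i in range(n)}
    for step, (a, b, d, _cnt) in enumerate(z):
        a, b = int(a), int(b)
        h = d / 2.0
        node = n + step
        la = h - heights[a]
        lb = h - heights[b]
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
        heights[node] = h
    return newick[n + len(z) - 1] + ";"


@dataclass
class CollectorCurve:
    ordering: List[str]
    cumulative: List[int]


def collectors_curve(
    index: KmerIndex,
    orderings: Optional[Sequence[Sequence[str]]] = None,
    n_random: int = 0,
    seed: int = 0,
) -> List[CollectorCurve]:
    """Cumulative distinct canonical k-mers as genomes are added in order.

    With no explicit orderings, the index's own genome order is used;
    ``n_random`` adds random permutations. The terminal value equals the total
    number of distinct k-mers regardless of order.
    """
    if len(index.genome_names) < 1:
        raise ValueError("empty index")
    all_orderings: List[List[str]] = [list(o) for o in (orderings or [])]
    if not all_orderings and n_random == 0:
        all_orderings = [list(index.genome_names)]
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        perm = rng.permutation(len(index.genome_names))
        all_orderings.append([index.genome_names[i] for i in perm])
    counts = index.mask_counts()
    curves = []
    for ordering in all_orderings:
        bits = [index.genome_bit(g) for g in ordering]
        cum = np.zeros(len(ordering), dtype=np.int64)
        for mask, c in counts.items():
            for i, b in enumerate(bits):
                if mask & b:
                    cum[i] += c
                    break
        curves.append(CollectorCurve(ordering=ordering, cumulative=list(np.cumsum(cum))))
    return curves


def unique_kmer_track(
    index: KmerIndex,
    genome: str,
    seqs: GenomeSeqs,
    bin_width: int = 1_000_000,
) -> pd.DataFrame:
    """Count occurrences of a genome's unique k-mers in physical bins.

    Rescans the source sequences: every window whose canonical k-mer is unique
    to the genome increments the bin containing its leftmost base (multiple
    occurrences all count). Returns a BedGraph-style frame with columns chrom,
    bin_start, bin_end, count tiling each sequence.
    """
    uniq = unique_kmers(index, genome)
    k = index.k
    rows = []
    for chrom, seq in _iter_seqs(seqs):
        length = len(seq)
        n_bins = max(1, -(-length // bin_width))
        counts = np.zeros(n_bins, dtype=np.int64)
        seq_u = seq.upper()
        for m in _VALID.finditer(seq_u):
            chunk = m.group(0)
            start = m.start()
            rc_chunk = reverse_complement(chunk)
            n = len(chunk)
            for i in range(n - k + 1):
                fwd = chunk[i : i + k]
                rev = rc_chunk[n - k - i : n - i]
                km = fwd if fwd <= rev else rev
                if km in uniq:
                    counts[(start + i) // bin_width] += 1
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_width,
                    "bin_end": min((b + 1) * bin_width, length),
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)
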