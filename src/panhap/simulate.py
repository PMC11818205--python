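"""Synthetic-data generators with planted ground truth.

Every generator in this module emits both its data product (FASTA haplotypes,
marker tables, SNP allele-count tables) and a :class:`TruthSet` recording the
parameters that were planted, so downstream stages (k-mer indexing, AROH
calling, recombination-landscape estimation, bulk segregant analysis) can be
validated against known answers without any external data.

Models
------
* Diploid haplotype pairs: haplotype 2 is haplotype 1 with i.i.d. substitutions
  at a fixed background rate, except inside planted runs of homozygosity where
  the two haplotypes are identical.
* Genome panels: each genome is a concatenation of fixed-length blocks drawn
  with replacement from a shared pool, plus genome-private blocks.
* F2 populations: per-gamete crossover counts are Poisson(map length / 100)
  with positions i.i.d. from a crossover-density function over relative
  physical position (no interference). Segregation distortion is applied as
  post-hoc viability selection against one homozygote class.
* Bulk segregant pools: informative gametes carry crossovers at a uniform
  cM/Mb rate; the selected bulk is conditioned to carry the selected allele at
  the causal position; read depths are Poisson and allele counts binomial at
  the gamete-pool frequency.

All generators are bit-reproducible given their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DiploidSim",
    "PanelSim",
    "F2Sim",
    "BulkSim",
    "TruthSet",
    "CrossoverDensity",
    "mutate",
    "random_sequence",
    "simulate_diploid",
    "simulate_panel",
    "simulate_f2",
    "simulate_bulks",
    "diploid_truth_alignment",
    "write_fasta",
]

# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


def _encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes 0-3 (ACGT) and 4 (N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGTN base {bad!r} in sequence")
    return codes.copy()


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence of the given length."""
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(seq: str, rate: float, seed_or_rng: Union[int, np.random.Generator] = 0) -> str:
    """Substitute each position with probability ``rate`` to a different base.

    ``N`` positions are left untouched; the output has the same length as the
    input. Bases outside ACGTN are rejected.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    codes = _encode(seq)
    mask = (rng.random(codes.size) < rate) & (codes < 4)
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return _decode(codes)


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences as 60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TruthSet
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Planted parameters emitted by every simulator for recovery testing."""

    roh_bed: Optional[List[Tuple[str, int, int]]] = None
    crossover_density_table: Optional[pd.DataFrame] = None
    causal_pos: Optional[int] = None
    distortion_params: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    def write(self, outdir, prefix: str = "truth") -> None:
        """Serialize to a BED (ROH segments, 0-based half-open) + YAML sidecar."""
        import os

        os.makedirs(outdir, exist_ok=True)
        if self.roh_bed is not None:
            with open(os.path.join(outdir, f"{prefix}.roh.bed"), "w") as fh:
                for chrom, start, end in self.roh_bed:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
        if self.crossover_density_table is not None:
            self.crossover_density_table.to_csv(
                os.path.join(outdir, f"{prefix}.crossover_density.tsv"), sep="\t", index=False
            )
        meta = {
            "causal_pos": self.causal_pos,
            "distortion_params": self.distortion_params,
            "extras": {
                k: v for k, v in self.extras.items() if isinstance(v, (int, float, str, list, dict, type(None)))
            },
        }
        with open(os.path.join(outdir, f"{prefix}.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)


# ---------------------------------------------------------------------------
# diploid haplotype pairs
# ---------------------------------------------------------------------------


@dataclass
class DiploidSim:
    """Configuration for a diploid genome with planted identical segments.

    background_divergence is the per-bp substitution probability between the
    haplotypes outside planted segments; roh_segments are (chrom, start, end)
    in 0-based half-open coordinates and must not overlap. indel_rate inserts
    or deletes single bases in haplotype 2 (default 0 so that coordinate truth
    is exact).
    """

    chrom_lengths: Dict[str, int]
    background_divergence: float = 0.02
    roh_segments: List[Tuple[str, int, int]] = field(default_factory=list)
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.background_divergence <= 0.2:
            raise ValueError("background_divergence must be in [0, 0.2]")
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in self.roh_segments:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"ROH segment on unknown chromosome {chrom}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(f"ROH segment ({chrom},{start},{end}) outside [0, length)")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping ROH segments on {chrom}")


def simulate_diploid(cfg: DiploidSim) -> Tuple[Dict[str, str], Dict[str, str], TruthSet]:
    """Generate two haplotype FASTA dicts and the planted-segment truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hap1: Dict[str, str] = {}
    hap2: Dict[str, str] = {}
    for chrom, length in cfg.chrom_lengths.items():
        codes1 = rng.integers(0, 4, size=length, dtype=np.uint8)
        mask = rng.random(length) < cfg.background_divergence
        for c, s, e in cfg.roh_segments:
            if c == chrom:
                mask[s:e] = False
        codes2 = codes1.copy()
        n = int(mask.sum())
        if n:
            codes2[mask] = (codes2[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
        if cfg.indel_rate > 0:
            codes2 = _apply_indels(codes2, cfg.indel_rate, rng)
        hap1[chrom] = _decode(codes1)
        hap2[chrom] = _decode(codes2)
    truth = TruthSet(
        roh_bed=sorted(cfg.roh_segments),
        extras={"background_divergence": cfg.background_divergence, "seed": cfg.seed},
    )
    return hap1, hap2, truth


def _apply_indels(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Single-base insertions/deletions, half of events each."""
    n_events = rng.poisson(rate * codes.size)
    if n_events == 0:
        return codes
    pos = np.sort(rng.integers(0, codes.size, size=n_events))
    is_del = rng.random(n_events) < 0.5
    out = codes
    # apply right-to-left so earlier positions stay valid
    for p, d in zip(pos[::-1], is_del[::-1]):
        if d:
            out = np.delete(out, p)
        else:
            out = np.insert(out, p, rng.integers(0, 4, dtype=np.uint8))
    return out


def diploid_truth_alignment(
    hap1: Mapping[str, str],
    hap2: Mapping[str, str],
    truth: TruthSet,
    split_length: Optional[int] = None,
    split_gap: int = 1000,
):
    """Exact truth alignment between two simulated haplotypes as PAF records.

    Emits one + strand record per maximal segment (planted identical segments
    and the background stretches between them), with ``n_match`` counted from
    the actual sequences. ``split_length`` optionally chops each segment into
    sub-records separated by ``split_gap`` unaligned bases, to exercise
    downstream alignment-break merging. Requires indel-free haplotypes
    (identical per-chromosome lengths).
    """
    from .aroh import PafRecord

    roh = truth.roh_bed or []
    records = []
    for chrom in hap1:
        a = _encode(hap1[chrom])
        b = _encode(hap2[chrom])
        if a.size != b.size:
            raise ValueError("truth alignment requires indel-free haplotypes")
        length = a.size
        segs = sorted([(s, e) for c, s, e in roh if c == chrom])
        bounds = [0]
        for s, e in segs:
            bounds.extend([s, e])
        bounds.append(length)
        pieces = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if bounds[i] < bounds[i + 1]]
        for s, e in pieces:
            subs = [(s, e)]
            if split_length is not None and e - s > split_length:
                subs = []
                p = s
                while p < e:
                    q = min(p + split_length, e)
                    subs.append((p, q))
                    p = q + split_gap
            for ss, ee in subs:
                if ee <= ss:
                    continue
                nmatch = int((a[ss:ee] == b[ss:ee]).sum())
                records.append(
                    PafRecord(
                        qname=chrom,
                        qlen=length,
                        qstart=ss,
                        qend=ee,
                        strand="+",
                        tname=chrom,
                        tlen=length,
                        tstart=ss,
                        tend=ee,
                        nmatch=nmatch,
                        alnlen=ee - ss,
                        mapq=60,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# genome panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSim:
    """Panel of genomes built from a shared block pool plus private blocks."""

    n_genomes: int = 5
    n_blocks: int = 10
    block_length: int = 5000
    pool_size: int = 8
    private_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.private_rate <= 1:
            raise ValueError("private_rate must be in [0, 1]")
        if self.pool_size == 0 and self.private_rate < 1:
            raise ValueError("pool_size=0 requires private_rate=1")
        if self.n_genomes < 1 or self.n_blocks < 1 or self.block_length < 1:
            raise ValueError("n_genomes, n_blocks, block_length must be positive")


def simulate_panel(cfg: PanelSim) -> Tuple[Dict[str, str], TruthSet]:
    """Generate named genomes as block concatenations and the block truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pool = [random_sequence(cfg.block_length, rng) for _ in range(cfg.pool_size)]
    genomes: Dict[str, str] = {}
    rows = []
    for g in range(cfg.n_genomes):
        name = f"genome_{g + 1}"
        blocks = []
        for b in range(cfg.n_blocks):
            private = rng.random() < cfg.private_rate
            if private:
                blocks.append(random_sequence(cfg.block_length, rng))
                source = "private"
            else:
                idx = int(rng.integers(0, cfg.pool_size))
                blocks.append(pool[idx])
                source = f"pool:{idx}"
            rows.append(
                {
                    "genome": name,
                    "block_index": b,
                    "start": b * cfg.block_length,
                    "end": (b + 1) * cfg.block_length,
                    "source": source,
                }
            )
        genomes[name] = "".join(blocks)
    blocks_df = pd.DataFrame(rows)
    n_private = blocks_df[blocks_df.source == "private"].groupby("genome").size()
    truth = TruthSet(
        extras={
            "blocks": blocks_df,
            "n_private_blocks": {name: int(n_private.get(name, 0)) for name in genomes},
            "seed": cfg.seed,
        }
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# crossover density
# ---------------------------------------------------------------------------


class CrossoverDensity:
    """Probability density of crossover position over relative position [0, 1].

    Presets: ``"uniform"`` and ``"periphery"`` (density proportional to
    (2x-1)^2, i.e. crossovers concentrated at chromosome ends with a
    suppressed centre). Arbitrary tabulated densities are accepted as
    (positions, values) and normalized; negative values or zero total mass are
    rejected.
    """

    GRID = 4096

    def __init__(self, spec: Union[str, Tuple[Sequence[float], Sequence[float]]] = "uniform"):
        x = np.linspace(0.0, 1.0, self.GRID + 1)
        if spec == "uniform":
            pdf = np.ones_like(x)
        elif spec == "periphery":
            pdf = 3.0 * (2.0 * x - 1.0) ** 2
        elif isinstance(spec, str):
            raise ValueError(f"unknown density preset {spec!r}")
        else:
            xs, vs = np.asarray(spec[0], dtype=float), np.asarray(spec[1], dtype=float)
            if (vs < 0).any():
                raise ValueError("density table has negative values")
            pdf = np.interp(x, xs, vs)
        mass = np.trapezoid(pdf, x)
        if not np.isfinite(mass) or mass <= 0:
            raise ValueError("density not normalizable")
        self.x = x
        self.pdf_grid = pdf / mass
        cdf = np.concatenate([[0.0], np.cumsum((self.pdf_grid[1:] + self.pdf_grid[:-1]) / 2 * np.diff(x))])
        self.cdf_grid = cdf / cdf[-1]
        self.spec = spec

    def pdf(self, x):
        return np.interp(x, self.x, self.pdf_grid)

    def cdf(self, x):
        return np.interp(x, self.x, self.cdf_grid)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of crossover positions."""
        u = rng.random(n)
        # cdf_grid is non-decreasing; flat stretches (zero density) are fine
        return np.interp(u, self.cdf_grid, self.x)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"rel_pos": self.x, "density": self.pdf_grid})


# ---------------------------------------------------------------------------
# F2 populations
# ---------------------------------------------------------------------------


@dataclass
class F2Sim:
    """Bi-parental F2 genotype matrix under a crossover-density landscape.

    Genotypes are coded AA/AB/BB with the A allele from parent 1. The optional
    distortion locus (chrom, relative position, selection coefficient s) is
    applied as viability selection: individuals homozygous for the
    selected-against class (BB by default) survive with probability 1 - s.
    """

    map_length_cM: Dict[str, float]
    n_markers: Union[int, Dict[str, int]] = 200
    n_individuals: int = 100
    chrom_lengths_bp: Optional[Dict[str, int]] = None
    crossover_density: Union[str, Tuple[Sequence[float], Sequence[float]]] = "uniform"
    distortion_locus: Optional[Tuple[str, float, float]] = None
    distortion_against: str = "BB"
    monomorphic_region: Optional[Tuple[str, float, float]] = None
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.distortion_against not in ("AA", "BB"):
            raise ValueError("distortion_against must be AA or BB")
        if self.distortion_locus is not None:
            chrom, pos, s = self.distortion_locus
            if chrom not in self.map_length_cM:
                raise ValueError("distortion locus on unknown chromosome")
            if not (0 <= pos <= 1 and 0 <= s <= 1):
                raise ValueError("distortion locus needs rel pos and s in [0, 1]")

    def markers_per_chrom(self, chrom: str) -> int:
        if isinstance(self.n_markers, dict):
            return self.n_markers[chrom]
        return self.n_markers

    def length_bp(self, chrom: str) -> int:
        if self.chrom_lengths_bp is not None:
            return self.chrom_lengths_bp[chrom]
        return 100_000_000


_GENO = np.array(["AA", "AB", "BB"])


def _sample_gametes(
    density: CrossoverDensity,
    map_length_cM: float,
    rel_positions: np.ndarray,
    n_gametes: int,
    rng: np.random.Generator,
    collect_xo: Optional[list] = None,
) -> np.ndarray:
    """Gamete allele matrix (n_gametes x markers), 0 = parent-1 allele.

    Crossover counts are Poisson(map length / 100); positions i.i.d. from the
    density (no interference). Allele at a marker flips with each crossover to
    its left.
    """
    out = np.empty((n_gametes, rel_positions.size), dtype=np.uint8)
    lam = map_length_cM / 100.0
    ks = rng.poisson(lam, size=n_gametes)
    for i, k in enumerate(ks):
        phase = int(rng.integers(0, 2))
        if k == 0:
            out[i, :] = phase
            continue
        xo = np.sort(density.sample(int(k), rng))
        if collect_xo is not None:
            collect_xo.append(xo)
        out[i, :] = (phase + np.searchsorted(xo, rel_positions, side="right")) % 2
    return out


def simulate_f2(cfg: F2Sim) -> Tuple[pd.DataFrame, TruthSet]:
    """Generate an F2 marker genotype table and its truth.

    Returns a DataFrame with columns marker, chrom, pos_bp, cM (true genetic
    position from the cumulative crossover density) followed by one column per
    individual holding AA/AB/BB/NA strings.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    density = CrossoverDensity(cfg.crossover_density)
    chroms = list(cfg.map_length_cM)
    dist_chrom = cfg.distortion_locus[0] if cfg.distortion_locus else None

    geno: Dict[str, np.ndarray] = {}
    meta_rows = []
    xo_positions: Dict[str, list] = {c: [] for c in chroms}

    # the distortion chromosome is generated first under rejection sampling;
    # all other chromosomes are independent of viability and generated plainly
    for chrom in chroms:
        m = cfg.markers_per_chrom(chrom)
        rel = (np.arange(m) + 0.5) / m
        length = cfg.length_bp(chrom)
        pos_bp = np.round(rel * length).astype(np.int64)
        cm = cfg.map_length_cM[chrom] * density.cdf(rel)
        for mk in range(m):
            meta_rows.append(
                {
                    "marker": f"{chrom}_m{mk + 1:04d}",
                    "chrom": chrom,
                    "pos_bp": int(pos_bp[mk]),
                    "cM": float(cm[mk]),
                }
            )
        if chrom == dist_chrom:
            _, rel_pos, s = cfg.distortion_locus
            eval_pos = np.append(rel, rel_pos)
            accepted = []
            n_have = 0
            while n_have < cfg.n_individuals:
                batch = max(32, cfg.n_individuals - n_have)
                g1 = _sample_gametes(density, cfg.map_length_cM[chrom], eval_pos, batch, rng, xo_positions[chrom])
                g2 = _sample_gametes(density, cfg.map_length_cM[chrom], eval_pos, batch, rng, xo_positions[chrom])
                gt = g1 + g2  # 0/1/2 copies of the B allele
                at_locus = gt[:, -1]
                target = 2 if cfg.distortion_against == "BB" else 0
                survive = (at_locus != target) | (rng.random(batch) >= s)
                kept = gt[survive, :-1]
                accepted.append(kept)
                n_have += kept.shape[0]
            geno[chrom] = np.concatenate(accepted, axis=0)[: cfg.n_individuals]
        else:
            g1 = _sample_gametes(density, cfg.map_length_cM[chrom], rel, cfg.n_individuals, rng, xo_positions[chrom])
            g2 = _sample_gametes(density, cfg.map_length_cM[chrom], rel, cfg.n_individuals, rng, xo_positions[chrom])
            geno[chrom] = g1 + g2

    # assemble table
    table = pd.DataFrame(meta_rows)
    ind_names = [f"ind_{i + 1:04d}" for i in range(cfg.n_individuals)]
    cols = {}
    for chrom in chroms:
        gt = geno[chrom]  # individuals x markers
        if cfg.monomorphic_region and cfg.monomorphic_region[0] == chrom:
            _, rs, re_ = cfg.monomorphic_region
            m = cfg.markers_per_chrom(chrom)
            rel = (np.arange(m) + 0.5) / m
            gt = gt.copy()
            gt[:, (rel >= rs) & (rel <= re_)] = 0
        labels = _GENO[gt]  # individuals x markers
        if cfg.missing_rate > 0:
            miss = rng.random(labels.shape) < cfg.missing_rate
            labels = labels.copy()
            labels[miss] = "NA"
        cols[chrom] = labels
    all_labels = np.concatenate([cols[c].T for c in chroms], axis=0)  # markers x individuals
    table = pd.concat([table, pd.DataFrame(all_labels, columns=ind_names)], axis=1)

    truth = TruthSet(
        crossover_density_table=density.table(),
        distortion_params=(
            {
                "chrom": cfg.distortion_locus[0],
                "rel_pos": cfg.distortion_locus[1],
                "s": cfg.distortion_locus[2],
                "against": cfg.distortion_against,
            }
            if cfg.distortion_locus
            else None
        ),
        extras={
            "genetic_positions": {c: cfg.map_length_cM[c] for c in chroms},
            "crossover_positions": {
                c: (np.concatenate(xo_positions[c]) if xo_positions[c] else np.array([])) for c in chroms
            },
            "seed": cfg.seed,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# bulk segregant pools
# ---------------------------------------------------------------------------


@dataclass
class BulkSim:
    """Bulk segregant allele-count table around an optional causal locus.

    Allele frequencies are expressed in the segregating-gamete coding: the
    frequency of the selected allele among the informative (F1-derived)
    gametes of a bulk. A backcross bulk has one informative gamete per plant,
    an F2 bulk two; the selected bulk is conditioned to carry the selected
    allele at causal_pos in every informative gamete (full penetrance), the
    unselected bulk sits at the Mendelian expectation of 0.5. With
    causal_pos=None both bulks are null. Crossovers follow a homogeneous
    Poisson process at recomb_rate cM/Mb, i.e. the Haldane map function.
    """

    chrom_length: int = 30_000_000
    n_snps: int = 1500
    causal_pos: Optional[int] = 15_000_000
    design: str = "backcross"
    n_plants: int = 50
    mean_depth: float = 40.0
    recomb_rate: float = 1.0
    selected_bulk_allele: str = "alt"
    chrom: str = "chr1"
    positions: Optional[np.ndarray] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("n_plants must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.design not in ("backcross", "f2"):
            raise ValueError("design must be 'backcross' or 'f2'")
        if self.causal_pos is not None and not 0 <= self.causal_pos < self.chrom_length:
            raise ValueError("causal_pos outside chromosome")
        if self.selected_bulk_allele not in ("ref", "alt"):
            raise ValueError("selected_bulk_allele must be 'ref' or 'alt'")

    @property
    def gametes_per_bulk(self) -> int:
        return self.n_plants if self.design == "backcross" else 2 * self.n_plants


def gamete_pool_frequency(
    snp_pos: np.ndarray,
    chrom_length: int,
    recomb_rate: float,
    n_gametes: int,
    rng: np.random.Generator,
    causal_pos: Optional[int] = None,
) -> np.ndarray:
    """Selected-allele frequency at each SNP over a finite gamete pool.

    Each gamete carries Poisson crossovers at recomb_rate cM/Mb (uniform
    positions). With causal_pos given, every gamete is conditioned to carry
    the selected allele there; otherwise phases are random (null).
    """
    lam = recomb_rate * chrom_length / 1e6 / 100.0  # expected crossovers per gamete
    ks = rng.poisson(lam, size=n_gametes)
    freq = np.zeros(snp_pos.size)
    n0 = int((ks == 0).sum())
    if causal_pos is None:
        freq += int(rng.binomial(n0, 0.5))
    else:
        freq += n0  # no crossovers: selected allele everywhere
    for k in ks[ks > 0]:
        xo = np.sort(rng.uniform(0, chrom_length, size=int(k)))
        cnt = np.searchsorted(xo, snp_pos, side="right")
        if causal_pos is None:
            phase = int(rng.integers(0, 2))
        else:
            phase = (1 - int(np.searchsorted(xo, causal_pos, side="right"))) % 2
        freq += (phase + cnt) % 2
    return freq / n_gametes


def simulate_bulks(cfg: BulkSim) -> Tuple[pd.DataFrame, TruthSet]:
    """Generate a per-SNP allele-count table for a selected + unselected bulk.

    Returns a DataFrame with columns CHROM, POS (1-based), REF, ALT,
    AD_bulk1_ref, AD_bulk1_alt, AD_bulk2_ref, AD_bulk2_alt; bulk 1 is the
    selected bulk and the ALT column counts the selected allele by default.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.positions is not None:
        pos = np.sort(np.asarray(cfg.positions, dtype=np.int64))
    else:
        pos = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_snps, replace=False)).astype(np.int64)
    n_gam = cfg.gametes_per_bulk
    f_sel = gamete_pool_frequency(pos, cfg.chrom_length, cfg.recomb_rate, n_gam, rng, cfg.causal_pos)
    f_uns = gamete_pool_frequency(pos, cfg.chrom_length, cfg.recomb_rate, n_gam, rng, None)
    d1 = rng.poisson(cfg.mean_depth, size=pos.size)
    d2 = rng.poisson(cfg.mean_depth, size=pos.size)
    sel1 = rng.binomial(d1, f_sel)
    sel2 = rng.binomial(d2, f_uns)
    if cfg.selected_bulk_allele == "alt":
        a1, r1 = sel1, d1 - sel1
        a2, r2 = sel2, d2 - sel2
    else:
        r1, a1 = sel1, d1 - sel1
        r2, a2 = sel2, d2 - sel2
    table = pd.DataFrame(
        {
            "CHROM": cfg.chrom,
            "POS": pos + 1,
            "REF": "A",
            "ALT": "T",
            "AD_bulk1_ref": r1,
            "AD_bulk1_alt": a1,
            "AD_bulk2_ref": r2,
            "AD_bulk2_alt": a2,
        }
    )
    truth = TruthSet(
        causal_pos=cfg.causal_pos,
        extras={
            "design": cfg.design,
            "n_plants": cfg.n_plants,
            "recomb_rate": cfg.recomb_rate,
            "selected_bulk_allele": cfg.selected_bulk_allele,
            "selected_freq": f_sel,
            "unselected_freq": f_uns,
            "seed": cfg.seed,
        },
    )
    return table, truth
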