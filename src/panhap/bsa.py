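"""G-statistic bulk segregant analysis with multi-reference consensus peaks.

At each SNP the 2x2 table of (bulk x allele) read counts is scored with the
log-likelihood-ratio G statistic; G is averaged in sliding windows (2 Mb wide
by default, stepped every 10 kb) and compared against per-window significance
thresholds obtained by simulating the null design. Significant windows are
merged into peak intervals, peaks from analyses against different reference
assemblies are projected through pairwise alignment chains (PAF) onto a
common anchor, and the consensus interval plus a depth/frequency-filtered
diagnostic SNP panel are reported.

Null thresholds support two recipes: a per-SNP binomial redraw at fixed null
allele frequencies, and a design-matched parametric bootstrap that simulates
whole bulks of informative gametes (finite-pool allele-frequency drift is
correlated along the chromosome, which the per-SNP redraw cannot capture; the
bootstrap is the calibrated default whenever the bulk size is known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aroh import PafRecord
from .simulate import gamete_pool_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "g_statistic",
    "filter_snps",
    "smooth_g",
    "null_threshold",
    "significant_intervals",
    "project_interval",
    "consensus_interval",
    "select_diagnostic_snps",
    "GProfile",
    "PeakInterval",
    "ProjectionResult",
]


def g_statistic(n1_ref, n1_alt, n2_ref, n2_alt):
    """Log-likelihood-ratio statistic of the 2x2 bulk-by-allele count table.

    G = 2 * sum o_ij * ln(o_ij / e_ij) with expectations from the row and
    column totals under independence; zero cells contribute nothing, and a
    zero row or column total yields G = 0 (no information). Accepts scalars
    or aligned arrays.
    """
    o = np.array(np.broadcast_arrays(n1_ref, n1_alt, n2_ref, n2_alt), dtype=float)
    scalar = o.ndim == 1
    o = o.reshape(4, -1)
    n = o.sum(axis=0)
    r1 = o[0] + o[1]
    r2 = o[2] + o[3]
    c1 = o[0] + o[2]
    c2 = o[1] + o[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / n
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = 2.0 * terms.sum(axis=0)
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0) | (n == 0)
    if degenerate.any():
        logger.debug("%d tables with a zero margin scored as G=0", int(degenerate.sum()))
    g = np.where(degenerate, 0.0, g)
    return float(g[0]) if scalar else g


def filter_snps(table: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Retain SNPs with read depth >= min_depth in each bulk (inclusive)."""
    if len(table) == 0:
        return table
    d1 = table["AD_bulk1_ref"] + table["AD_bulk1_alt"]
    d2 = table["AD_bulk2_ref"] + table["AD_bulk2_alt"]
    return table[(d1 >= min_depth) & (d2 >= min_depth)].reset_index(drop=True)


def snp_g(table: pd.DataFrame) -> np.ndarray:
    return g_statistic(
        table["AD_bulk1_ref"].to_numpy(),
        table["AD_bulk1_alt"].to_numpy(),
        table["AD_bulk2_ref"].to_numpy(),
        table["AD_bulk2_alt"].to_numpy(),
    )


@dataclass
class GProfile:
    """Smoothed G track on a regular grid of window centers."""

    chrom: str
    centers: np.ndarray
    g: np.ndarray  # NaN where a window holds no SNP
    n_snps: np.ndarray
    window: float
    step: float
    threshold: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"chrom": self.chrom, "center": self.centers, "smoothed_G": self.g, "n_snps": self.n_snps})
        if self.threshold is not None:
            out["threshold"] = self.threshold
        return out


def _window_bounds(positions: np.ndarray, centers: np.ndarray, window: float) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(positions, centers - window / 2.0, side="left")
    hi = np.searchsorted(positions, centers + window / 2.0, side="right")
    return lo, hi


def _window_means(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values, axis=-1)], axis=-1)
    cnt = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (cs[..., hi] - cs[..., lo]) / cnt
    return np.where(cnt > 0, means, np.nan)


def smooth_g(
    positions: Sequence[float],
    g: Sequence[float],
    window: float = 2_000_000,
    step: float = 10_000,
    chrom: str = "chr",
    chrom_length: Optional[float] = None,
) -> GProfile:
    """Mean G over SNPs within window/2 of each grid center (step apart).

    Windows containing no SNP are emitted with NaN. SNP positions must be
    sorted ascending.
    """
    pos = np.asarray(positions, dtype=float)
    gv = np.asarray(g, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("SNP positions must be sorted")
    end = chrom_length if chrom_length is not None else (pos[-1] if pos.size else 0.0)
    centers = np.arange(0.0, end + step / 2.0, step)
    lo, hi = _window_bounds(pos, centers, window)
    means = _window_means(gv, lo, hi)
    return GProfile(chrom=chrom, centers=centers, g=means, n_snps=hi - lo, window=window, step=step)


def null_threshold(
    table: pd.DataFrame,
    window: float = 2_000_000,
    step: float = 10_000,
    n_sim: int = 1000,
    percentile: float = 99.5,
    design: str = "backcross",
    null_freqs: Tuple[float, float] = (0.5, 0.5),
    n_plants: Optional[int] = None,
    recomb_rate: float = 1.0,
    chrom_length: Optional[float] = None,
    redraw_depths: bool = False,
    mean_depth: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-window significance threshold from null simulations.

    Each replicate redraws every SNP's allele counts under the null of equal
    bulk composition, preserving the observed depths (or Poisson-redrawing
    them with ``redraw_depths``), recomputes the smoothed G profile, and the
    threshold is the requested percentile of the simulated distribution per
    window. With ``n_plants`` given, the null allele frequency of each bulk is
    drawn from a simulated pool of informative gametes (backcross: n_plants
    gametes; f2: 2*n_plants), reproducing the finite-bulk drift and its
    along-chromosome correlation; with ``n_plants=None`` counts are redrawn
    independently per SNP at ``null_freqs``.
    """
    if n_sim < 100:
        logger.warning("n_sim=%d is small; thresholds will be noisy", n_sim)
    rng = np.random.default_rng(seed)
    pos = table["POS"].to_numpy(dtype=float)
    d1_obs = (table["AD_bulk1_ref"] + table["AD_bulk1_alt"]).to_numpy()
    d2_obs = (table["AD_bulk2_ref"] + table["AD_bulk2_alt"]).to_numpy()
    end = chrom_length if chrom_length is not None else pos[-1]
    centers = np.arange(0.0, end + step / 2.0, step)
    lo, hi = _window_bounds(pos, centers, window)
    n_gam = None
    if n_plants is not None:
        if design not in ("backcross", "f2"):
            raise ValueError("design must be 'backcross' or 'f2'")
        n_gam = n_plants if design == "backcross" else 2 * n_plants
    sims = np.empty((n_sim, centers.size))
    md = mean_depth if mean_depth is not None else float(np.mean(np.concatenate([d1_obs, d2_obs])))
    for s in range(n_sim):
        if redraw_depths:
            d1 = rng.poisson(md, size=pos.size)
            d2 = rng.poisson(md, size=pos.size)
        else:
            d1, d2 = d1_obs, d2_obs
        if n_gam is not None:
            f1 = gamete_pool_frequency(pos, int(end), recomb_rate, n_gam, rng, None)
            f2 = gamete_pool_frequency(pos, int(end), recomb_rate, n_gam, rng, None)
        else:
            f1 = np.full(pos.size, null_freqs[0])
            f2 = np.full(pos.size, null_freqs[1])
        a1 = rng.binomial(d1, f1)
        a2 = rng.binomial(d2, f2)
        g = g_statistic(d1 - a1, a1, d2 - a2, a2)
        sims[s] = _window_means(g, lo, hi)
    with np.errstate(invalid="ignore"):
        thr = np.nanpercentile(sims, percentile, axis=0)
    return thr


@dataclass
class PeakInterval:
    """A run of significant windows on one reference."""

    reference: str
    chrom: str
    start: float
    end: float
    max_g: float


def significant_intervals(profile: GProfile, reference: str = "ref") -> List[PeakInterval]:
    """Maximal runs of windows with smoothed G above the per-window threshold,
    merged across gaps of at most one step."""
    if profile.threshold is None:
        raise ValueError("profile carries no threshold")
    sig = np.where(np.isnan(profile.g), False, profile.g > profile.threshold)
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    out = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev <= 2:  # allow one non-significant window between runs
            prev = i
            continue
        out.append((run_start, prev))
        run_start = prev = i
    out.append((run_start, prev))
    intervals = []
    for a, b in out:
        gmax = float(np.nanmax(profile.g[a : b + 1]))
        intervals.append(
            PeakInterval(
                reference=reference,
                chrom=profile.chrom,
                start=float(profile.centers[a]),
                end=float(profile.centers[b] + profile.step),
                max_g=gmax,
            )
        )
    return sorted(intervals, key=lambda p: -p.max_g)


# ---------------------------------------------------------------------------
# cross-reference projection
# ---------------------------------------------------------------------------


@dataclass
class ProjectionResult:
    start: float
    end: float
    unmapped_bp: float  # interval bases not covered by any alignment block


def project_interval(
    interval: Tuple[float, float],
    chain: Sequence[PafRecord],
    source: str = "query",
) -> Optional[ProjectionResult]:
    """Map an interval through pairwise alignment blocks onto the other genome.

    ``source`` names the side the interval lives on ("query" maps onto the
    target, "target" onto the query). Endpoints are carried by linear
    interpolation within each overlapping block; minus-strand blocks reverse
    orientation. The result is the minimal interval covering all projected
    pieces; returns None when no block overlaps (unmappable).
    """
    a, b = float(interval[0]), float(interval[1])
    if b <= a:
        raise ValueError("interval must have positive length")
    pieces = []
    covered = 0.0
    for rec in chain:
        if source == "query":
            s_lo, s_hi = rec.qstart, rec.qend
        else:
            s_lo, s_hi = rec.tstart, rec.tend
        lo = max(a, s_lo)
        hi = min(b, s_hi)
        if hi <= lo:
            continue
        covered += hi - lo
        if source == "query":
            if rec.strand == "+":
                p_lo = rec.tstart + (lo - rec.qstart)
                p_hi = rec.tstart + (hi - rec.qstart)
            else:
                p_lo = rec.tstart + (rec.qend - hi)
                p_hi = rec.tstart + (rec.qend - lo)
        else:
            if rec.strand == "+":
                p_lo = rec.qstart + (lo - rec.tstart)
                p_hi = rec.qstart + (hi - rec.tstart)
            else:
                p_lo = rec.qstart + (rec.tend - hi)
                p_hi = rec.qstart + (rec.tend - lo)
        pieces.append((p_lo, p_hi))
    if not pieces:
        return None
    start = min(p for p, _ in pieces)
    end = max(q for _, q in pieces)
    return ProjectionResult(start=start, end=end, unmapped_bp=(b - a) - covered)


@dataclass
class ConsensusResult:
    chrom: str
    start: float
    end: float
    support: List[str]
    unmappable: List[str] = field(default_factory=list)
    mode: str = "intersection"  # or "majority"


def consensus_interval(
    peaks: Dict[str, PeakInterval],
    chains: Dict[str, Sequence[PafRecord]],
    anchor: str,
) -> Optional[ConsensusResult]:
    """Project each reference's top peak onto the anchor and intersect.

    ``chains[ref]`` aligns reference ``ref`` (query side) to the anchor
    (target side); the anchor's own peak needs no chain. When the common
    intersection is empty the minimal interval covering the deepest point of
    overlap is returned instead (majority rule). References whose peak cannot
    be projected are recorded as unmappable. Returns None when no two
    projections overlap at all.
    """
    if len(peaks) < 2:
        raise ValueError("consensus needs peaks from at least 2 references")
    projected: Dict[str, Tuple[float, float]] = {}
    unmappable: List[str] = []
    chrom = peaks[anchor].chrom if anchor in peaks else next(iter(peaks.values())).chrom
    for ref, peak in peaks.items():
        if ref == anchor:
            projected[ref] = (peak.start, peak.end)
            continue
        proj = project_interval((peak.start, peak.end), chains[ref], source="query")
        if proj is None:
            unmappable.append(ref)
            logger.warning("peak of %s unmappable onto %s", ref, anchor)
        else:
            projected[ref] = (proj.start, proj.end)
    if len(projected) == 0:
        return None
    starts = [s for s, _ in projected.values()]
    ends = [e for _, e in projected.values()]
    inter = (max(starts), min(ends))
    if inter[1] > inter[0]:
        return ConsensusResult(
            chrom=chrom,
            start=inter[0],
            end=inter[1],
            support=sorted(projected),
            unmappable=sorted(unmappable),
            mode="intersection",
        )
    # majority rule: the segment(s) covered by the most projections
    bounds = sorted(set(starts) | set(ends))
    best_depth, best_seg, best_refs = 0, None, []
    for lo, hi in zip(bounds, bounds[1:]):
        mid = (lo + hi) / 2.0
        refs = [r for r, (s, e) in projected.items() if s <= mid < e]
        if len(refs) > best_depth:
            best_depth, best_seg, best_refs = len(refs), (lo, hi), refs
    if best_depth < 2:
        logger.warning("projections are pairwise disjoint; no consensus")
        return None
    return ConsensusResult(
        chrom=chrom,
        start=best_seg[0],
        end=best_seg[1],
        support=sorted(best_refs),
        unmappable=sorted(unmappable),
        mode="majority",
    )


def select_diagnostic_snps(
    table: pd.DataFrame,
    interval: Tuple[float, float],
    expected_freqs: Tuple[float, float] = (1.0, 0.5),
    min_depth: int = 10,
    tol: float = 0.1,
) -> pd.DataFrame:
    """Score SNPs inside the consensus interval as diagnostic-marker candidates.

    A SNP passes when both bulks reach ``min_depth`` and each bulk's observed
    selected-allele (ALT) frequency is within ``tol`` of the design
    expectation. Output is ranked by the smaller of the two depths,
    descending, and carries pass/fail with the failing criterion.
    """
    sel = table[(table["POS"] >= interval[0]) & (table["POS"] < interval[1])].copy()
    d1 = sel["AD_bulk1_ref"] + sel["AD_bulk1_alt"]
    d2 = sel["AD_bulk2_ref"] + sel["AD_bulk2_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = sel["AD_bulk1_alt"] / d1
        f2 = sel["AD_bulk2_alt"] / d2
    depth_ok = (d1 >= min_depth) & (d2 >= min_depth)
    freq_ok = ((f1 - expected_freqs[0]).abs() <= tol) & ((f2 - expected_freqs[1]).abs() <= tol)
    sel["depth_bulk1"] = d1
    sel["depth_bulk2"] = d2
    sel["freq_bulk1"] = f1
    sel["freq_bulk2"] = f2
    sel["passed"] = depth_ok & freq_ok
    sel["reason"] = np.where(depth_ok, np.where(freq_ok, "", "frequency"), "depth")
    return sel.sort_values(
        by=["passed", "depth_bulk1", "depth_bulk2"], ascending=[False, False, False], kind="stable"
    ).reset_index(drop=True)


def run_bsa(
    table: pd.DataFrame,
    min_depth: int = 10,
    window: float = 2_000_000,
    step: float = 10_000,
    n_sim: int = 1000,
    percentile: float = 99.5,
    design: str = "backcross",
    n_plants: Optional[int] = None,
    recomb_rate: float = 1.0,
    chrom_length: Optional[float] = None,
    reference: str = "ref",
    seed: int = 0,
) -> Tuple[GProfile, List[PeakInterval]]:
    """Depth-filter, score, smooth, threshold, and call peak intervals."""
    snps = filter_snps(table, min_depth=min_depth)
    if len(snps) == 0:
        raise ValueError("no SNPs pass the depth filter")
    chrom = str(snps["CHROM"].iat[0])
    g = snp_g(snps)
    profile = smooth_g(
        snps["POS"].to_numpy(dtype=float), g, window=window, step=step, chrom=chrom, chrom_length=chrom_length
    )
    profile.threshold = null_threshold(
        snps,
        window=window,
        step=step,
        n_sim=n_sim,
        percentile=percentile,
        design=design,
        n_plants=n_plants,
        recomb_rate=recomb_rate,
        chrom_length=chrom_length,
        seed=seed,
    )
    return profile, significant_intervals(profile, reference=reference)
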