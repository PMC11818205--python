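"""Marker QC and Marey-map recombination-landscape estimation.

F2 linkage markers (genotypes coded AA/AB/BB with the A allele from parent 1)
are filtered for segregation distortion against the Mendelian 1:2:1
expectation, excess missing data, and complete linkage disequilibrium
(identical genotype vectors). Genetic position (cM) is regressed on physical
position (bp) per chromosome with LOESS (span 0.25 of the data), the fit is
monotonized by isotonic projection, and the recombination rate in cM/Mb is
the absolute numerical derivative between successive fitted values. Long
low-rate stretches are reported as regions of suppressed recombination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "segregation_chi2",
    "maf",
    "genotype_counts",
    "filter_markers",
    "marey_fit",
    "recombination_rate",
    "suppressed_regions",
    "RecombProfile",
]

GENOTYPE_CODES = {"AA": 0, "AB": 1, "BB": 2, "NA": -1, "": -1, "-": -1}


def segregation_chi2(n_AA: int, n_AB: int, n_BB: int) -> Tuple[float, float]:
    """Chi-square goodness of fit against the 1:2:1 F2 expectation (df = 2)."""
    n = n_AA + n_AB + n_BB
    if n <= 0:
        raise ValueError("no genotyped individuals")
    obs = np.array([n_AA, n_AB, n_BB], dtype=float)
    exp = n * np.array([0.25, 0.5, 0.25])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, p


def maf(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Family-level minor allele frequency from genotype counts."""
    n = n_AA + n_AB + n_BB
    if n <= 0:
        raise ValueError("no genotyped individuals")
    p_a = (2 * n_AA + n_AB) / (2 * n)
    return min(p_a, 1.0 - p_a)


def _genotype_matrix(table: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    meta = {"marker", "chrom", "pos_bp", "cM"}
    ind_cols = [c for c in table.columns if c not in meta]
    codes = np.full((len(table), len(ind_cols)), -1, dtype=np.int8)
    for j, col in enumerate(ind_cols):
        vals = table[col].astype(str).str.upper()
        codes[:, j] = vals.map(lambda v: GENOTYPE_CODES.get(v, -1)).to_numpy(dtype=np.int8)
    return codes, ind_cols


def genotype_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-marker n_AA, n_AB, n_BB, n_missing from a genotype-matrix table."""
    codes, _ = _genotype_matrix(table)
    return pd.DataFrame(
        {
            "marker": table["marker"].to_numpy(),
            "n_AA": (codes == 0).sum(axis=1),
            "n_AB": (codes == 1).sum(axis=1),
            "n_BB": (codes == 2).sum(axis=1),
            "n_missing": (codes == -1).sum(axis=1),
        }
    )


def filter_markers(
    table: pd.DataFrame,
    distortion_p: float = 1e-5,
    max_missing: float = 0.35,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop distorted, gappy and duplicated markers; return (kept, QC report).

    A marker is dropped when its 1:2:1 goodness-of-fit p-value falls below
    ``distortion_p``, when its missing fraction exceeds ``max_missing``
    (strict), or when its genotype vector duplicates an earlier retained
    marker on the same chromosome (missing entries match anything). The QC
    report lists one row per input marker with its fate and statistics.
    """
    if len(table) == 0:
        raise ValueError("empty marker table")
    codes, ind_cols = _genotype_matrix(table)
    n_ind = len(ind_cols)
    chroms = table["chrom"].to_numpy()
    report_rows = []
    keep = np.zeros(len(table), dtype=bool)
    retained_by_chrom: Dict[str, List[int]] = {}
    for i in range(len(table)):
        row = codes[i]
        n_aa = int((row == 0).sum())
        n_ab = int((row == 1).sum())
        n_bb = int((row == 2).sum())
        n_missing = n_ind - (n_aa + n_ab + n_bb)
        missing_frac = n_missing / n_ind
        rec = {
            "marker": table["marker"].iat[i],
            "n_AA": n_aa,
            "n_AB": n_ab,
            "n_BB": n_bb,
            "missing_frac": missing_frac,
            "status": "retained",
            "reason": "",
            "duplicate_of": "",
        }
        if n_aa + n_ab + n_bb == 0:
            rec.update(status="dropped", reason="no_data", chi2=np.nan, p=np.nan)
            report_rows.append(rec)
            continue
        chi2, p = segregation_chi2(n_aa, n_ab, n_bb)
        rec["chi2"], rec["p"] = chi2, p
        if p < distortion_p:
            rec.update(status="dropped", reason="distortion")
        elif missing_frac > max_missing:
            rec.update(status="dropped", reason="missingness")
        else:
            dup_of = None
            for j in retained_by_chrom.get(chroms[i], []):
                other = codes[j]
                both = (row >= 0) & (other >= 0)
                if np.array_equal(row[both], other[both]):
                    dup_of = j
                    break
            if dup_of is not None:
                rec.update(status="dropped", reason="duplicate", duplicate_of=table["marker"].iat[dup_of])
            else:
                keep[i] = True
                retained_by_chrom.setdefault(chroms[i], []).append(i)
        report_rows.append(rec)
    report = pd.DataFrame(report_rows)
    assert keep.sum() + (report.status == "dropped").sum() == len(table)
    return table.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Marey map
# ---------------------------------------------------------------------------


def _local_polyfit(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Local polynomial regression with tricube weights over the span-nearest
    fraction of points, evaluated at each x (used for degree != 1)."""
    n = x.size
    k = max(degree + 1, int(np.ceil(span * n)))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, k - 1)[k - 1]
        w = np.clip(1 - (d / max(h, 1e-300)) ** 3, 0, None) ** 3
        sel = w > 0
        coeffs = np.polyfit(x[sel] - x[i], y[sel], degree, w=np.sqrt(w[sel]))
        fitted[i] = coeffs[-1]
    return fitted


def marey_fit(
    physical: Sequence[float],
    genetic: Sequence[float],
    span: float = 0.25,
    degree: int = 1,
    monotonic: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """LOESS fit of genetic position (cM) on physical position (bp).

    Duplicate physical positions are collapsed to their mean genetic position
    first; at least 10 distinct positions are required. The fitted sequence is
    projected onto the nearest monotone sequence (isotonic regression) before
    differentiation unless ``monotonic=False``, which reproduces the raw LOESS
    output. Returns (unique physical positions, fitted genetic positions).
    """
    phys = np.asarray(physical, dtype=float)
    gen = np.asarray(genetic, dtype=float)
    if phys.size != gen.size:
        raise ValueError("physical and genetic arrays differ in length")
    order = np.argsort(phys, kind="stable")
    phys, gen = phys[order], gen[order]
    ux, inv = np.unique(phys, return_inverse=True)
    if ux.size < phys.size:
        sums = np.bincount(inv, weights=gen)
        counts = np.bincount(inv)
        gen = sums / counts
        phys = ux
    if phys.size < 10:
        raise ValueError("need at least 10 markers with distinct physical positions")
    if degree == 1:
        fitted = lowess(gen, phys, frac=span, return_sorted=False)
    else:
        fitted = _local_polyfit(phys, gen, span, degree)
    if monotonic:
        iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
        fitted = iso.fit_transform(phys, fitted)
    return phys, fitted


@dataclass
class RecombProfile:
    """Recombination-rate track for one chromosome."""

    chrom: str
    positions: np.ndarray  # marker physical positions (bp)
    fitted: np.ndarray  # LOESS-fitted genetic positions (cM)
    midpoints: np.ndarray  # inter-marker midpoints (bp)
    rates: np.ndarray  # |d genetic / d physical| in cM/Mb

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "midpoint_bp": self.midpoints, "rate_cM_Mb": self.rates})


def recombination_rate(
    physical: Sequence[float],
    fitted: Sequence[float],
    chrom: str = "chr",
) -> RecombProfile:
    """Rate between successive fitted values, attached to pair midpoints.

    rate_i = |fit_{i+1} - fit_i| / (p_{i+1} - p_i) * 1e6 cM/Mb. Marker pairs
    with zero physical gap are skipped and logged.
    """
    phys = np.asarray(physical, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if phys.size < 2:
        raise ValueError("need at least 2 markers")
    dp = np.diff(phys)
    dg = np.abs(np.diff(fit))
    ok = dp > 0
    if not ok.all():
        logger.warning("%d marker pairs with zero physical gap skipped", int((~ok).sum()))
    mids = (phys[:-1] + phys[1:])[ok] / 2.0
    rates = dg[ok] / dp[ok] * 1e6
    return RecombProfile(chrom=chrom, positions=phys, fitted=fit, midpoints=mids, rates=rates)


def suppressed_regions(
    profile: RecombProfile,
    rate_threshold: float = 0.5,
    min_span: float = 40_000_000,
) -> List[Tuple[float, float]]:
    """Maximal runs of midpoints with rate below threshold spanning >= min_span.

    Returns (start, end) in bp over the run's midpoints.
    """
    below = profile.rates < rate_threshold
    regions = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            start, end = profile.midpoints[i], profile.midpoints[j]
            if end - start >= min_span:
                regions.append((float(start), float(end)))
            i = j + 1
        else:
            i += 1
    return regions
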