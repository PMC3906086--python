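"""Chromosome-proportion Z-score test for trisomy and evaluation statistics.

The molecular-counting test: a sample's target-chromosome proportion p_j is
the sum of corrected bin values on the target divided by the sum over all
chromosomes except chrY.  A trisomic fetus at fetal fraction f raises the
target's representation by f/2, and the Z-score of p_j against a reference
set of euploid pregnancies (mean, n-1 standard deviation) exceeds 3 when the
excess is resolvable at the sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import is_chry


def chrom_proportion(
    bins: pd.DataFrame, target: str, value_col: str = "corrected"
) -> float:
    """Target-chromosome share of the corrected bin mass, chrY excluded.

    Sums are restricted to valid bins; chrY bins never enter the denominator.
    """
    valid = bins["valid"].to_numpy(dtype=bool)
    vals = bins[value_col].to_numpy(dtype=float)
    chroms = bins["chrom"].to_numpy()
    usable = valid & np.isfinite(vals) & ~np.fromiter(
        (is_chry(c) for c in chroms), dtype=bool, count=len(bins)
    )
    denom = vals[usable].sum()
    if denom <= 0:
        raise ValueError("zero total corrected mass; cannot form a proportion")
    num = vals[usable & (chroms == target)].sum()
    return float(num / denom)


@dataclass
class ReferenceStats:
    """Mean and n-1 standard deviation of reference-set proportions."""

    n_ref: int
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "ReferenceStats":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("reference set must contain at least 2 samples")
        sd = float(v.std(ddof=1))
        if sd <= 0:
            raise ValueError("degenerate reference: zero standard deviation")
        return cls(n_ref=int(v.size), mean=float(v.mean()), sd=sd)


@dataclass
class ZScoreResult:
    z: float
    call: str  # "trisomy" | "euploid"
    threshold: float


def z_score(p: float, reference, threshold: float = 3.0) -> ZScoreResult:
    """Z-score of a sample proportion against the reference set.

    ``reference`` is either a ReferenceStats or an array of reference
    proportions.  The trisomy call uses the strict inequality z > threshold.
    """
    ref = reference if isinstance(reference, ReferenceStats) else ReferenceStats.from_values(reference)
    z = (p - ref.mean) / ref.sd
    return ZScoreResult(z=float(z), call="trisomy" if z > threshold else "euploid", threshold=threshold)


def discriminatory_distance(z_normals, z_trisomies) -> float:
    """5th percentile of trisomy Z-scores minus 95th percentile of normal Z-scores.

    Positive values mean the groups are separated; negative values occur when
    the distributions overlap.  Quantiles interpolate linearly between order
    statistics.
    """
    zn = np.asarray(z_normals, dtype=float)
    zt = np.asarray(z_trisomies, dtype=float)
    if zn.size == 0 or zt.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.quantile(zt, 0.05) - np.quantile(zn, 0.95))


def accuracy(calls, truth) -> float:
    """Fraction of per-sample trisomy calls matching the known karyotypes."""
    calls = list(calls)
    truth = list(truth)
    if len(calls) != len(truth):
        raise ValueError("calls and truth must be aligned")
    if not calls:
        raise ValueError("empty input")
    return float(np.mean([c == t for c, t in zip(calls, truth)]))


def welch_t(a, b) -> tuple[float, float]:
    """Welch's t statistic and Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return float(t), float(df)


def welch_pairwise_min_t(
    bins: pd.DataFrame,
    chromosomes=None,
    alpha_base: float = 0.001,
    value_col: str = "corrected",
) -> pd.DataFrame:
    """Reference-free over-representation test via pairwise Welch t-tests.

    For every ordered chromosome pair (i, j) the corrected bin values of i
    are tested against j; chromosome i's statistic is the minimum t over all
    j, and i is called over-represented when that minimum exceeds the
    one-sided critical value at alpha_base / (m * (m-1)) comparisons.
    """
    if chromosomes is None:
        chromosomes = [c for c in pd.unique(bins["chrom"]) if not is_chry(c)]
    chromosomes = list(chromosomes)
    m = len(chromosomes)
    if m < 2:
        raise ValueError("need at least two chromosomes")
    values = {}
    for c in chromosomes:
        sel = (bins["chrom"] == c) & bins["valid"] & np.isfinite(bins[value_col])
        v = bins.loc[sel, value_col].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"chromosome {c!r} has fewer than 2 valid bins")
        values[c] = v
    alpha = alpha_base / (m * (m - 1))
    rows = []
    for ci in chromosomes:
        min_t, min_df = np.inf, np.nan
        for cj in chromosomes:
            if cj == ci:
                continue
            t, df = welch_t(values[ci], values[cj])
            if t < min_t:
                min_t, min_df = t, df
        crit = float(stats.t.ppf(1.0 - alpha, min_df))
        rows.append(
            {
                "chrom": ci,
                "min_t": min_t,
                "df": min_df,
                "critical_value": crit,
                "call": "over-represented" if min_t > crit else "normal",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    return out
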