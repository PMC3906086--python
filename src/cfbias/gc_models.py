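"""GC-bias models: binned LOESS, single-position rates, TV-score and MAD.

Two corrections are implemented.  The classical one fits a LOESS curve to
mean bin count per 1% GC interval and divides each bin by its predicted
count.  The single-position model instead stratifies uniquely mappable
positions by the GC count of a fixed-length window beginning at the position
(strand-specifically), estimates a mean fragment rate per GC stratum, smooths
the rates, and corrects each bin by the sum of its per-position predictions.

The total-variation score measures how much of the variation in fragment
rate is explained by a stratification: it is the half-L1 distance between the
distribution of fragments over strata and the distribution of positions over
strata, zero when the fragment rate is constant across strata and approaching
one when all fragments concentrate in strata holding few positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .bins import BinScheme, scheme_from_table
from .positions import (
    PositionSample,
    attach_fragment_counts,
    sample_unique_positions,
    window_gc_at,
)
from .reference import GenomeSequence, MappabilityTrack

DEFAULT_POSITION_SAMPLE = 5_000_000


# ---------------------------------------------------------------------------
# LOESS correction on binned counts
# ---------------------------------------------------------------------------


@dataclass
class LoessFit:
    """LOESS fit of mean bin count against GC percent-interval midpoints."""

    span: float
    gc_mid: np.ndarray  # interval midpoints, percent
    mean_count: np.ndarray
    fitted: np.ndarray

    def predict(self, gc_fraction) -> np.ndarray:
        """Evaluate the fit at bin GC fractions (linear interpolation)."""
        return np.interp(np.asarray(gc_fraction, dtype=float) * 100.0, self.gc_mid, self.fitted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gc_mid_percent": self.gc_mid, "mean_count": self.mean_count, "fitted": self.fitted}
        )


def loess_gc_correct(
    bins: pd.DataFrame,
    span: float = 0.3,
    count_col: str = "raw_count",
    out_col: str = "corrected",
) -> tuple[pd.DataFrame, LoessFit]:
    """LOESS GC correction of bin counts.

    Mean counts are computed per 1% GC interval over valid bins with nonzero
    counts, a LOESS curve with the given span is fitted to (midpoint, mean),
    and each valid bin's corrected value is count / prediction at its GC.
    Zero-count bins are excluded from the fit but still corrected (to 0).
    """
    counts = bins[count_col].to_numpy(dtype=float)
    gc = bins["gc"].to_numpy(dtype=float)
    valid = bins["valid"].to_numpy(dtype=bool) & np.isfinite(counts) & np.isfinite(gc)
    fit_sel = valid & (counts > 0)
    interval = np.floor(gc[fit_sel] * 100.0).astype(int)
    if np.unique(interval).size < 5:
        raise ValueError("fewer than 5 occupied 1% GC intervals; cannot fit LOESS")
    grp = pd.Series(counts[fit_sel]).groupby(interval).mean()
    mids = grp.index.to_numpy(dtype=float) + 0.5
    means = grp.to_numpy(dtype=float)
    smoothed = _sm_lowess(means, mids, frac=span, return_sorted=True)
    fit = LoessFit(span=span, gc_mid=smoothed[:, 0], mean_count=means, fitted=smoothed[:, 1])
    pred = np.full(len(bins), np.nan)
    pred[valid] = fit.predict(gc[valid])
    if np.any(pred[valid] <= 0):
        raise ValueError("nonpositive LOESS prediction at a valid bin")
    out = bins.copy()
    vals = np.full(len(bins), np.nan)
    vals[valid] = counts[valid] / pred[valid]
    out[out_col] = vals
    out[f"{count_col}_loess_pred"] = pred
    out.attrs["method"] = f"loess(span={span})"
    return out, fit


def mad(observed, predicted) -> float:
    """Mean absolute deviation between observed and predicted bin counts."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty input to mad")
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    return float(np.mean(np.abs(obs - pred)))


# ---------------------------------------------------------------------------
# TV-score
# ---------------------------------------------------------------------------


def tv_score(n, F) -> float:
    """Total variation from independence between positions and fragments.

    score = 1/2 * sum_s | F_s / sum(F) - n_s / sum(n) |, the half-L1 distance
    between the fragment and position distributions over strata.  Zero iff
    the fragment rate is identical in every stratum.
    """
    n = np.asarray(n, dtype=float)
    F = np.asarray(F, dtype=float)
    if n.shape != F.shape:
        raise ValueError("n and F must have the same shape")
    tn, tF = n.sum(), F.sum()
    if tn <= 0:
        raise ValueError("no positions in any stratum")
    if tF <= 0:
        raise ValueError("no fragments in any stratum")
    return float(0.5 * np.abs(F / tF - n / tn).sum())


@dataclass
class TVScoreCurve:
    """TV score as a function of GC window length, plus the selected length."""

    lengths: np.ndarray
    scores: np.ndarray
    selected: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_length": self.lengths, "tv_score": self.scores})


def gc_window_scan(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    track: MappabilityTrack,
    lengths=range(1, 701),
    sample_size: int | None = 500_000,
    seed: int = 0,
) -> TVScoreCurve:
    """TV score of the GC stratification for each candidate window length.

    One position sample is drawn and shared across lengths; for each length,
    positions whose window runs off the chromosome (or contains N) are
    excluded for that length only.
    """
    sample = sample_unique_positions(genome, track, sample_size, seed=seed)
    attach_fragment_counts(sample, frags)
    lengths = np.asarray(list(lengths), dtype=int)
    scores = np.empty(lengths.size, dtype=float)
    for i, l in enumerate(lengths):
        gc, ok = window_gc_at(sample, genome, int(l))
        if ok.sum() < 1000:
            raise ValueError(
                f"fewer than 1000 sampled positions remain at window length {l}"
            )
        n_s = np.bincount(gc[ok], minlength=int(l) + 1)
        F_s = np.bincount(gc[ok], weights=sample.F[ok], minlength=int(l) + 1)
        scores[i] = tv_score(n_s, F_s)
    return TVScoreCurve(lengths=lengths, scores=scores)


def select_gc_window(
    curve: TVScoreCurve,
    low: int = 50,
    high: int = 500,
    flatness_tol: float = 0.005,
    fallback: int = 180,
) -> int:
    """Pick the GC window: argmax of the curve on [low, high] bp.

    The sub-10 bp fragmentation-motif spike lies outside the eligible range.
    If the restricted curve is flat (max - median < flatness_tol) the
    nucleosome-scale fallback (180 bp) is returned.
    """
    sel = (curve.lengths >= low) & (curve.lengths <= high)
    if not sel.any():
        curve.selected = fallback
        return fallback
    s = curve.scores[sel]
    if s.max() - np.median(s) < flatness_tol:
        curve.selected = fallback
        return fallback
    choice = int(curve.lengths[sel][np.argmax(s)])
    curve.selected = choice
    return choice


# ---------------------------------------------------------------------------
# Single-position model
# ---------------------------------------------------------------------------


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def weighted_local_linear(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.3,
) -> np.ndarray:
    """Locally weighted linear regression with observation weights.

    At each evaluation point the nearest ceil(span * len(x)) data points get
    tricube neighbourhood weights, multiplied by the observation weights
    ``w``; a weighted straight line is fitted and evaluated there.  Falls
    back to the weighted mean when the local design is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    out = np.empty(x_eval.size, dtype=float)
    q = max(int(np.ceil(span * x.size)), 2)
    q = min(q, x.size)
    for j, xe in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - xe)
        dq = np.partition(d, q - 1)[q - 1]
        if dq == 0:
            dq = max(d.max(), 1.0)
        ww = _tricube(d / dq) * w
        sw = ww.sum()
        if sw <= 0:
            # no local support: fall back to global weighted mean
            out[j] = float(np.average(y, weights=w)) if w.sum() > 0 else float(y.mean())
            continue
        xm = np.average(x, weights=ww)
        ym = np.average(y, weights=ww)
        sxx = np.sum(ww * (x - xm) ** 2)
        if sxx <= 1e-12:
            out[j] = ym
        else:
            beta = np.sum(ww * (x - xm) * (y - ym)) / sxx
            out[j] = ym + beta * (xe - xm)
    return out


@dataclass
class GCStrataTable:
    """Stratified position/fragment counts and rates for the single-position model.

    For window length l there are l + 1 strata (integer G+C counts).  ``n``
    counts sampled positions per stratum, ``F`` fragments starting at those
    positions, ``rate`` = F/n where defined, and ``rate_smooth`` the smoothed,
    non-negative rate evaluated at every stratum (including empty ones).
    """

    window_length: int
    n: np.ndarray
    F: np.ndarray
    rate: np.ndarray
    rate_smooth: np.ndarray
    n_positions: int
    seed: int | None = None

    def predict(self, strata) -> np.ndarray:
        return self.rate_smooth[np.asarray(strata, dtype=int)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gc_count": np.arange(self.window_length + 1),
                "n_positions": self.n,
                "n_fragments": self.F,
                "rate": self.rate,
                "rate_smooth": self.rate_smooth,
            }
        )


def single_position_fit(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    track: MappabilityTrack,
    window_length: int,
    sample_size: int | None = None,
    seed: int = 0,
    span: float = 0.3,
    position_mask=None,
) -> GCStrataTable:
    """Estimate per-GC-stratum fragment rates from sampled unique positions.

    Positions are sampled uniformly from uniquely mappable positions on both
    strands (default sample size min(N_unique, 5e6)); each is assigned the GC
    count of its strand-oriented window; rates F_s/n_s are smoothed by local
    linear regression weighted by n_s and clamped at zero.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if sample_size is None:
        sample_size = DEFAULT_POSITION_SAMPLE
    sample = sample_unique_positions(
        genome, track, sample_size, seed=seed, position_mask=position_mask
    )
    attach_fragment_counts(sample, frags)
    return _fit_strata_from_sample(sample, genome, window_length, span=span)


def _fit_strata_from_sample(
    sample: PositionSample,
    genome: GenomeSequence,
    window_length: int,
    span: float = 0.3,
) -> GCStrataTable:
    gc, ok = window_gc_at(sample, genome, window_length)
    n_s = np.bincount(gc[ok], minlength=window_length + 1)
    F_s = np.bincount(gc[ok], weights=sample.F[ok], minlength=window_length + 1).astype(
        np.int64
    )
    occupied = n_s > 0
    if occupied.sum() < 10:
        raise ValueError("fewer than 10 occupied GC strata; input too small")
    rate = np.full(window_length + 1, np.nan)
    rate[occupied] = F_s[occupied] / n_s[occupied]
    s_all = np.arange(window_length + 1, dtype=float)
    smooth = weighted_local_linear(
        s_all[occupied], rate[occupied], n_s[occupied].astype(float), s_all, span=span
    )
    rate_smooth = np.clip(smooth, 0.0, None)
    return GCStrataTable(
        window_length=window_length,
        n=n_s,
        F=F_s,
        rate=rate,
        rate_smooth=rate_smooth,
        n_positions=int(ok.sum()),
        seed=sample.seed,
    )


def bin_prediction_sums(
    genome: GenomeSequence,
    track: MappabilityTrack,
    scheme: BinScheme,
    strata: GCStrataTable,
    position_mask=None,
) -> np.ndarray:
    """Sum per-position predicted rates over each bin, both strands.

    Every uniquely mappable position gets the smoothed rate of its GC stratum
    (zero elsewhere, and zero where the GC window is undefined); predictions
    are accumulated into the bin holding the position.
    """
    l = strata.window_length
    lam = strata.rate_smooth
    pred = np.zeros(scheme.total_bins, dtype=float)
    offsets = scheme.row_offsets()
    B = scheme.bin_size
    for chrom, nb in scheme.nbins.items():
        if nb == 0:
            continue
        L = genome.lengths[chrom]
        gccum = genome.gc_cumsum(chrom)
        ncum = genome.n_cumsum(chrom)
        nwin = L - l + 1
        per_pos = np.zeros(L, dtype=float)
        if nwin > 0:
            g = gccum[l:] - gccum[:-l]  # GC of window [x, x+l), x in 0..L-l
            clean = (ncum[l:] - ncum[:-l]) == 0
            # forward strand: window starts at the position
            u_f = track.forward_unique(chrom, L)[:nwin]
            sel = u_f & clean
            fwd = np.zeros(L, dtype=float)
            fwd[:nwin][sel] = lam[g[sel]]
            if position_mask is not None:
                fwd[~position_mask(chrom, False)] = 0.0
            # reverse strand: window ends at the 5' position x, so the window
            # starting index is x - l + 1 and g[x - l + 1] applies
            u_r = track.reverse_unique(chrom, L)[l - 1 :][:nwin]
            sel_r = u_r & clean
            rev = np.zeros(L, dtype=float)
            rev[l - 1 :][: nwin][sel_r] = lam[g[sel_r]]
            if position_mask is not None:
                rev[~position_mask(chrom, True)] = 0.0
            per_pos = fwd + rev
        last = nb * B
        sums = per_pos[:last].reshape(nb, B).sum(axis=1)
        pred[offsets[chrom] : offsets[chrom] + nb] = sums
    return pred


def single_position_correct(
    bins: pd.DataFrame,
    strata: GCStrataTable,
    genome: GenomeSequence,
    track: MappabilityTrack,
    count_col: str = "raw_count",
    out_col: str = "corrected",
    reciprocal_mappability: bool = True,
    mappability_cutoff: float = 0.5,
    min_prediction: float = 1e-12,
) -> pd.DataFrame:
    """Correct bin counts by aggregated single-position predictions.

    corrected = count / sum(predictions in bin), multiplied by 1/mappability
    (the model's stated form; disable with ``reciprocal_mappability=False``).
    Bins with aggregated prediction below tolerance or mappability below the
    cutoff are invalidated.
    """
    if bins["mappability"].isna().any():
        raise ValueError("bin mappability is missing; compute or import a track first")
    scheme = scheme_from_table(bins)
    pred = bin_prediction_sums(genome, track, scheme, strata)
    out = bins.copy()
    m = out["mappability"].to_numpy(dtype=float)
    counts = out[count_col].to_numpy(dtype=float)
    bad = (pred < min_prediction) | (m < mappability_cutoff)
    out.loc[bad, "valid"] = False
    vals = np.full(len(out), np.nan)
    ok = ~bad
    vals[ok] = counts[ok] / pred[ok]
    if reciprocal_mappability:
        vals[ok] = vals[ok] / m[ok]
    out[out_col] = vals
    out["sp_prediction"] = pred
    out.attrs["method"] = f"single_position(l={strata.window_length})"
    return out
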