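"""Fragmentation-signature analysis of plasma cfDNA and motif-stratified correction.

Plasma DNA is cleaved by biological processes (apoptotic nucleases) rather
than mechanical shearing, which leaves a position-specific nucleotide
signature around fragment ends.  This module quantifies that signature
(positional base profiles, TV-score conditioning on breakpoint offsets,
breakpoint 3-mer tables, a strand-homogeneity test) and implements the
two-stratum, motif-conditional variant of the single-position GC correction.

The *breakpoint 3-mer* of a fragment is the ordered reference bases at
offsets (-2, 0, +1) relative to its 5' end, in read-strand orientation,
rendered like ``C*CC`` with the wildcard at offset -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bins import scheme_from_table
from .fragments import five_prime
from .gc_models import (
    _fit_strata_from_sample,
    bin_prediction_sums,
    single_position_fit,
    tv_score,
)
from .positions import (
    attach_fragment_counts,
    base_codes_at,
    sample_unique_positions,
)
from .reference import COMPLEMENT, GenomeSequence, MappabilityTrack

MOTIF_OFFSETS = (-2, 0, 1)
_BASES = "ACGT"

DEFAULT_STRATUM1_MOTIFS = frozenset({"C*CC", "C*GG", "C*CA", "C*TG"})


def motif_name(index: int) -> str:
    """Render motif index (base-4 over offsets -2, 0, +1) as ``X*YZ``."""
    a, rest = divmod(index, 16)
    b, c = divmod(rest, 4)
    return f"{_BASES[a]}*{_BASES[b]}{_BASES[c]}"


def all_motifs() -> list[str]:
    """The 64 possible breakpoint 3-mers, in index order."""
    return [motif_name(i) for i in range(64)]


def motif_index(name: str) -> int:
    a, b, c = name[0], name[2], name[3]
    return 16 * _BASES.index(a) + 4 * _BASES.index(b) + _BASES.index(c)


def _context_code(codes: np.ndarray, coords: np.ndarray, is_rev: bool) -> np.ndarray:
    """Base codes at coordinates with strand orientation; 255 = out of bounds/N."""
    L = codes.size
    out = np.full(coords.size, 255, dtype=np.uint8)
    inb = (coords >= 0) & (coords < L)
    c = codes[coords[inb]]
    if is_rev:
        c = COMPLEMENT[c]
    out[inb] = c
    out[out == 4] = 255
    return out


def fragment_motif_indices(frags: pd.DataFrame, genome: GenomeSequence) -> np.ndarray:
    """Breakpoint 3-mer index (0..63) per fragment; -1 when undetermined.

    The context is taken from the reference at the mapped 5' position, so the
    motif is a property of (position, strand) rather than of read bases.
    """
    out = np.full(len(frags), -1, dtype=np.int64)
    pos5 = five_prime(frags)
    chrom_arr = frags["chrom"].to_numpy()
    rev = frags["strand"].to_numpy() == "-"
    for chrom in pd.unique(chrom_arr):
        codes = genome.codes(chrom)
        for is_rev in (False, True):
            sel = np.flatnonzero((chrom_arr == chrom) & (rev == is_rev))
            if sel.size == 0:
                continue
            p = pos5[sel]
            idx = np.zeros(sel.size, dtype=np.int64)
            good = np.ones(sel.size, dtype=bool)
            for off in MOTIF_OFFSETS:
                coords = p + (-off if is_rev else off)
                c = _context_code(codes, coords, is_rev)
                good &= c != 255
                idx = idx * 4 + np.where(c == 255, 0, c)
            out[sel[good]] = idx[good]
    return out


def position_motif_indices(
    genome: GenomeSequence, chrom: str, is_rev: bool
) -> np.ndarray:
    """Motif index of every 5'-end coordinate of a chromosome on one strand."""
    codes = genome.codes(chrom)
    L = codes.size
    pos = np.arange(L, dtype=np.int64)
    idx = np.zeros(L, dtype=np.int64)
    good = np.ones(L, dtype=bool)
    for off in MOTIF_OFFSETS:
        coords = pos + (-off if is_rev else off)
        c = _context_code(codes, coords, is_rev)
        good &= c != 255
        idx = idx * 4 + np.where(c == 255, 0, c)
    idx[~good] = -1
    return idx


# ---------------------------------------------------------------------------
# Positional base profile
# ---------------------------------------------------------------------------


@dataclass
class PositionalBaseProfile:
    """Per-offset base proportions around fragment termini, read orientation."""

    end: str  # "5p" or "3p"
    offsets: np.ndarray
    counts: np.ndarray  # (n_offsets, 4)
    n_fragments: int

    @property
    def proportions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore"):
            return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=list(_BASES))
        df.insert(0, "offset", self.offsets)
        return df


def base_profile(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    end: str = "5p",
    flank: int = 25,
    mapq_min: int = 60,
) -> PositionalBaseProfile:
    """Base proportions at offsets -flank..flank-1 around fragment termini.

    Only stringently mapped fragments (mapq > mapq_min) contribute.  Reverse
    strand contexts are reverse-complemented so that offset 0 is the terminal
    fragment base on either strand; offsets whose context is out of bounds
    are excluded per fragment.
    """
    if end not in {"5p", "3p"}:
        raise ValueError("end must be '5p' or '3p'")
    use = frags[frags["mapq"].to_numpy() > mapq_min]
    if use.empty:
        raise ValueError("no fragments pass the mapping-quality filter")
    rev = use["strand"].to_numpy() == "-"
    if end == "5p":
        term = five_prime(use)
    else:
        term = np.where(rev, use["start"].to_numpy(), use["end"].to_numpy() - 1)
    chrom_arr = use["chrom"].to_numpy()
    offsets = np.arange(-flank, flank)
    counts = np.zeros((offsets.size, 4), dtype=np.int64)
    for chrom in pd.unique(chrom_arr):
        codes = genome.codes(chrom)
        for is_rev in (False, True):
            sel = (chrom_arr == chrom) & (rev == is_rev)
            if not sel.any():
                continue
            t = term[sel]
            for j, off in enumerate(offsets):
                coords = t + (-off if is_rev else off)
                c = _context_code(codes, coords, is_rev)
                counts[j] += np.bincount(c[c != 255], minlength=4)[:4]
    return PositionalBaseProfile(
        end=end, offsets=offsets, counts=counts, n_fragments=int(len(use))
    )


# ---------------------------------------------------------------------------
# Positional TV conditioning
# ---------------------------------------------------------------------------


def _offset_strata(sample, genome, offsets: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Stratum index over the k-mer at the given offsets; invalid rows masked."""
    idx = np.zeros(sample.size, dtype=np.int64)
    good = np.ones(sample.size, dtype=bool)
    for off in offsets:
        c = base_codes_at(sample, genome, off)
        good &= c != 255
        idx = idx * 4 + np.where(c == 255, 0, c).astype(np.int64)
    return idx, good


def positional_tv(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    track: MappabilityTrack,
    offsets_conditioned,
    candidate: int,
    sample_size: int | None = 500_000,
    seed: int = 0,
) -> float:
    """TV score of stratifying positions by bases at given offsets plus a candidate."""
    sample = sample_unique_positions(genome, track, sample_size, seed=seed)
    attach_fragment_counts(sample, frags)
    offsets = sorted(set(offsets_conditioned) | {int(candidate)})
    return _tv_for_offsets(sample, genome, offsets)


def _tv_for_offsets(sample, genome, offsets: list[int]) -> float:
    idx, good = _offset_strata(sample, genome, offsets)
    if good.sum() < 1000:
        raise ValueError("fewer than 1000 sampled positions with full context")
    nstrata = 4 ** len(offsets)
    n_s = np.bincount(idx[good], minlength=nstrata)
    F_s = np.bincount(idx[good], weights=sample.F[good], minlength=nstrata)
    return tv_score(n_s, F_s)


def greedy_motif_positions(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    track: MappabilityTrack,
    max_k: int = 6,
    gain_tol: float = 0.005,
    candidates=range(-25, 25),
    sample_size: int | None = 500_000,
    seed: int = 0,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection of breakpoint offsets by conditional TV gain.

    Starting from the unconditioned score (0), repeatedly add the offset with
    the highest TV score until the gain drops below ``gain_tol`` or ``max_k``
    offsets are selected.  Returns the selection order and the score after
    each addition.
    """
    if max_k > 6:
        raise ValueError("max_k must be <= 6 (4^k strata grow too sparse)")
    sample = sample_unique_positions(genome, track, sample_size, seed=seed)
    attach_fragment_counts(sample, frags)
    remaining = [int(o) for o in candidates]
    selected: list[int] = []
    scores: list[float] = []
    current = 0.0
    while remaining and len(selected) < max_k:
        best_off, best_score = None, -np.inf
        for off in remaining:
            s = _tv_for_offsets(sample, genome, sorted(selected + [off]))
            if s > best_score:
                best_off, best_score = off, s
        if best_score - current < gain_tol:
            break
        selected.append(best_off)
        remaining.remove(best_off)
        scores.append(best_score)
        current = best_score
    return selected, scores


# ---------------------------------------------------------------------------
# Breakpoint 3-mer table and strand homogeneity
# ---------------------------------------------------------------------------


@dataclass
class MotifFrequencyTable:
    """Counts of the 64 breakpoint 3-mers per strand."""

    counts: pd.DataFrame  # index: 64 motif names, columns "+" and "-"
    n_excluded: int = 0

    def proportions(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def top_partition(self, k: int = 20) -> tuple[list[str], np.ndarray]:
        """Top-k motifs by combined count plus an aggregated rest class.

        Returns the category labels (k + 1 of them) and a 2 x (k+1) count
        matrix with rows (+, -).
        """
        totals = self.counts.sum(axis=1)
        top = list(totals.sort_values(ascending=False).index[:k])
        rest = [m for m in self.counts.index if m not in top]
        mat = np.zeros((2, k + 1), dtype=float)
        for i, strand in enumerate(["+", "-"]):
            mat[i, :k] = self.counts.loc[top, strand].to_numpy()
            mat[i, k] = self.counts.loc[rest, strand].sum()
        return top + ["rest"], mat


def motif_table(
    frags: pd.DataFrame, genome: GenomeSequence, mapq_min: int = 60
) -> MotifFrequencyTable:
    """64-way breakpoint 3-mer counts per strand for stringently mapped reads.

    Fragments whose 5' context is out of bounds or contains N are excluded
    and counted in ``n_excluded``.
    """
    use = frags[frags["mapq"].to_numpy() > mapq_min]
    idx = fragment_motif_indices(use, genome)
    rev = use["strand"].to_numpy() == "-"
    counts = pd.DataFrame(0, index=all_motifs(), columns=["+", "-"], dtype=np.int64)
    for strand, is_rev in (("+", False), ("-", True)):
        sel = (~rev if not is_rev else rev) & (idx >= 0)
        c = np.bincount(idx[sel], minlength=64)
        counts[strand] = c
    return MotifFrequencyTable(counts=counts, n_excluded=int((idx < 0).sum()))


def strand_homogeneity_test(
    table: MotifFrequencyTable, k: int = 20
) -> tuple[float, int, float]:
    """Chi-square test of homogeneity between the strands' motif distributions.

    The contingency table is 2 x (k+1): the common top-k motifs plus the
    aggregated rest class.  Returns (statistic, df, p-value).
    """
    _, mat = table.top_partition(k)
    if mat.sum(axis=1).min() <= 0:
        raise ValueError("both strands must have motif counts")
    expected = np.outer(mat.sum(axis=1), mat.sum(axis=0)) / mat.sum()
    if (expected < 5).any():
        warnings.warn("chi-square expected cell count below 5", stacklevel=2)
    stat, p, dof, _ = stats.chi2_contingency(mat, correction=False)
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# Two-stratum (motif-conditional) single-position correction
# ---------------------------------------------------------------------------


@dataclass
class StratumAssignment:
    """Two-class fragment stratification by breakpoint 3-mer.

    Stratum 1 holds fragments whose breakpoint 3-mer is in ``stratum1_motifs``
    (GC-shifted, over-represented motifs); stratum 2 holds everything else,
    including fragments with undetermined context.  ``w1``/``w2`` are the
    sample-wide stratum proportions used as combination weights.
    """

    stratum1_motifs: frozenset = field(default_factory=lambda: DEFAULT_STRATUM1_MOTIFS)
    fragment_stratum: np.ndarray | None = None
    w1: float = 0.0

    @property
    def w2(self) -> float:
        return 1.0 - self.w1


def assign_strata(
    frags: pd.DataFrame,
    genome: GenomeSequence,
    stratum1_motifs=DEFAULT_STRATUM1_MOTIFS,
) -> StratumAssignment:
    """Assign each fragment to stratum 1 or 2 by its reference breakpoint 3-mer."""
    motifs = frozenset(stratum1_motifs)
    idx_set = {motif_index(m) for m in motifs}
    idx = fragment_motif_indices(frags, genome)
    stratum = np.where(np.isin(idx, list(idx_set)), 1, 2).astype(np.int8)
    w1 = float((stratum == 1).mean()) if len(frags) else 0.0
    return StratumAssignment(stratum1_motifs=motifs, fragment_stratum=stratum, w1=w1)


def combine_stratum_corrections(obs, pred, weights) -> float:
    """Weighted combination of per-stratum corrected values for one bin."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * (obs / pred)))


def stratified_correct(
    bins: pd.DataFrame,
    frags: pd.DataFrame,
    genome: GenomeSequence,
    track: MappabilityTrack,
    assignment: StratumAssignment,
    window_length: int,
    sample_size: int | None = None,
    seed: int = 0,
    span: float = 0.3,
    out_col: str = "corrected",
    reciprocal_mappability: bool = True,
    mappability_cutoff: float = 0.5,
    min_prediction: float = 1e-12,
    per_bin_weights: bool = False,
) -> pd.DataFrame:
    """Motif-stratified single-position GC correction.

    The single-position model is fitted separately within stratum-1 and
    stratum-2 positions (positions are partitioned by their own reference
    breakpoint 3-mer); per bin, each stratum's observed count is normalized
    by its stratum prediction, and the corrected stratum values are combined
    with the sample-wide stratum proportions as weights (or per-bin read
    proportions when ``per_bin_weights`` is set).  The reciprocal-mappability
    factor is applied as in the unstratified correction.
    """
    if bins["mappability"].isna().any():
        raise ValueError("bin mappability is missing; compute or import a track first")
    if assignment.fragment_stratum is None or len(assignment.fragment_stratum) != len(frags):
        raise ValueError("assignment does not match the fragment set")
    scheme = scheme_from_table(bins)
    idx_set = np.array([motif_index(m) for m in assignment.stratum1_motifs])

    # position stratum masks, cached per (chrom, strand)
    motif_cache: dict[tuple[str, bool], np.ndarray] = {}

    def pos_motif(chrom: str, is_rev: bool) -> np.ndarray:
        key = (chrom, is_rev)
        if key not in motif_cache:
            motif_cache[key] = position_motif_indices(genome, chrom, is_rev)
        return motif_cache[key]

    def mask_stratum1(chrom: str, is_rev: bool) -> np.ndarray:
        m = pos_motif(chrom, is_rev)
        return np.isin(m, idx_set)

    def mask_stratum2(chrom: str, is_rev: bool) -> np.ndarray:
        m = pos_motif(chrom, is_rev)
        return ~np.isin(m, idx_set)  # undetermined context (-1) joins stratum 2

    masks = {1: mask_stratum1, 2: mask_stratum2}
    strat = assignment.fragment_stratum
    n_by_stratum = {k: int((strat == k).sum()) for k in (1, 2)}
    total = sum(n_by_stratum.values())
    weights = {k: (n_by_stratum[k] / total if total else 0.0) for k in (1, 2)}

    out = bins.copy()
    m = out["mappability"].to_numpy(dtype=float)
    invalid = m < mappability_cutoff
    combined = np.zeros(len(out), dtype=float)
    stratum_fits: dict[int, object] = {}
    from .fragments import assign_bins  # local import to avoid cycle

    for k in (1, 2):
        if n_by_stratum[k] == 0:
            continue
        sub = frags[strat == k]
        strata_k = single_position_fit(
            sub,
            genome,
            track,
            window_length,
            sample_size=sample_size,
            seed=seed,
            span=span,
            position_mask=masks[k],
        )
        stratum_fits[k] = strata_k
        pred_k = bin_prediction_sums(genome, track, scheme, strata_k, position_mask=masks[k])
        obs_k = assign_bins(sub, scheme)["raw_count"].to_numpy(dtype=float)
        bad_k = pred_k < min_prediction
        invalid |= bad_k
        ok = ~bad_k
        if per_bin_weights:
            obs_tot = assign_bins(frags, scheme)["raw_count"].to_numpy(dtype=float)
            w_k = np.divide(obs_k, obs_tot, out=np.zeros_like(obs_k), where=obs_tot > 0)
        else:
            w_k = weights[k]
        contrib = np.zeros(len(out), dtype=float)
        contrib[ok] = obs_k[ok] / pred_k[ok]
        combined += (w_k if np.isscalar(w_k) else np.asarray(w_k)) * contrib

    out.loc[invalid, "valid"] = False
    vals = np.full(len(out), np.nan)
    ok = ~invalid
    vals[ok] = combined[ok]
    if reciprocal_mappability:
        vals[ok] = vals[ok] / m[ok]
    out[out_col] = vals
    out.attrs["method"] = f"single_position_frag(l={window_length})"
    out.attrs["stratum_fits"] = stratum_fits
    out.attrs["weights"] = weights
    return out
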