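"""Aligned-fragment handling: input, 5' ends, binning, repeat removal, subsampling.

A FragmentSet is a pandas DataFrame with columns ``chrom`` (str), ``start``
and ``end`` (0-based half-open), ``strand`` ('+'/'-') and ``mapq`` (int, -1
when absent).  The 5' end of a fragment is ``start`` on the forward strand
and ``end - 1`` on the reverse strand; every binning and filtering operation
in the package keys on the 5' end.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import BinScheme, make_bin_table  # noqa: F401  (re-exported surface)
from .reference import GenomeSequence, MappabilityTrack, RepeatAnnotation

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "mapq"]


def make_fragments(
    chrom, start, end, strand, mapq=None
) -> pd.DataFrame:
    """Assemble and validate a FragmentSet from column arrays."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": np.asarray(strand, dtype=object),
        }
    )
    df["mapq"] = -1 if mapq is None else np.asarray(mapq, dtype=np.int64)
    if not df.empty:
        if (df["end"] <= df["start"]).any():
            raise ValueError("fragment with end <= start")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("fragment strand must be '+' or '-'")
    return df


def five_prime(frags: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' end positions (start for +, end-1 for -)."""
    fwd = frags["strand"].to_numpy() == "+"
    return np.where(fwd, frags["start"].to_numpy(), frags["end"].to_numpy() - 1)


def _check_chromosomes(frags: pd.DataFrame, genome: GenomeSequence) -> None:
    present = set(genome.names)
    seen = set(frags["chrom"].unique())
    missing = sorted(seen - present)
    if missing:
        raise ValueError(f"fragments on chromosomes absent from the genome: {missing}")


def read_fragments(path: str | Path, genome: GenomeSequence | None = None) -> pd.DataFrame:
    """Read fragments from BED6 or SAM/BAM.

    For SAM/BAM input, unmapped, secondary, supplementary and duplicate-flagged
    records are skipped with logged counts and ``mapq`` is carried through.
    For BED6 the score column is taken as the mapping quality.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam", ".cram"}:
        frags = _read_alignments(path)
    else:
        frags = _read_bed(path)
    if genome is not None:
        _check_chromosomes(frags, genome)
    return frags


def _read_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return make_fragments(
        df["chrom"], df["start"], df["end"], df["strand"],
        pd.to_numeric(df["score"], errors="coerce").fillna(-1).astype(np.int64),
    )


def _read_alignments(path: Path) -> pd.DataFrame:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "duplicate": 0}
    chroms, starts, ends, strands, mapqs = [], [], [], [], []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            if rec.is_duplicate:
                skipped["duplicate"] += 1
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
            mapqs.append(rec.mapping_quality)
    for kind, n in skipped.items():
        if n:
            logger.info("%s: skipped %d %s records", path, n, kind)
    frags = make_fragments(chroms, starts, ends, strands, mapqs)
    frags.attrs["skipped"] = skipped
    return frags


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    out = frags[["chrom", "start", "end"]].copy()
    out["name"] = "."
    out["score"] = frags["mapq"]
    out["strand"] = frags["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def assign_bins(
    frags: pd.DataFrame,
    scheme: BinScheme,
    genome: GenomeSequence | None = None,
    track: MappabilityTrack | None = None,
) -> pd.DataFrame:
    """Count fragment 5' ends per bin.

    Each fragment increments exactly the bin containing its 5' end; fragments
    whose 5' end falls past the last full bin of their chromosome are dropped
    and reported in ``table.attrs['n_dropped']``.
    """
    if genome is not None:
        table = make_bin_table(genome, scheme, track=track)
    else:
        table = scheme.skeleton()
        table["raw_count"] = 0
        table["gc"] = np.nan
        table["mappability"] = np.nan
        table["valid"] = True
    offsets = scheme.row_offsets()
    counts = np.zeros(scheme.total_bins, dtype=np.int64)
    dropped = 0
    pos_all = five_prime(frags)
    chrom_arr = frags["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        if chrom not in scheme.nbins:
            raise ValueError(f"fragments on chromosome {chrom!r} not in the bin scheme")
        sel = chrom_arr == chrom
        idx = pos_all[sel] // scheme.bin_size
        nb = scheme.nbins[chrom]
        ok = idx < nb
        dropped += int((~ok).sum())
        c = np.bincount(idx[ok], minlength=nb)
        counts[offsets[chrom] : offsets[chrom] + nb] += c
    table["raw_count"] = counts
    table.attrs["n_dropped"] = dropped
    table.attrs["n_assigned"] = int(len(frags) - dropped)
    return table


def remove_repeat_fragments(
    frags: pd.DataFrame, repeats: RepeatAnnotation, mode: str = "end"
) -> pd.DataFrame:
    """Discard fragments hitting repeat-annotated intervals.

    ``mode='end'`` (default) discards a fragment iff its 5' end lies inside a
    repeat interval, consistent with 5'-based bin counting; ``mode='overlap'``
    discards on any overlap of [start, end).
    """
    if mode not in {"end", "overlap"}:
        raise ValueError("mode must be 'end' or 'overlap'")
    keep = np.ones(len(frags), dtype=bool)
    chrom_arr = frags["chrom"].to_numpy()
    if mode == "end":
        pos = five_prime(frags)
        for chrom in pd.unique(chrom_arr):
            sel = chrom_arr == chrom
            keep[sel] = ~repeats.contains(chrom, pos[sel])
    else:
        starts = frags["start"].to_numpy()
        ends = frags["end"].to_numpy()
        for chrom in pd.unique(chrom_arr):
            sel = np.flatnonzero(chrom_arr == chrom)
            ivals = repeats.intervals.get(chrom)
            if ivals is None or ivals.size == 0:
                continue
            s, e = starts[sel], ends[sel]
            # overlap iff some interval has iv_start < end and iv_end > start
            idx = np.searchsorted(ivals[:, 0], e, side="left") - 1
            hit = idx >= 0
            hit[hit] &= ivals[idx[hit], 1] > s[hit]
            keep[sel] = ~hit
    out = frags[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int(len(frags) - len(out))
    return out


def mappability_correct(
    bins: pd.DataFrame,
    cutoff: float = 0.5,
    count_col: str = "raw_count",
    out_col: str = "map_corrected",
) -> pd.DataFrame:
    """Divide bin counts by their mappability; filter low-mappability bins.

    Bins with mappability below ``cutoff`` (default 0.5, i.e. fewer than half
    of start positions unique) are invalidated to prevent over-correction.
    """
    if bins["mappability"].isna().any():
        raise ValueError("bin mappability is missing; compute or import a track first")
    out = bins.copy()
    m = out["mappability"].to_numpy(dtype=float)
    low = m < cutoff
    out.loc[low, "valid"] = False
    vals = np.full(len(out), np.nan)
    ok = ~low
    vals[ok] = out.loc[ok, count_col].to_numpy(dtype=float) / m[ok]
    out[out_col] = vals
    return out


def subsample_fragments(frags: pd.DataFrame, proportion: float, seed: int) -> pd.DataFrame:
    """Draw round(proportion * N) fragments uniformly without replacement."""
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    n = int(np.rint(proportion * len(frags)))
    if n == len(frags):
        return frags.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(frags), size=n, replace=False))
    return frags.iloc[idx].reset_index(drop=True)
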