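"""Fixed-width genomic bin schemes and the tabular bin container.

A BinTable is a plain pandas DataFrame with columns
``chrom, start, end, raw_count, gc, mappability, valid`` plus zero or more
``corrected*`` columns added by the correction protocols.  Only full-width
bins are kept: each chromosome is tiled from 0 and any trailing partial bin
is dropped, so counts are comparable across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .reference import GenomeSequence, MappabilityTrack, is_chry

BIN_COLUMNS = ["chrom", "start", "end", "raw_count", "gc", "mappability", "valid"]


@dataclass(frozen=True)
class BinScheme:
    """Non-overlapping full-width bins of ``bin_size`` bp tiling each chromosome prefix."""

    bin_size: int
    nbins: Mapping[str, int] = field(default_factory=dict)

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int], bin_size: int = 50_000) -> "BinScheme":
        if bin_size < 1:
            raise ValueError("bin_size must be positive")
        return cls(bin_size=bin_size, nbins={c: L // bin_size for c, L in lengths.items()})

    @classmethod
    def from_genome(cls, genome: GenomeSequence, bin_size: int = 50_000) -> "BinScheme":
        return cls.from_lengths(genome.lengths, bin_size)

    @property
    def total_bins(self) -> int:
        return int(sum(self.nbins.values()))

    def row_offsets(self) -> dict[str, int]:
        offsets, row = {}, 0
        for chrom, nb in self.nbins.items():
            offsets[chrom] = row
            row += nb
        return offsets

    def skeleton(self) -> pd.DataFrame:
        chroms, starts = [], []
        for chrom, nb in self.nbins.items():
            chroms.extend([chrom] * nb)
            starts.extend(range(0, nb * self.bin_size, self.bin_size))
        starts = np.asarray(starts, dtype=np.int64)
        return pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + self.bin_size}
        )


def scheme_from_table(bins: pd.DataFrame) -> BinScheme:
    """Recover the BinScheme of a BinTable (full-width bins tiling from 0)."""
    widths = (bins["end"] - bins["start"]).unique()
    if len(widths) != 1:
        raise ValueError("bin table does not have a single bin width")
    nbins = {
        str(chrom): int(len(grp))
        for chrom, grp in bins.groupby("chrom", sort=False)
    }
    return BinScheme(bin_size=int(widths[0]), nbins=nbins)


def make_bin_table(
    genome: GenomeSequence,
    scheme: BinScheme,
    track: MappabilityTrack | None = None,
    max_n_fraction: float = 0.1,
) -> pd.DataFrame:
    """Bin skeleton annotated with GC, mappability and validity flags.

    Bins whose N fraction exceeds ``max_n_fraction`` are flagged invalid, and
    chrY bins are flagged out of the analysis.
    """
    table = scheme.skeleton()
    gc, gc_ok = reference.window_gc(genome, scheme, max_n_fraction=max_n_fraction)
    table["raw_count"] = 0
    table["gc"] = gc
    if track is not None:
        table["mappability"] = reference.window_mappability(track, scheme)
    else:
        table["mappability"] = np.nan
    chry = table["chrom"].map(is_chry).to_numpy()
    table["valid"] = gc_ok & ~chry
    return table


def write_bin_table(bins: pd.DataFrame, path: str | Path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        bins.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_bin_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    df["valid"] = df["valid"].astype(bool)
    return df
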