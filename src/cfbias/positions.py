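"""Shared machinery for sampling uniquely mappable positions, strand-specifically.

The single-position GC model, the TV-score window scan and the positional
fragmentation analyses all operate on the same object: a random sample of
(chromosome, position, strand) triples drawn from the uniquely mappable
positions of the genome, together with the number of fragment 5' ends
observed at each sampled position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import COMPLEMENT, GenomeSequence, MappabilityTrack


@dataclass
class PositionSample:
    """A strand-specific sample of uniquely mappable positions.

    ``chrom_id`` indexes into ``chrom_names``; ``pos`` is the 5'-end
    coordinate of a read starting there; ``is_reverse`` marks reverse-strand
    positions (the read extends leftward from ``pos``).  ``F`` holds fragment
    5'-end counts at each sampled position once attached.
    """

    chrom_names: list[str]
    chrom_id: np.ndarray
    pos: np.ndarray
    is_reverse: np.ndarray
    seed: int | None = None
    F: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.pos.size)


def sample_unique_positions(
    genome: GenomeSequence,
    track: MappabilityTrack,
    sample_size: int | None,
    seed: int = 0,
    position_mask=None,
) -> PositionSample:
    """Sample uniformly (without replacement) from uniquely mappable positions.

    Both strands enter the universe: a forward position x is eligible when
    the k-mer at x is unique, a reverse 5'-end position x when the k-mer at
    x - k + 1 is unique.  ``position_mask(chrom, is_reverse)`` may return a
    boolean array over 5'-end coordinates to restrict the universe (used for
    motif-stratified fits).  ``sample_size=None`` keeps the whole universe.
    """
    names = genome.names
    chunks_chrom, chunks_pos, chunks_rev = [], [], []
    for ci, chrom in enumerate(names):
        L = genome.lengths[chrom]
        for is_rev in (False, True):
            flags = (
                track.reverse_unique(chrom, L) if is_rev else track.forward_unique(chrom, L)
            )
            if position_mask is not None:
                flags = flags & position_mask(chrom, is_rev)
            idx = np.flatnonzero(flags)
            if idx.size == 0:
                continue
            chunks_chrom.append(np.full(idx.size, ci, dtype=np.int32))
            chunks_pos.append(idx.astype(np.int64))
            chunks_rev.append(np.full(idx.size, is_rev, dtype=bool))
    if not chunks_pos:
        raise ValueError("no uniquely mappable positions available to sample")
    chrom_id = np.concatenate(chunks_chrom)
    pos = np.concatenate(chunks_pos)
    is_rev = np.concatenate(chunks_rev)
    n_total = pos.size
    if sample_size is not None and sample_size < n_total:
        rng = np.random.default_rng(seed)
        take = np.sort(rng.choice(n_total, size=int(sample_size), replace=False))
        chrom_id, pos, is_rev = chrom_id[take], pos[take], is_rev[take]
    return PositionSample(
        chrom_names=list(names), chrom_id=chrom_id, pos=pos, is_reverse=is_rev, seed=seed
    )


def attach_fragment_counts(sample: PositionSample, frags: pd.DataFrame) -> None:
    """Count fragment 5' ends at each sampled (position, strand) in place."""
    from .fragments import five_prime

    F = np.zeros(sample.size, dtype=np.int64)
    pos5 = five_prime(frags)
    chrom_arr = frags["chrom"].to_numpy()
    strand_rev = frags["strand"].to_numpy() == "-"
    name_to_id = {c: i for i, c in enumerate(sample.chrom_names)}
    for chrom in pd.unique(chrom_arr):
        if chrom not in name_to_id:
            continue
        ci = name_to_id[chrom]
        in_chrom = chrom_arr == chrom
        for is_rev in (False, True):
            sel = in_chrom & (strand_rev == is_rev)
            if not sel.any():
                continue
            p = pos5[sel]
            smask = (sample.chrom_id == ci) & (sample.is_reverse == is_rev)
            if not smask.any():
                continue
            counts = np.bincount(p, minlength=int(p.max()) + 1)
            spos = sample.pos[smask]
            vals = np.zeros(spos.size, dtype=np.int64)
            inb = spos < counts.size
            vals[inb] = counts[spos[inb]]
            F[smask] = vals
    sample.F = F


def window_gc_at(
    sample: PositionSample, genome: GenomeSequence, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """GC count of the strand-oriented window of ``length`` bp at each position.

    Forward positions use [x, x+length); reverse positions use the window
    ending at x, [x-length+1, x+1) (its GC equals that of the reverse
    complement read off the reverse strand).  Returns (gc_counts, valid) where
    windows running off the chromosome or containing N are invalid.
    """
    gc = np.zeros(sample.size, dtype=np.int64)
    ok = np.zeros(sample.size, dtype=bool)
    for ci, chrom in enumerate(sample.chrom_names):
        L = genome.lengths[chrom]
        gccum = genome.gc_cumsum(chrom)
        ncum = genome.n_cumsum(chrom)
        for is_rev in (False, True):
            sel = np.flatnonzero((sample.chrom_id == ci) & (sample.is_reverse == is_rev))
            if sel.size == 0:
                continue
            p = sample.pos[sel]
            if is_rev:
                lo = p - length + 1
                hi = p + 1
                inb = lo >= 0
            else:
                lo = p
                hi = p + length
                inb = hi <= L
            lo_c = np.clip(lo, 0, L)
            hi_c = np.clip(hi, 0, L)
            g = gccum[hi_c] - gccum[lo_c]
            nn = ncum[hi_c] - ncum[lo_c]
            good = inb & (nn == 0)
            gc[sel[good]] = g[good]
            ok[sel] = good
    return gc, ok


def base_codes_at(
    sample: PositionSample, genome: GenomeSequence, offset: int
) -> np.ndarray:
    """Reference base code at a strand-oriented offset from each position.

    Offset o maps to coordinate pos + o on the forward strand and to the
    complement of the base at pos - o on the reverse strand, so that offset 0
    is the first read base on either strand.  Out-of-bounds or N -> 255.
    """
    out = np.full(sample.size, 255, dtype=np.uint8)
    for ci, chrom in enumerate(sample.chrom_names):
        codes = genome.codes(chrom)
        L = codes.size
        for is_rev in (False, True):
            sel = np.flatnonzero((sample.chrom_id == ci) & (sample.is_reverse == is_rev))
            if sel.size == 0:
                continue
            coord = sample.pos[sel] + (-offset if is_rev else offset)
            inb = (coord >= 0) & (coord < L)
            vals = np.full(sel.size, 255, dtype=np.uint8)
            c = codes[coord[inb]]
            if is_rev:
                c = COMPLEMENT[c]
            vals[inb] = c
            vals[vals == 4] = 255
            out[sel] = vals
    return out
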