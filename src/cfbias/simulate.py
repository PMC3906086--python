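"""Synthetic plasma-cfDNA generator with known GC, motif and ploidy truth.

The generator emulates the data model behind maternal-plasma sequencing at
desk scale: a toy genome with blockwise GC heterogeneity and optional
duplicated (non-unique) segments; fragments whose per-(position, strand)
sampling weight is

    rate(GC of the window of length l starting at the position, strand-
    oriented) x motif weight of the breakpoint 3-mer x copy factor,

where the copy factor is (1-f)*2 + f*(3 if the chromosome is the trisomic
target else 2) against a disomic baseline of 2; fragment lengths follow the
nucleosomal mixture (modes near 166 bp and 340 bp).  When a mappability track
is supplied, fragments whose 5' read would not map uniquely are never emitted,
emulating the upstream multi-mapper removal applied to real aligned data.

The rate curve is a scaled Beta density over GC fraction, unimodal like the
empirically observed coverage bias (maximal near 40-50% GC); its parameters
are ground truth against which model recovery is tested.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import make_fragments
from .reference import GenomeSequence, MappabilityTrack, RepeatAnnotation


@dataclass(frozen=True)
class Duplication:
    """Copy [start, end) of ``chrom`` verbatim to ``dest_start`` of ``dest_chrom``."""

    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_start: int


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic plasma-DNA experiment."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000, "chr21": 1_000_000}
    )
    block_length: int = 5_000
    gc_range: tuple[float, float] = (0.30, 0.60)
    duplications: list[Duplication] = field(default_factory=list)
    n_fragments: int = 500_000
    gc_peak: float = 0.45  # GC fraction of maximal fragment rate
    gc_concentration: float = 30.0  # sharpness of the Beta-shaped rate curve
    window_length: int = 166  # true GC window (l_true)
    motif_weights: dict[str, float] | None = None  # 64 breakpoint 3-mers; None = flat
    length_means: tuple[float, float] = (166.0, 340.0)
    length_sds: tuple[float, float] = (20.0, 30.0)
    length_weights: tuple[float, float] = (0.85, 0.15)
    min_length: int = 50
    fetal_short_lengths: bool = False  # draw fetal fragment lengths from N(143, 15)
    fetal_length_mean: float = 143.0
    fetal_length_sd: float = 15.0
    fetal_fraction: float = 0.0
    trisomy_chrom: str | None = None
    repeat_fraction: float = 0.0  # genome share covered by annotated 'repeat' intervals
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fetal_fraction < 1:
            raise ValueError("fetal_fraction must be in [0, 1)")
        if abs(sum(self.length_weights) - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")
        if self.motif_weights is not None and any(
            w <= 0 for w in self.motif_weights.values()
        ):
            raise ValueError("motif weights must be positive")


def gc_rate_curve(config: SimulationConfig, gc_fraction) -> np.ndarray:
    """The true fragment-rate curve: a scaled Beta density with mode at gc_peak."""
    a = 1.0 + config.gc_peak * config.gc_concentration
    b = 1.0 + (1.0 - config.gc_peak) * config.gc_concentration
    return stats.beta.pdf(np.asarray(gc_fraction, dtype=float), a, b)


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """Blockwise-GC random genome with optional verbatim duplicated segments."""
    rng = np.random.default_rng([config.seed, 0])
    chroms: dict[str, np.ndarray] = {}
    lo, hi = config.gc_range
    for name, L in config.chrom_lengths.items():
        nblocks = -(-L // config.block_length)
        p_block = rng.uniform(lo, hi, size=nblocks)
        p = np.repeat(p_block, config.block_length)[:L]
        is_gc = rng.random(L) < p
        pick = rng.integers(0, 2, size=L)
        codes = np.where(is_gc, np.where(pick == 0, 1, 2), np.where(pick == 0, 0, 3))
        chroms[name] = codes.astype(np.uint8)
    for dup in config.duplications:
        src = chroms.get(dup.chrom)
        dst = chroms.get(dup.dest_chrom)
        if src is None or dst is None:
            raise ValueError(f"duplication references unknown chromosome: {dup}")
        n = dup.end - dup.start
        if not (0 <= dup.start < dup.end <= src.size) or dup.dest_start + n > dst.size:
            raise ValueError(f"duplicated segment out of bounds: {dup}")
        segment = src[dup.start : dup.end].copy()
        dst[dup.dest_start : dup.dest_start + n] = segment
    return GenomeSequence(chroms)


def duplication_intervals(config: SimulationConfig) -> dict[str, list[tuple[int, int]]]:
    """Both copies of every duplicated segment, as repeat-like intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    for dup in config.duplications:
        out.setdefault(dup.chrom, []).append((dup.start, dup.end))
        out.setdefault(dup.dest_chrom, []).append(
            (dup.dest_start, dup.dest_start + (dup.end - dup.start))
        )
    return out


def simulate_repeats(config: SimulationConfig) -> RepeatAnnotation:
    """Scattered annotated intervals covering ~repeat_fraction of each chromosome.

    Mirrors the character of curated repeat databases: the annotation is much
    broader than the truly non-unique sequence, so hard-filtering reads in
    these intervals removes uniquely mapping data.  Duplicated segments are
    always included.
    """
    rng = np.random.default_rng([config.seed, 1])
    raw = {c: list(v) for c, v in duplication_intervals(config).items()}
    if config.repeat_fraction > 0:
        for chrom, L in config.chrom_lengths.items():
            target = config.repeat_fraction * L
            covered = 0.0
            ivals = raw.setdefault(chrom, [])
            while covered < target:
                length = int(rng.uniform(5_000, 50_000))
                start = int(rng.integers(0, max(L - length, 1)))
                ivals.append((start, start + length))
                covered += length
    return RepeatAnnotation.from_intervals(raw)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated fragment set."""

    fetal_fraction: float
    trisomy_chrom: str | None
    n_fragments: int
    seed: int
    window_length: int
    gc_peak: float
    gc_concentration: float
    expected_representation: float  # 1 + f/2 for the trisomic target, else 1
    expected_share_euploid: dict[str, float]
    expected_share: dict[str, float]
    realized_counts: dict[str, int]
    expected_motif_distribution: dict[str, float] | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class FragmentSampler:
    """Reusable fragment sampler: weights are built once per (genome, config).

    Sampling many cohort members from one genome only repeats the cheap
    multinomial draw, not the per-position weight construction.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        config: SimulationConfig,
        mappability: MappabilityTrack | None = None,
    ):
        from .fragmentation import all_motifs, position_motif_indices

        self.genome = genome
        self.config = config
        self.chrom_names = genome.names
        self._weights: list[np.ndarray] = []  # (chrom, strand) blocks, float32
        self._block_meta: list[tuple[str, bool]] = []
        motif_mass = np.zeros(65)  # 64 motifs + undetermined
        l = config.window_length
        if config.motif_weights is not None:
            lut = np.zeros(64)
            for i, name in enumerate(all_motifs()):
                lut[i] = config.motif_weights.get(name, 1.0)
            undetermined_factor = 0.0
        else:
            lut = np.ones(64)
            undetermined_factor = 1.0
        for chrom in self.chrom_names:
            L = genome.lengths[chrom]
            gccum = genome.gc_cumsum(chrom)
            ncum = genome.n_cumsum(chrom)
            nwin = L - l + 1
            if nwin <= 0:
                raise ValueError(f"chromosome {chrom!r} shorter than the GC window")
            g = (gccum[l:] - gccum[:-l]) / float(l)
            clean = (ncum[l:] - ncum[:-l]) == 0
            rate = gc_rate_curve(config, g)
            rate[~clean] = 0.0
            for is_rev in (False, True):
                w = np.zeros(L)
                if is_rev:
                    w[l - 1 :] = rate  # window ends at the 5' position
                else:
                    w[:nwin] = rate
                midx = position_motif_indices(genome, chrom, is_rev)
                factor = np.where(midx >= 0, lut[np.clip(midx, 0, 63)], undetermined_factor)
                w *= factor
                if mappability is not None:
                    u = (
                        mappability.reverse_unique(chrom, L)
                        if is_rev
                        else mappability.forward_unique(chrom, L)
                    )
                    w[~u] = 0.0
                motif_mass += np.bincount(
                    np.where(midx >= 0, midx, 64), weights=w, minlength=65
                )
                self._weights.append(w.astype(np.float32))
                self._block_meta.append((chrom, is_rev))
        self._block_sums = np.array([float(w.sum()) for w in self._weights])
        if self._block_sums.sum() <= 0:
            raise ValueError("all sampling weights are zero")
        total = motif_mass.sum()
        self.expected_motif_distribution = {
            name: float(motif_mass[i] / total) for i, name in enumerate(all_motifs())
        }

    def _chrom_weight_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {c: 0.0 for c in self.chrom_names}
        for (chrom, _), s in zip(self._block_meta, self._block_sums):
            sums[chrom] += float(s)
        return sums

    def expected_shares(
        self, fetal_fraction: float = 0.0, trisomy_chrom: str | None = None
    ) -> dict[str, float]:
        sums = self._chrom_weight_sums()
        cf = {
            c: ((1 - fetal_fraction) * 2 + fetal_fraction * (3 if c == trisomy_chrom else 2))
            / 2.0
            for c in sums
        }
        mass = {c: sums[c] * cf[c] for c in sums}
        total = sum(mass.values())
        return {c: v / total for c, v in mass.items()}

    def sample(
        self,
        n_fragments: int | None = None,
        fetal_fraction: float | None = None,
        trisomy_chrom: str | None = None,
        seed: int | None = None,
    ) -> tuple[pd.DataFrame, SimulationTruth]:
        cfg = self.config
        n = cfg.n_fragments if n_fragments is None else int(n_fragments)
        f = cfg.fetal_fraction if fetal_fraction is None else float(fetal_fraction)
        tri = cfg.trisomy_chrom if trisomy_chrom is None else trisomy_chrom
        if tri is not None and tri not in self.chrom_names:
            raise ValueError(f"trisomy chromosome {tri!r} not in the genome")
        seed = cfg.seed if seed is None else int(seed)
        rng = np.random.default_rng([seed, 2])

        copy_factor = np.array(
            [
                ((1 - f) * 2 + f * (3 if chrom == tri else 2)) / 2.0
                for chrom, _ in self._block_meta
            ]
        )
        block_mass = self._block_sums * copy_factor
        block_counts = rng.multinomial(n, block_mass / block_mass.sum())

        chroms_out, pos_out, rev_out = [], [], []
        for (chrom, is_rev), w, nb in zip(self._block_meta, self._weights, block_counts):
            if nb == 0:
                continue
            p = w.astype(np.float64)
            counts = rng.multinomial(int(nb), p / p.sum())
            nz = np.flatnonzero(counts)
            positions = np.repeat(nz, counts[nz])
            chroms_out.append(np.full(positions.size, chrom, dtype=object))
            pos_out.append(positions.astype(np.int64))
            rev_out.append(np.full(positions.size, is_rev, dtype=bool))
        chrom_arr = np.concatenate(chroms_out)
        pos5 = np.concatenate(pos_out)
        is_rev = np.concatenate(rev_out)

        # fetal origin per fragment (affects only the length model)
        p_fetal = {
            c: (f * (3 if c == tri else 2))
            / ((1 - f) * 2 + f * (3 if c == tri else 2))
            for c in self.chrom_names
        }
        fetal = rng.random(pos5.size) < np.array([p_fetal[c] for c in chrom_arr])
        comp = rng.choice(2, size=pos5.size, p=list(cfg.length_weights))
        means = np.where(comp == 0, cfg.length_means[0], cfg.length_means[1])
        sds = np.where(comp == 0, cfg.length_sds[0], cfg.length_sds[1])
        if cfg.fetal_short_lengths:
            means = np.where(fetal, cfg.fetal_length_mean, means)
            sds = np.where(fetal, cfg.fetal_length_sd, sds)
        lengths = np.rint(rng.normal(means, sds)).astype(np.int64)
        lengths = np.maximum(lengths, cfg.min_length)

        L_arr = np.array([self.genome.lengths[c] for c in chrom_arr])
        start = np.where(is_rev, pos5 - lengths + 1, pos5)
        end = np.where(is_rev, pos5 + 1, pos5 + lengths)
        start = np.maximum(start, 0)
        end = np.minimum(end, L_arr)
        frags = make_fragments(
            chrom_arr,
            start,
            end,
            np.where(is_rev, "-", "+"),
            np.full(pos5.size, 70, dtype=np.int64),
        )
        order = np.lexsort((frags["start"].to_numpy(), frags["chrom"].to_numpy().astype(str)))
        frags = frags.iloc[order].reset_index(drop=True)

        realized = frags["chrom"].value_counts().to_dict()
        truth = SimulationTruth(
            fetal_fraction=f,
            trisomy_chrom=tri,
            n_fragments=n,
            seed=seed,
            window_length=cfg.window_length,
            gc_peak=cfg.gc_peak,
            gc_concentration=cfg.gc_concentration,
            expected_representation=1.0 + f / 2.0 if tri is not None else 1.0,
            expected_share_euploid=self.expected_shares(0.0, None),
            expected_share=self.expected_shares(f, tri),
            realized_counts={c: int(realized.get(c, 0)) for c in self.chrom_names},
            expected_motif_distribution=self.expected_motif_distribution,
        )
        return frags, truth


def simulate_fragments(
    genome: GenomeSequence,
    config: SimulationConfig,
    mappability: MappabilityTrack | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """One-shot fragment simulation; see FragmentSampler for cohort reuse."""
    return FragmentSampler(genome, config, mappability).sample(seed=seed)
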