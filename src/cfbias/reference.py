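"""Reference-genome handling: sequence loading, k-mer mappability and windowed tracks.

The mappability model used throughout the package defines a genomic start
position as *uniquely mappable* when the length-``k`` sequence beginning there
occurs exactly once in the whole genome, counting occurrences on both strands
(a k-mer and its reverse complement are hits of the same read).  This is an
exact-match definition: it is deterministic and aligner-free.  Externally
computed tracks (e.g. derived from an aligner) can be imported from bedGraph
instead, preserving whatever definition produced them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Base codes: A=0, C=1, G=2, T=3, N=4.  IUPAC ambiguity codes fold to N.
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i
for _b in "Nn":
    _CODES[ord(_b)] = 4
for _b in "RYSWKMBDHVU":
    _CODES[ord(_b)] = 5
    _CODES[ord(_b.lower())] = 5

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_CHRY_NAMES = frozenset({"chrY", "Y", "chry", "y"})


def is_chry(name: str) -> bool:
    """True for names conventionally denoting the Y chromosome."""
    return name in _CHRY_NAMES


def encode_sequence(seq: str) -> tuple[np.ndarray, int]:
    """Encode a nucleotide string to base codes (A=0,C=1,G=2,T=3,N=4).

    Returns the code array and the number of IUPAC-ambiguous characters that
    were folded to N.  Characters that are not IUPAC nucleotide codes raise.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODES[raw].copy()
    if (codes == 255).any():
        bad = {chr(c) for c in raw[codes == 255][:10]}
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n_ambig = int((codes == 5).sum())
    if n_ambig:
        codes[codes == 5] = 4
    return codes, n_ambig


class GenomeSequence:
    """An in-memory genome over {A,C,G,T,N}, one code array per chromosome.

    Cumulative GC and N tracks are computed lazily and cached; they are the
    workhorse for every windowed GC computation in the package.
    """

    def __init__(self, chroms: dict[str, np.ndarray]):
        if not chroms:
            raise ValueError("genome has no chromosomes")
        for name, codes in chroms.items():
            if codes.size == 0:
                raise ValueError(f"chromosome {name!r} has length 0")
            if codes.dtype != np.uint8 or codes.max() > 4:
                raise ValueError(f"chromosome {name!r}: invalid base codes")
        self._chroms = dict(chroms)
        self._gc_cum: dict[str, np.ndarray] = {}
        self._n_cum: dict[str, np.ndarray] = {}

    @classmethod
    def from_strings(cls, mapping: dict[str, str]) -> "GenomeSequence":
        chroms = {}
        for name, seq in mapping.items():
            codes, n_ambig = encode_sequence(seq)
            if n_ambig:
                logger.warning(
                    "chromosome %s: %d ambiguous bases converted to N", name, n_ambig
                )
            chroms[name] = codes
        return cls(chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: codes.size for name, codes in self._chroms.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def codes(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]

    def sequence(self, chrom: str) -> str:
        return _BASES[self._chroms[chrom]].tobytes().decode("ascii")

    def gc_cumsum(self, chrom: str) -> np.ndarray:
        """Cumulative count of G/C bases; gc of [a, b) = cum[b] - cum[a]."""
        if chrom not in self._gc_cum:
            codes = self._chroms[chrom]
            is_gc = (codes == 1) | (codes == 2)
            cum = np.zeros(codes.size + 1, dtype=np.int64)
            np.cumsum(is_gc, out=cum[1:])
            self._gc_cum[chrom] = cum
        return self._gc_cum[chrom]

    def n_cumsum(self, chrom: str) -> np.ndarray:
        """Cumulative count of N bases; Ns in [a, b) = cum[b] - cum[a]."""
        if chrom not in self._n_cum:
            codes = self._chroms[chrom]
            cum = np.zeros(codes.size + 1, dtype=np.int64)
            np.cumsum(codes == 4, out=cum[1:])
            self._n_cum[chrom] = cum
        return self._n_cum[chrom]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n")
                seq = self.sequence(name)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a GenomeSequence.

    Sequences are upper-cased; IUPAC ambiguity codes other than N are folded
    to N with a logged count.  Duplicate headers and empty files are errors.
    """
    chroms: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise ValueError(f"duplicate FASTA header: {record.id!r}")
        codes, n_ambig = encode_sequence(str(record.seq))
        if n_ambig:
            logger.warning(
                "%s: chromosome %s: %d ambiguous bases converted to N",
                path,
                record.id,
                n_ambig,
            )
        chroms[record.id] = codes
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chroms)


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------


@dataclass
class MappabilityTrack:
    """Per-position read-start uniqueness at read length ``k``.

    ``unique[chrom][x]`` is defined for 0 <= x <= L - k and is True when the
    k-mer starting at x occurs exactly once in the genome over both strands.
    """

    k: int
    unique: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = "computed"

    def forward_unique(self, chrom: str, length: int) -> np.ndarray:
        """Boolean over all positions 0..length-1 (starts past L-k are False)."""
        out = np.zeros(length, dtype=bool)
        arr = self.unique.get(chrom)
        if arr is not None and arr.size:
            out[: arr.size] = arr
        return out

    def reverse_unique(self, chrom: str, length: int) -> np.ndarray:
        """Uniqueness indexed by the 5' end of a reverse-strand read.

        A reverse-strand read whose 5' end is at x covers [x-k+1, x]; it maps
        uniquely iff the forward k-mer at x-k+1 is unique (both-strand
        counting is strand-symmetric).
        """
        out = np.zeros(length, dtype=bool)
        arr = self.unique.get(chrom)
        if arr is not None and arr.size:
            out[self.k - 1 : self.k - 1 + arr.size] = arr
        return out

    def n_unique(self) -> int:
        return int(sum(int(a.sum()) for a in self.unique.values()))

    def n_positions(self) -> int:
        return int(sum(a.size for a in self.unique.values()))

    def to_bedgraph(self, path: str | Path) -> None:
        """Write the per-position 0/1 track as run-length bedGraph intervals."""
        with open(path, "w") as fh:
            fh.write(f"# cfbias mappability track k={self.k} provenance={self.provenance}\n")
            for chrom, arr in self.unique.items():
                if arr.size == 0:
                    continue
                vals = arr.astype(np.int8)
                change = np.flatnonzero(np.diff(vals)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(vals[s])}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, k: int, lengths: dict[str, int]
    ) -> "MappabilityTrack":
        """Import a track; value > 0.5 marks a position unique.

        The file must cover every start position 0..L-k of every chromosome
        in ``lengths``.
        """
        unique = {c: np.zeros(max(L - k + 1, 0), dtype=bool) for c, L in lengths.items()}
        covered = {c: np.zeros(max(L - k + 1, 0), dtype=bool) for c, L in lengths.items()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in unique:
                    continue
                arr = unique[chrom]
                s2, e2 = max(s, 0), min(e, arr.size)
                if e2 > s2:
                    arr[s2:e2] = v > 0.5
                    covered[chrom][s2:e2] = True
        for chrom, cov in covered.items():
            if cov.size and not cov.all():
                raise ValueError(
                    f"imported mappability does not cover all start positions of {chrom}"
                )
        return cls(k=k, unique=unique, provenance="imported")


def _pack_kmers(codes_u64: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer into (hi, lo) uint64 pairs, 2 bits per base, k <= 64."""
    n = codes_u64.size - k + 1
    hi = np.zeros(n, dtype=np.uint64)
    lo = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    k1 = max(k - 32, 0)
    for i in range(k1):
        hi *= four
        hi += codes_u64[i : i + n]
    for i in range(k1, k):
        lo *= four
        lo += codes_u64[i : i + n]
    return hi, lo


def compute_unique_positions(genome: GenomeSequence, k: int = 50) -> MappabilityTrack:
    """Flag every start position whose k-mer is unique over both strands.

    A k-mer containing N is never unique and does not count as an occurrence
    of any other k-mer.  A reverse-palindromic k-mer occurs on both strands at
    its own locus and is therefore never unique.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 64:
        raise ValueError("k > 64 is not supported by the exact k-mer packer")
    lengths = genome.lengths
    if k > max(lengths.values()):
        raise ValueError(f"k={k} exceeds the length of every chromosome")

    chrom_names: list[str] = []
    chrom_sizes: list[int] = []
    his, los, valids, pals = [], [], [], []
    for chrom in genome.names:
        L = lengths[chrom]
        n = L - k + 1
        chrom_names.append(chrom)
        chrom_sizes.append(max(n, 0))
        if n <= 0:
            continue
        codes = genome.codes(chrom)
        ncum = genome.n_cumsum(chrom)
        valid = (ncum[k:] - ncum[:-k]) == 0
        c = np.where(codes == 4, 0, codes).astype(np.uint64)
        hi, lo = _pack_kmers(c, k)
        rc_codes = COMPLEMENT[codes][::-1]
        rc = np.where(rc_codes == 4, 0, rc_codes).astype(np.uint64)
        rhi_seq, rlo_seq = _pack_kmers(rc, k)
        # reverse complement of the k-mer at x = k-mer of the rc sequence at n-1-x
        rhi = rhi_seq[::-1].copy()
        rlo = rlo_seq[::-1].copy()
        pal = (hi == rhi) & (lo == rlo)
        take_rc = (rhi < hi) | ((rhi == hi) & (rlo < lo))
        his.append(np.where(take_rc, rhi, hi))
        los.append(np.where(take_rc, rlo, lo))
        valids.append(valid)
        pals.append(pal)

    hi_all = np.concatenate(his) if his else np.empty(0, dtype=np.uint64)
    lo_all = np.concatenate(los) if los else np.empty(0, dtype=np.uint64)
    valid_all = np.concatenate(valids) if valids else np.empty(0, dtype=bool)
    pal_all = np.concatenate(pals) if pals else np.empty(0, dtype=bool)

    unique_all = np.zeros(hi_all.size, dtype=bool)
    vidx = np.flatnonzero(valid_all)
    if vidx.size:
        hv, lv = hi_all[vidx], lo_all[vidx]
        order = np.lexsort((lv, hv))
        hs, ls = hv[order], lv[order]
        new_group = np.empty(hs.size, dtype=bool)
        new_group[0] = True
        new_group[1:] = (hs[1:] != hs[:-1]) | (ls[1:] != ls[:-1])
        gid = np.cumsum(new_group) - 1
        counts = np.bincount(gid)
        uniq_sorted = counts[gid] == 1
        uniq_v = np.empty(hs.size, dtype=bool)
        uniq_v[order] = uniq_sorted
        unique_all[vidx] = uniq_v
    unique_all &= ~pal_all

    track: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, size in zip(chrom_names, chrom_sizes):
        track[chrom] = unique_all[offset : offset + size].copy()
        offset += size
    return MappabilityTrack(k=k, unique=track, provenance="computed")


def window_mappability(track: MappabilityTrack, scheme) -> np.ndarray:
    """Per-bin fraction of uniquely mapping start positions.

    The denominator is the number of valid start positions in the bin, i.e.
    positions x with x <= L - k.  Bins that contain no valid start (possible
    only in a trailing bin when k > 1) get 0.
    """
    values = np.empty(scheme.total_bins, dtype=float)
    row = 0
    for chrom, nb in scheme.nbins.items():
        if nb == 0:
            continue
        if chrom not in track.unique:
            raise ValueError(f"mappability track does not cover chromosome {chrom!r}")
        arr = track.unique[chrom]
        cum = np.zeros(arr.size + 1, dtype=np.int64)
        np.cumsum(arr, out=cum[1:])
        B = scheme.bin_size
        for i in range(nb):
            s = i * B
            e = min((i + 1) * B, arr.size)
            n_valid = max(e - s, 0)
            values[row] = (cum[e] - cum[s]) / n_valid if n_valid > 0 else 0.0
            row += 1
    return values


def window_gc(
    genome: GenomeSequence, scheme, max_n_fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin GC fraction (over A/C/G/T) and an N-content validity flag."""
    gc = np.empty(scheme.total_bins, dtype=float)
    ok = np.ones(scheme.total_bins, dtype=bool)
    row = 0
    for chrom, nb in scheme.nbins.items():
        if nb == 0:
            continue
        if chrom not in genome:
            raise ValueError(f"bin scheme references unknown chromosome {chrom!r}")
        B = scheme.bin_size
        if nb * B > genome.lengths[chrom]:
            raise ValueError(f"bin beyond end of chromosome {chrom!r}")
        gccum = genome.gc_cumsum(chrom)
        ncum = genome.n_cumsum(chrom)
        edges = np.arange(nb + 1, dtype=np.int64) * B
        n_in_bin = ncum[edges[1:]] - ncum[edges[:-1]]
        gc_in_bin = gccum[edges[1:]] - gccum[edges[:-1]]
        denom = B - n_in_bin
        with np.errstate(invalid="ignore"):
            vals = gc_in_bin / denom
        bad = denom == 0
        vals[bad] = np.nan
        gc[row : row + nb] = vals
        ok[row : row + nb] = ~bad & (n_in_bin / B <= max_n_fraction)
        row += nb
    return gc, ok


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------


@dataclass
class RepeatAnnotation:
    """Per-chromosome sorted, merged 0-based half-open intervals."""

    intervals: dict[str, np.ndarray]  # (m, 2) int64 arrays

    @classmethod
    def from_intervals(cls, raw: dict[str, list[tuple[int, int]]]) -> "RepeatAnnotation":
        merged: dict[str, np.ndarray] = {}
        for chrom, ivals in raw.items():
            merged[chrom] = merge_intervals(ivals)
        return cls(intervals=merged)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Membership of each position in any interval (half-open)."""
        ivals = self.intervals.get(chrom)
        out = np.zeros(len(positions), dtype=bool)
        if ivals is None or ivals.size == 0:
            return out
        idx = np.searchsorted(ivals[:, 0], positions, side="right") - 1
        hit = idx >= 0
        out[hit] = positions[hit] < ivals[idx[hit], 1]
        return out

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, ivals in self.intervals.items():
                for s, e in ivals:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def merge_intervals(ivals) -> np.ndarray:
    arr = np.asarray(sorted((int(s), int(e)) for s, e in ivals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def load_repeat_bed(path: str | Path) -> RepeatAnnotation:
    """Load a BED3+ repeat annotation; intervals are sorted and merged."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = parts[0]
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if s < 0 or e <= s:
                raise ValueError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            raw.setdefault(chrom, []).append((s, e))
    return RepeatAnnotation.from_intervals(raw)
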