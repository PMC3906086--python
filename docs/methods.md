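# Methods

This note documents the models implemented in `cfbias`, their assumptions,
the tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Data model and coordinates

All coordinates are 0-based, half-open.  The universal input is a fragment
set: per fragment a chromosome, `[start, end)`, strand and optional mapping
quality.  The 5′ end — `start` on the forward strand, `end − 1` on the
reverse strand — is the quantity every downstream operation keys on: bin
counts are 5′-end counts, repeat filtering tests the 5′ end, and the
single-position model treats each (position, strand) pair as a potential
fragment start.  Genomes are tiled with full-width bins (default 50 000 bp)
from position 0; trailing partial bins are dropped rather than rescaled so
bin counts stay comparable.  Bins whose N fraction exceeds 0.1 and all chrY
bins are excluded from analysis.

## Mappability

A start position is *uniquely mappable at read length k* (default k = 50)
when its k-mer occurs exactly once in the genome counting both strands: a
k-mer and its reverse complement are occurrences of the same read, and a
reverse-palindromic k-mer is therefore never unique, nor is a k-mer
containing N.  This exact-match definition is deterministic and
aligner-free; tracks produced by an aligner-based definition (which differs
near diverged repeats when mismatches are tolerated) can be imported from
bedGraph instead.  The implementation packs k-mers (k ≤ 64) into pairs of
64-bit integers and sorts, so uniqueness is exact, not hash-approximate.
Window mappability is the fraction of uniquely mapping start positions in
the bin.  Bin counts are corrected by 1/mappability; bins with mappability
below 0.5 are dropped to prevent over-correction.

## GC-bias corrections

**Binned LOESS.**  Valid bins with nonzero counts are grouped into 1% GC
intervals; a LOESS curve (span 0.3, via `statsmodels` lowess) is fitted to
(interval midpoint, mean count); each bin's prediction is the fit evaluated
at its GC by linear interpolation between fitted midpoints, and the
corrected value is count/prediction.  Zero-count bins are excluded from the
fit but still corrected (to 0).  The fit requires at least five occupied
intervals and strictly positive predictions at every used bin.  Fitting to
interval means rather than to all bins is deliberate: it equalizes the
influence of rare and common GC values.

**Single-position model.**  Uniquely mappable positions are sampled
uniformly on both strands (default sample size min(N_unique, 5×10⁶), fixed
seed); each sampled position is assigned the integer GC count s ∈ {0..l} of
the window of length l starting at it in read orientation (reverse-strand
windows end at the position; windows containing N or running off the
chromosome are excluded).  Stratum rates λ_s = F_s/n_s (fragments starting
at sampled positions / sampled positions) are smoothed against s by local
linear regression with tricube neighbourhood weights multiplied by n_s
(span 0.3) and clamped at zero — a hand-written smoother because the
library lowess does not accept observation weights.  Every uniquely
mappable position then receives the prediction λ̂_{s(x)} (zero elsewhere);
predictions are summed per bin and the corrected value is
count / prediction × 1/mappability.  The reciprocal-mappability factor is
applied literally as the model's published form even though zeroed
predictions at non-unique positions already absorb part of the effect; a
flag disables it.

**GC window length.**  The TV-score of a stratification is
½ Σ_s |F_s/ΣF − n_s/Σn|, the total-variation distance between the fragment
and position distributions over strata: 0 when the fragment rate is
constant across strata, approaching 1 when fragments concentrate in strata
holding few positions, and never decreased by refining the stratification.
Scanning window lengths 1–700 bp with one shared position sample traces how
much coverage variation window GC explains; the selected window is the
argmax on [50, 500] bp — the sub-10 bp spike reflects breakpoint motifs,
not fragment-scale GC — with a fallback of 180 bp (nucleosome scale) when
the restricted curve is flat (max − median < 0.005).

## Fragmentation signature

Positional base profiles count reference bases at offsets −25..+24 around
fragment termini in read orientation, using stringently mapped fragments
(mapq > 60); offsets without full context are excluded per fragment.  The
breakpoint 3-mer is the ordered reference bases at offsets (−2, 0, +1) from
the 5′ end, rendered `X*YZ` with a wildcard at −1 — 64 classes.  Motif
context comes from the reference at the mapped position, never from read
bases, so the stratum is a property of (position, strand); this is what
allows position-level stratification of the GC model.  Greedy offset
selection repeatedly adds the offset with the highest conditional TV score
until the gain falls below `gain_tol` (default 0.005); note that with few
fragments the refinement noise floor grows with the stratum count, so
desk-scale analyses should raise `gain_tol` accordingly (the validation
tests use 0.003–0.03 at 10⁵–5×10⁵ fragments).  Strand homogeneity is a
chi-square test on the 2 × 21 table of the common top-20 motifs plus an
aggregated rest class (df = 20, counts not proportions; expected cells
below 5 warn rather than fail).

**Stratified correction.**  Fragments (and positions) are split into
stratum 1 — breakpoint 3-mer in {C*CC, C*GG, C*CA, C*TG}, the
GC-shifted, over-represented motifs — and stratum 2, everything else.
Positions whose context runs off the chromosome join stratum 2 (at most
four positions per chromosome).  The single-position model is fitted and
predicted separately within each stratum's positions; per bin the stratum
corrections obs_k/pred_k are combined with sample-wide stratum proportions
as weights (a per-bin-weights variant sits behind a flag), then the
1/mappability factor is applied.  A globally empty stratum is skipped with
weight 0, so a stratum set covering all motifs reproduces the unstratified
correction exactly.

## Trisomy test and evaluation statistics

The sample proportion p_j is the corrected bin mass on the target
chromosome divided by the mass on all chromosomes except chrY (valid bins
only).  The Z-score uses the reference-set mean and n−1 standard deviation;
diploidy is rejected for z strictly greater than 3 (the 99.9th one-tailed
Normal percentile).  In cohort evaluation a reference sample's own z is
computed leave-one-out.  Note that with a finite genome the clean
copy-number identity (a trisomic target at fetal fraction f carries
(1 + f/2)× mass) holds on the odds s/(1−s), not on the raw proportion,
because the total mass grows too; the validation studies therefore measure
the odds-ratio increase.

Supporting statistics: discriminatory distance = 5th percentile of trisomy
z minus 95th percentile of euploid z (linear-interpolation quantiles;
positive = separated); MAD = mean |observed − LOESS-predicted| bin count,
used to compare repeat handling; accuracy = fraction of correct calls; and
a reference-free test reporting, per chromosome, the minimum one-sided
Welch t against every other chromosome's corrected bin values
(Welch–Satterthwaite df), called over-represented above the critical value
at α = 0.001/(m(m−1)) for m chromosomes.

## Synthetic-data generator

The generator emulates the structure of aligned maternal-plasma data at
desk scale.  Genomes are blockwise-random (default 5 kb blocks, per-block
GC drawn from U(0.30, 0.60)) with optional verbatim duplicated segments
creating non-unique regions.  Per-(position, strand) sampling weight =
rate(window GC) × motif weight × copy factor, where the rate curve is a
scaled Beta density over GC fraction parameterized by peak location
(default 0.45, matching the observed coverage maximum at 40–50% GC) and
concentration (default 30), the motif weights act on the breakpoint 3-mer
at the 5′ end (default flat), and the copy factor is
((1−f)·2 + f·(3 if trisomic target else 2))/2.  Fragment starts are a
multinomial draw; lengths follow 0.85·N(166, 20) + 0.15·N(340, 30)
truncated at 50 bp (fetal fragments optionally from N(143, 15)); mapq is
70.  When a mappability track is supplied, fragments whose 5′ read would
not map uniquely are never emitted — emulating the upstream multi-mapper
removal applied to real aligned data, and the reason the 1/mappability
correction has something to correct.  The simulated repeat annotation
covers a configurable genome fraction (default 0.30) with scattered 5–50 kb
intervals plus the duplicated segments, deliberately much broader than the
truly non-unique sequence, as curated repeat databases are.

What the generator does **not** emulate: sequencing errors and duplicate
reads; alignment mismatches (uniqueness is exact-match); fragment-length–
dependent GC bias; motif effects at the 3′ terminus — only the 5′ end of
each simulated fragment is a motif-biased cleavage site, the other end is
set by the length model, so 5′/3′ profile mirror-symmetry seen in real
plasma data is replicated only as +/− strand symmetry of 5′ profiles;
inter-run technical variation between reference and test samples.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
bias model, not performance on real libraries.

## Validation studies and problem sizes

`cfbias.studies` fixes the simulated study conditions (and
`scripts/acceptance.py` re-runs them from scratch): the mixture identity at
f = 0.10 with 10⁶ fragments on a 3 Mb genome; GC-curve recovery (Pearson r
on strata with n_s ≥ 200) and TV window selection with 10⁶ fragments on a
10 Mb genome; end-to-end detection with 20 euploid references and 20
trisomic samples (f = 0.10, 5×10⁵ fragments each, position sample 2×10⁶
per fit) on a 20 Mb eight-chromosome genome sharing one reference build;
the fragmentation profile with 2.5-fold C preference at offsets −2, 0, +1;
and the repeat-handling MAD comparison on an 8 Mb genome with three 40 kb
duplications and 30% annotated repeats.

## Numerical choices and degenerate inputs

- Subsampling draws exactly round(p·N) fragments without replacement,
  deterministically per seed.
- Quantiles interpolate linearly between order statistics.
- Bins with aggregated single-position prediction below 10⁻¹² (practically:
  fully non-unique bins) are invalidated rather than divided by ~0.
- The stratum-rate smoother falls back to the local weighted mean when the
  local design is degenerate, and to the global weighted mean when a point
  has no local support.
- `mapq` is −1 when absent; mapq filters then exclude such fragments.
- Hard errors (rather than silent results): empty FASTA, duplicate headers,
  k exceeding every chromosome, fragments on unknown chromosomes, malformed
  BED intervals, degenerate (zero-sd) references, zero denominators, and
  fewer than 10 occupied GC strata or 5 occupied GC intervals.

## Known limitations

Exact-match uniqueness is stricter than mismatch-tolerant aligners near
diverged repeats; import an external track for fidelity to a specific
aligner.  The greedy TV selection's stopping rule is noise-floor dependent
at low depth.  The two-stratum correction inherits the variance cost of
estimating two GC curves from a 16%/84% split, and on simulated data (as
reported for real data) does not improve detection over the unstratified
single-position model.  Residual inter-sample variation is not modelled;
the Z-test against references remains necessary.
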