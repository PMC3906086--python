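# cfbias

Coverage bias correction and aneuploidy testing for low-coverage sequencing of
plasma cell-free DNA (cfDNA).

## The problem

Non-invasive prenatal testing detects fetal trisomy 21 by counting sequenced
maternal-plasma DNA fragments per chromosome: a trisomic fetus at fetal
fraction *f* raises the chromosome-21 representation by *f*/2 (a 5% excess at
*f* = 0.10).  Detecting so small an excess at 0.01–0.5x coverage requires
removing the systematic biases in read counts first:

- **GC bias** — coverage is a unimodal function of local GC content,
  maximal near 40–50% GC;
- **mappability bias** — short reads cannot be placed uniquely in repetitive
  regions, and hard-filtering annotated repeats discards uniquely mapping
  data;
- **fragmentation bias** — plasma DNA is cleaved by biological processes that
  prefer specific nucleotides around the cut site (the *breakpoint 3-mer*,
  the bases at offsets −2, 0, +1 from a fragment's 5′ end, e.g. `C*CC`).

`cfbias` implements four correction protocols over 50 kb bin counts and the
downstream Z-score trisomy test:

| protocol | stages |
| --- | --- |
| `rm_loess` | remove repeat-annotated reads → LOESS GC correction |
| `mapcorr_loess` | 1/mappability weighting → LOESS GC correction |
| `mapcorr_singlepos` | single-position GC model → 1/mappability |
| `mapcorr_singlepos_frag` | breakpoint-motif stratification → per-stratum single-position model → weighted combination → 1/mappability |

The **single-position model** stratifies uniquely mappable positions *x* by
the GC count *s* of the window of length *l* starting at *x*
(strand-specifically), estimates the mean fragment rate λ_s = F_s / n_s per
stratum, smooths λ̂_s against *s*, and corrects each bin by the sum of its
per-position predictions.  The window length is chosen by scanning the
**TV-score**

    TV(l) = ½ Σ_s | F_s/ΣF − n_s/Σn |,

the total-variation distance between the fragment and position distributions
over strata — the share of coverage variation explained by conditioning on
window GC.  The trisomy call uses the standard proportion Z-score
z_j = (p_j − μ_ref)/σ_ref against a euploid reference set, with z > 3
rejecting diploidy.

A synthetic-data module generates toy genomes (blockwise GC, duplicated
segments) and plasma-like fragments with a known Beta-shaped GC rate curve,
motif-biased cleavage, the nucleosomal fragment-length mixture (modes near
166 bp and 340 bp), configurable fetal fraction and whole-chromosome trisomy
— ground truth for every recovery test.

## Worked example

```
printf 'chrom_lengths: {chr1: 300000, chr21: 150000}\nn_fragments: 40000\n' > sim.yaml
cfbias simulate --config sim.yaml --out-dir sim --seed 5
cfbias correct --fasta sim/genome.fa --fragments sim/fragments.bed \
    --protocol mapcorr_singlepos --mappability sim/mappability.bedgraph \
    --bin-size 25000 --gc-window 166 --out-dir corrected
```

prints

```
wrote genome, fragments (40000), repeats and truth to sim
protocol mapcorr_singlepos: 18 valid bins -> corrected
```

and writes `corrected/bins_mapcorr_singlepos.tsv` (per bin: raw count, GC,
mappability, validity, corrected value) plus the fitted GC strata table.  The
corrected values fluctuate around 1 when the bias model explains the counts;
`cfbias test-trisomy` then turns per-sample bin tables into chromosome
proportions and Z-scores.  The same steps are available as library calls
(`cfbias.pipeline.run_protocol`, `cfbias.aneuploidy.z_score`); the Python
equivalent of the full chain on a simulated cohort is in
`cfbias/studies.py`.

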