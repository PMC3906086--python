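"""Self-contained validation studies run on simulated plasma-cfDNA data.

Each function simulates a dataset under the package's documented study
conditions, runs the relevant part of the analysis chain, and returns the
measured quantities together with the problem size.  They back both the
validation test suite and the reproduction script; everything is
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from . import fragmentation, gc_models, pipeline
from .aneuploidy import chrom_proportion, discriminatory_distance, z_score
from .fragmentation import all_motifs, base_profile
from .reference import compute_unique_positions
from .simulate import (
    Duplication,
    FragmentSampler,
    SimulationConfig,
    gc_rate_curve,
    simulate_genome,
    simulate_repeats,
)


def _base_seed(seed: int) -> int:
    # derived per-sample seeds stay below 2**31
    return int((seed * 100_003) % (2**31 - 100_000))


def mixture_identity_study(
    seed: int = 0, n_fragments: int = 1_000_000, fetal_fraction: float = 0.10
) -> dict:
    """Trisomy mixture identity: representation increase of f/2 at fetal fraction f.

    The analytic expectation comes from the generator's copy-factor model; the
    simulated value is the odds-ratio increase of the target chromosome's
    fragment share against the euploid expectation (the non-target
    chromosomes are the invariant reference mass).
    """
    config = SimulationConfig(
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_000_000, "chr21": 500_000},
        n_fragments=n_fragments,
        fetal_fraction=fetal_fraction,
        trisomy_chrom="chr21",
        seed=_base_seed(seed),
    )
    genome = simulate_genome(config)
    sampler = FragmentSampler(genome, config)
    frags, truth = sampler.sample(seed=_base_seed(seed) + 1)
    share = truth.realized_counts["chr21"] / truth.n_fragments
    s_e = truth.expected_share_euploid["chr21"]
    odds_ratio = (share / (1 - share)) / (s_e / (1 - s_e))
    return {
        "expected_pct": 100.0 * (truth.expected_representation - 1.0),
        "simulated_pct": 100.0 * (odds_ratio - 1.0),
        "n_fragments": n_fragments,
    }


def gc_recovery_study(
    seed: int = 0,
    n_fragments: int = 1_000_000,
    window_length: int = 166,
    scan_sample_size: int = 300_000,
) -> dict:
    """Single-position model recovery of a known GC rate curve on a 10 Mb genome.

    Measures the Pearson correlation between the smoothed stratum rates and
    the true Beta-shaped curve on well-populated strata, and the GC window
    length selected from the TV-score scan (truth: ``window_length``).
    """
    config = SimulationConfig(
        chrom_lengths={"chr1": 6_000_000, "chr2": 4_000_000},
        n_fragments=n_fragments,
        window_length=window_length,
        seed=_base_seed(seed) + 11,
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    frags, _ = FragmentSampler(genome, config, mappability=track).sample(
        seed=_base_seed(seed) + 12
    )
    strata = gc_models.single_position_fit(
        frags, genome, track, window_length, seed=seed
    )
    well = strata.n >= 200
    s = np.arange(window_length + 1)
    truth = gc_rate_curve(config, s / window_length)
    r = float(np.corrcoef(strata.rate_smooth[well], truth[well])[0, 1])
    curve = gc_models.gc_window_scan(
        frags, genome, track, lengths=range(1, 701),
        sample_size=scan_sample_size, seed=seed,
    )
    selected = gc_models.select_gc_window(curve)
    return {
        "pearson_r": r,
        "selected_window": int(selected),
        "true_window": window_length,
        "n_fragments": n_fragments,
        "curve": curve,
        "strata": strata,
    }


DETECTION_CHROMS = {
    "chr1": 3_500_000,
    "chr2": 3_000_000,
    "chr3": 3_000_000,
    "chr4": 2_500_000,
    "chr5": 2_500_000,
    "chr6": 2_000_000,
    "chr7": 1_500_000,
    "chr21": 2_000_000,
}


def trisomy_detection_study(
    seed: int = 0,
    n_trisomy: int = 20,
    n_reference: int = 20,
    n_fragments: int = 500_000,
    fetal_fraction: float = 0.10,
    sample_size: int = 2_000_000,
    gc_window: int = 180,
) -> dict:
    """End-to-end trisomy detection on a 20 Mb toy genome.

    One genome and mappability track are shared by the whole cohort (as one
    reference build is in practice); ``n_reference`` euploid references and
    ``n_trisomy`` trisomic samples at the given fetal fraction are simulated,
    corrected with the mappability-aware single-position protocol, and scored:
    trisomy z against the reference set, reference z leave-one-out.
    """
    config = SimulationConfig(
        chrom_lengths=DETECTION_CHROMS,
        n_fragments=n_fragments,
        seed=_base_seed(seed) + 21,
        duplications=[
            Duplication("chr1", 1_000_000, 1_030_000, "chr2", 1_000_000),
            Duplication("chr3", 500_000, 520_000, "chr3", 2_000_000),
        ],
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    sampler = FragmentSampler(genome, config, mappability=track)
    base = _base_seed(seed)

    def corrected_proportion(frags):
        bins, _ = pipeline.run_protocol(
            "mapcorr_singlepos", genome, frags,
            track=track, gc_window=gc_window, sample_size=sample_size, seed=seed,
        )
        return chrom_proportion(bins, "chr21")

    p_ref = []
    for i in range(n_reference):
        frags, _ = sampler.sample(seed=base + 100 + i)
        p_ref.append(corrected_proportion(frags))
    z_ref = [
        z_score(p, [q for j, q in enumerate(p_ref) if j != i]).z
        for i, p in enumerate(p_ref)
    ]
    z_tri = []
    for i in range(n_trisomy):
        frags, _ = sampler.sample(
            fetal_fraction=fetal_fraction, trisomy_chrom="chr21", seed=base + 500 + i
        )
        z_tri.append(z_score(corrected_proportion(frags), p_ref).z)
    z_tri = np.asarray(z_tri)
    z_ref = np.asarray(z_ref)
    return {
        "detection_rate_pct": 100.0 * float((z_tri > 3.0).mean()),
        "n_trisomy": n_trisomy,
        "false_positives": int((z_ref > 3.0).sum()),
        "n_reference": n_reference,
        "discriminatory_distance": discriminatory_distance(z_ref, z_tri),
        "z_trisomy": z_tri,
        "z_reference": z_ref,
        "n_fragments": n_fragments,
    }


def fragmentation_profile_study(
    seed: int = 0, n_fragments: int = 150_000, preference: float = 2.5
) -> dict:
    """Positional base profile of a motif-biased cleavage model.

    Cleavage prefers C at offsets -2, 0 and +1 (``preference``-fold per
    offset); the profile's C proportion should be elevated exactly there.
    Returns the minimum C proportion over the biased offsets, the maximum
    over all other offsets, and the most frequent breakpoint 3-mer.
    """
    weights = {}
    for name in all_motifs():
        w = 1.0
        for b in (name[0], name[2], name[3]):
            if b == "C":
                w *= preference
        weights[name] = w
    config = SimulationConfig(
        chrom_lengths={"chr1": 1_500_000},
        n_fragments=n_fragments,
        gc_concentration=0.0,
        motif_weights=weights,
        seed=_base_seed(seed) + 31,
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    frags, _ = FragmentSampler(genome, config, mappability=track).sample(
        seed=_base_seed(seed) + 32
    )
    prof = base_profile(frags, genome, end="5p")
    c = prof.proportions[:, 1]
    offs = list(prof.offsets)
    biased = [offs.index(o) for o in (-2, 0, 1)]
    neutral = [i for i, o in enumerate(offs) if o not in (-2, 0, 1)]
    table = fragmentation.motif_table(frags, genome)
    top = table.counts.sum(axis=1).idxmax()
    return {
        "c_biased_min": float(c[biased].min()),
        "c_neutral_max": float(c[neutral].max()),
        "top_motif": top,
        "n_fragments": n_fragments,
    }


def repeat_handling_study(seed: int = 0, n_fragments: int = 400_000) -> dict:
    """Prediction-error comparison of the two repeat-handling protocols.

    On a genome with duplicated (non-unique) segments and a broad repeat
    annotation, hard removal of annotated reads (rm_loess) inflates the
    LOESS prediction error relative to reciprocal mappability weighting
    (mapcorr_loess).
    """
    config = SimulationConfig(
        chrom_lengths={"chr1": 5_000_000, "chr2": 3_000_000},
        n_fragments=n_fragments,
        repeat_fraction=0.30,
        seed=_base_seed(seed) + 41,
        duplications=[
            Duplication("chr1", 500_000, 540_000, "chr1", 3_000_000),
            Duplication("chr2", 200_000, 240_000, "chr2", 1_500_000),
            Duplication("chr1", 4_000_000, 4_040_000, "chr2", 2_500_000),
        ],
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    repeats = simulate_repeats(config)
    frags, _ = FragmentSampler(genome, config, mappability=track).sample(
        seed=_base_seed(seed) + 42
    )
    _, rep_rm = pipeline.run_protocol(
        "rm_loess", genome, frags, repeats=repeats, track=track, seed=seed
    )
    _, rep_map = pipeline.run_protocol(
        "mapcorr_loess", genome, frags, track=track, seed=seed
    )
    return {
        "mad_rm_loess": rep_rm["mad"],
        "mad_mapcorr_loess": rep_map["mad"],
        "mad_ratio": rep_map["mad"] / rep_rm["mad"],
        "n_fragments": n_fragments,
    }
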