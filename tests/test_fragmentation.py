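"""Breakpoint-motif analysis: base profiles, positional TV, motif tables,
strand homogeneity and the motif-stratified GC correction."""

import numpy as np
import pandas as pd
import pytest

from cfbias.bins import BinScheme
from cfbias.fragments import assign_bins, make_fragments
from cfbias.fragmentation import (
    DEFAULT_STRATUM1_MOTIFS,
    MotifFrequencyTable,
    all_motifs,
    assign_strata,
    base_profile,
    combine_stratum_corrections,
    fragment_motif_indices,
    greedy_motif_positions,
    motif_index,
    motif_name,
    motif_table,
    positional_tv,
    strand_homogeneity_test,
    stratified_correct,
)
from cfbias.gc_models import single_position_correct, single_position_fit
from cfbias.reference import GenomeSequence, compute_unique_positions
from cfbias.simulate import FragmentSampler, SimulationConfig, simulate_genome


def per_base_motif_weights(prefs: dict[int, dict[str, float]]) -> dict[str, float]:
    """Multiplicative per-offset base preferences -> 64-motif weight map."""
    offsets = (-2, 0, 1)
    weights = {}
    for name in all_motifs():
        bases = {-2: name[0], 0: name[2], 1: name[3]}
        w = 1.0
        for off in offsets:
            w *= prefs.get(off, {}).get(bases[off], 1.0)
        weights[name] = w
    return weights


class TestMotifNaming:
    def test_exactly_64_classes(self):
        motifs = all_motifs()
        assert len(motifs) == len(set(motifs)) == 64
        assert all(motif_name(motif_index(m)) == m for m in motifs)

    def test_hand_walked_contexts(self):
        genome = GenomeSequence.from_strings({"c1": "AACCCCGT"})
        frags = make_fragments(
            ["c1", "c1"], [3, 2], [7, 6], ["+", "-"], [70, 70]
        )  # + fragment 5'=3; - fragment 5'=5
        idx = fragment_motif_indices(frags, genome)
        assert [motif_name(i) for i in idx] == ["A*CC", "A*GG"]

    def test_context_off_chromosome_is_undetermined(self):
        genome = GenomeSequence.from_strings({"c1": "AACCCCGT"})
        frags = make_fragments(["c1"], [1], [5], ["+"], [70])  # needs base at -1 index
        assert fragment_motif_indices(frags, genome)[0] == -1


@pytest.fixture(scope="module")
def motif_biased_sim():
    """Cleavage favouring C at offsets -2, 0 and +1 (2.5x per position)."""
    weights = per_base_motif_weights({-2: {"C": 2.5}, 0: {"C": 2.5}, 1: {"C": 2.5}})
    config = SimulationConfig(
        chrom_lengths={"c1": 1_500_000},
        n_fragments=150_000,
        gc_concentration=0.0,
        motif_weights=weights,
        seed=21,
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    frags, truth = FragmentSampler(genome, config, mappability=track).sample(seed=22)
    return config, genome, track, frags, truth


@pytest.fixture(scope="module")
def null_sim():
    config = SimulationConfig(
        chrom_lengths={"c1": 1_000_000},
        n_fragments=120_000,
        gc_concentration=0.0,
        seed=23,
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    frags, _ = FragmentSampler(genome, config, mappability=track).sample(seed=24)
    return config, genome, track, frags


class TestBaseProfile:
    def test_proportions_sum_to_one(self, null_sim):
        _, genome, _, frags = null_sim
        prof = base_profile(frags, genome, end="5p")
        np.testing.assert_allclose(prof.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_null_profile_matches_genome_composition(self, null_sim):
        # flat rates: the profile should reflect base availability, not cleavage
        config, genome, _, frags = null_sim
        prof = base_profile(frags, genome, end="5p")
        codes = genome.codes("c1")
        comp = np.bincount(codes[codes < 4], minlength=4) / (codes < 4).sum()
        se = np.sqrt(comp * (1 - comp) / prof.n_fragments)
        # offsets away from the (absent) motif should track composition;
        # reverse-strand complementation averages A with T and C with G
        sym = np.array([(comp[0] + comp[3]) / 2, (comp[1] + comp[2]) / 2])
        expected = np.array([sym[0], sym[1], sym[1], sym[0]])
        assert np.abs(prof.proportions - expected).max() < 4 * se.max() + 0.01

    def test_biased_offsets_show_elevated_c(self, motif_biased_sim):
        _, genome, _, frags, _ = motif_biased_sim
        prof = base_profile(frags, genome, end="5p")
        c = prof.proportions[:, 1]  # C column
        offs = list(prof.offsets)
        biased = [offs.index(o) for o in (-2, 0, 1)]
        neutral = [i for i, o in enumerate(offs) if o not in (-2, 0, 1)]
        assert c[biased].min() > c[neutral].max() + 0.05

    def test_strand_symmetric_cleavage_profiles_agree(self, motif_biased_sim):
        # the cleavage model is strand-symmetric: the 5' profile computed from
        # forward fragments alone matches the one from reverse fragments alone
        _, genome, _, frags, _ = motif_biased_sim
        fwd = frags[frags["strand"] == "+"]
        rev = frags[frags["strand"] == "-"]
        pf = base_profile(fwd, genome, end="5p")
        pr = base_profile(rev, genome, end="5p")
        assert np.abs(pf.proportions - pr.proportions).max() < 0.02

    def test_edge_fragment_contributes_partial_context(self):
        genome = GenomeSequence.from_strings({"c1": "ACGTACGTACGT"})
        frags = make_fragments(["c1"], [1], [6], ["+"], [70])
        prof = base_profile(frags, genome, end="5p", flank=25)
        assert prof.counts.sum() > 0  # only in-bounds offsets counted
        assert prof.counts.sum(axis=1).max() == 1

    def test_no_fragment_passes_filter_is_error(self):
        genome = GenomeSequence.from_strings({"c1": "ACGTACGTACGT"})
        frags = make_fragments(["c1"], [2], [8], ["+"], [10])
        with pytest.raises(ValueError, match="mapping-quality"):
            base_profile(frags, genome)


class TestMotifTable:
    def test_counts_sum_to_retained_fragments(self, motif_biased_sim):
        _, genome, _, frags, _ = motif_biased_sim
        table = motif_table(frags, genome)
        assert table.counts.to_numpy().sum() + table.n_excluded == len(frags)
        props = table.proportions()
        np.testing.assert_allclose(props.sum(axis=0), 1.0)

    def test_biased_motifs_over_represented(self, motif_biased_sim):
        _, genome, _, frags, truth = motif_biased_sim
        table = motif_table(frags, genome)
        props = table.proportions().sum(axis=1) / 2
        ccc = props["C*CC"]
        assert ccc == max(props)
        # realized frequencies track the weight-implied truth
        expected = pd.Series(truth.expected_motif_distribution)
        tv = 0.5 * np.abs(props - expected / expected.sum()).sum()
        assert tv < 0.02


class TestStrandHomogeneity:
    def _table(self, plus, minus):
        counts = pd.DataFrame(
            {"+": plus, "-": minus}, index=all_motifs(), dtype=np.int64
        )
        return MotifFrequencyTable(counts=counts)

    def test_identical_strands_give_zero(self, rng):
        c = rng.integers(100, 1000, size=64)
        stat, df, p = strand_homogeneity_test(self._table(c, c))
        assert stat == pytest.approx(0.0)
        assert df == 20
        assert p == pytest.approx(1.0)

    def test_statistic_matches_textbook_formula(self, rng):
        plus = rng.integers(50, 2000, size=64)
        minus = rng.integers(50, 2000, size=64)
        table = self._table(plus, minus)
        stat, df, p = strand_homogeneity_test(table)
        _, mat = table.top_partition(20)
        expected = np.outer(mat.sum(axis=1), mat.sum(axis=0)) / mat.sum()
        oracle = ((mat - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle)
        assert df == 20

    def test_type_one_error_rate_near_alpha(self, rng):
        # both strands drawn from one multinomial: rejections ~ alpha
        p = rng.dirichlet(np.ones(64) * 5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            plus = rng.multinomial(100_000, p)
            minus = rng.multinomial(100_000, p)
            _, _, pval = strand_homogeneity_test(self._table(plus, minus))
            rejections += pval < 0.05
        assert 0.005 <= rejections / reps <= 0.105

    def test_low_expected_counts_warn(self):
        plus = np.ones(64, dtype=int)
        minus = np.ones(64, dtype=int)
        with pytest.warns(UserWarning, match="below 5"):
            strand_homogeneity_test(self._table(plus, minus))


class TestPositionalTV:
    def test_biased_offset_is_maximal(self, rng):
        weights = per_base_motif_weights({-2: {"C": 3.0}})  # bias only at -2
        config = SimulationConfig(
            chrom_lengths={"c1": 800_000},
            n_fragments=120_000,
            gc_concentration=0.0,
            motif_weights=weights,
            seed=31,
        )
        genome = simulate_genome(config)
        track = compute_unique_positions(genome, 50)
        frags, _ = FragmentSampler(genome, config, mappability=track).sample(seed=32)
        scores = {
            off: positional_tv(frags, genome, track, [], off, sample_size=120_000, seed=0)
            for off in range(-25, 25)
        }
        assert max(scores, key=scores.get) == -2

    def test_null_scores_bounded_by_permuted_control(self, null_sim):
        # uniform placement: scores are pure sampling noise, on the same scale
        # as scores computed after shuffling fragment counts across positions
        from cfbias.fragmentation import _offset_strata
        from cfbias.positions import attach_fragment_counts, sample_unique_positions

        _, genome, track, frags = null_sim
        sample = sample_unique_positions(genome, track, None, seed=0)
        attach_fragment_counts(sample, frags)
        rng = np.random.default_rng(0)
        for off in (-3, 0, 4):
            score = positional_tv(frags, genome, track, [], off, sample_size=None, seed=0)
            idx, good = _offset_strata(sample, genome, [off])
            Fp = rng.permutation(sample.F[good])
            n_s = np.bincount(idx[good], minlength=4)
            F_s = np.bincount(idx[good], weights=Fp, minlength=4)
            from cfbias.gc_models import tv_score

            assert score < max(3.0 * tv_score(n_s, F_s), 0.005)


@pytest.fixture(scope="module")
def three_offset_sim():
    weights = per_base_motif_weights({-2: {"C": 3.0}, 0: {"C": 3.0}, 1: {"C": 3.0}})
    config = SimulationConfig(
        chrom_lengths={"c1": 800_000},
        n_fragments=500_000,
        gc_concentration=0.0,
        motif_weights=weights,
        seed=33,
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    frags, _ = FragmentSampler(genome, config, mappability=track).sample(seed=34)
    return genome, track, frags


class TestGreedySelection:
    def test_recovers_biased_offsets(self, three_offset_sim):
        # gain_tol sits between the third biased offset's (saturating) TV gain
        # and the refinement-noise gains of unbiased offsets at this depth
        genome, track, frags = three_offset_sim
        selected, scores = greedy_motif_positions(
            frags, genome, track, max_k=4, gain_tol=0.003,
            candidates=range(-10, 10), sample_size=None, seed=0,
        )
        assert set(selected) == {-2, 0, 1}
        assert scores == sorted(scores)  # TV increases along the greedy path

    def test_truncation_at_max_k(self, three_offset_sim):
        genome, track, frags = three_offset_sim
        selected, _ = greedy_motif_positions(
            frags, genome, track, max_k=1, candidates=range(-5, 5),
            sample_size=None, seed=0,
        )
        assert len(selected) == 1
        assert selected[0] in {-2, 0, 1}

    def test_null_generator_selects_nothing(self, null_sim):
        _, genome, track, frags = null_sim
        selected, _ = greedy_motif_positions(
            frags, genome, track, max_k=3, gain_tol=0.005,
            candidates=range(-5, 5), sample_size=None, seed=0,
        )
        assert selected == []


class TestStratifiedCorrect:
    def test_combination_arithmetic(self):
        assert combine_stratum_corrections([20, 80], [25, 100], [0.2, 0.8]) == pytest.approx(0.8)

    def test_degenerate_stratification_matches_unstratified(self, null_sim):
        # identical GC behaviour in both strata: combined correction ~ unstratified
        _, genome, track, frags = null_sim
        scheme = BinScheme.from_genome(genome, 25_000)
        bins = assign_bins(frags, scheme, genome=genome, track=track)
        assignment = assign_strata(frags, genome)
        strat = stratified_correct(
            bins, frags, genome, track, assignment, 166, sample_size=400_000, seed=0
        )
        strata = single_position_fit(frags, genome, track, 166, sample_size=400_000, seed=0)
        unstrat = single_position_correct(bins, strata, genome, track)
        ok = strat["valid"] & unstrat["valid"]
        ratio = strat.loc[ok, "corrected"] / unstrat.loc[ok, "corrected"]
        np.testing.assert_allclose(ratio, 1.0, rtol=0.02)

    def test_single_stratum_reproduces_unstratified_exactly(self):
        # duplicating the chromosome ends makes the edge positions (whose
        # breakpoint context runs off the chromosome) non-unique, so the
        # all-motif stratum spans exactly the uniquely mappable universe
        from cfbias.simulate import Duplication

        config = SimulationConfig(
            chrom_lengths={"c1": 400_000}, n_fragments=60_000,
            gc_concentration=10.0, seed=41,
            duplications=[
                Duplication("c1", 0, 52, "c1", 200_000),
                Duplication("c1", 399_948, 400_000, "c1", 250_000),
            ],
        )
        genome = simulate_genome(config)
        track = compute_unique_positions(genome, 50)
        frags, _ = FragmentSampler(genome, config, mappability=track).sample(seed=42)
        scheme = BinScheme.from_genome(genome, 20_000)
        bins = assign_bins(frags, scheme, genome=genome, track=track)
        assignment = assign_strata(frags, genome, stratum1_motifs=frozenset(all_motifs()))
        assert assignment.w1 == 1.0
        strat = stratified_correct(
            bins, frags, genome, track, assignment, 166, sample_size=200_000, seed=0
        )
        strata = single_position_fit(frags, genome, track, 166, sample_size=200_000, seed=0)
        unstrat = single_position_correct(bins, strata, genome, track)
        pd.testing.assert_series_equal(strat["valid"], unstrat["valid"])
        ok = strat["valid"]
        np.testing.assert_allclose(
            strat.loc[ok, "corrected"], unstrat.loc[ok, "corrected"], rtol=1e-12
        )

    def test_recovers_divergent_stratum_gc_peaks(self):
        # stratum-1 motifs cleave with a 60% GC optimum, the rest at 37%
        base = SimulationConfig(
            chrom_lengths={"c1": 1_500_000}, n_fragments=150_000, seed=43,
            gc_range=(0.25, 0.70),
        )
        genome = simulate_genome(base)
        track = compute_unique_positions(genome, 50)
        tiny = 1e-9
        w1 = {m: (1.0 if m in DEFAULT_STRATUM1_MOTIFS else tiny) for m in all_motifs()}
        w2 = {m: (tiny if m in DEFAULT_STRATUM1_MOTIFS else 1.0) for m in all_motifs()}
        cfg1 = SimulationConfig(**{**base.__dict__, "gc_peak": 0.60, "motif_weights": w1})
        cfg2 = SimulationConfig(**{**base.__dict__, "gc_peak": 0.37, "motif_weights": w2})
        f1, _ = FragmentSampler(genome, cfg1, mappability=track).sample(60_000, seed=44)
        f2, _ = FragmentSampler(genome, cfg2, mappability=track).sample(140_000, seed=45)
        frags = pd.concat([f1, f2], ignore_index=True)
        scheme = BinScheme.from_genome(genome, 50_000)
        bins = assign_bins(frags, scheme, genome=genome, track=track)
        assignment = assign_strata(frags, genome)
        out = stratified_correct(
            bins, frags, genome, track, assignment, 166, sample_size=800_000, seed=0
        )
        fits = out.attrs["stratum_fits"]
        for k, expected_peak in ((1, 0.60), (2, 0.37)):
            strata = fits[k]
            well = strata.n >= 100
            s = np.arange(strata.window_length + 1)[well]
            peak = s[np.argmax(strata.rate_smooth[well])] / strata.window_length
            assert abs(peak - expected_peak) <= 0.05
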