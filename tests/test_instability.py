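import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import proteosubtype as pst
from proteosubtype.io import Segment, SegmentProfile

from .oracles import naive_scores, random_profile

MB = 1_000_000


def profile(segs, sample="t"):
    return SegmentProfile(sample, [Segment(*s) for s in segs])


def diploid_genome_profile(genome):
    return profile([(c, 0, genome.length(c), 2, 1, 1) for c in genome.chroms])


class TestPloidyWgd:
    def test_diploid(self, genome):
        ploidy, wgd, cov = pst.ploidy_wgd(diploid_genome_profile(genome), genome)
        assert ploidy == 2.0 and not wgd and cov == 1.0

    def test_wgd_forced_above_half(self, genome):
        # 60% of the autosomal genome at major 2
        segs, acc, target = [], 0, 0.6 * genome.autosomal_length()
        for c in genome.autosomes:
            ln = genome.length(c)
            take = min(ln, int(target - acc))
            if take > 0:
                segs.append((c, 0, take, 4, 2, 2))
                acc += take
            if take < ln:
                segs.append((c, take, ln, 2, 1, 1))
        _, wgd, _ = pst.ploidy_wgd(profile(segs), genome)
        assert wgd

    def test_weighted_mean(self, genome):
        c = genome.autosomes[0]
        ln = genome.length(c)
        half = ln // 2
        p = profile([(c, 0, half, 2, 1, 1), (c, half, 2 * half, 4, 2, 2)])
        ploidy, _, _ = pst.ploidy_wgd(p, genome)
        assert ploidy == pytest.approx(3.0, abs=1e-9)

    def test_empty_profile_rejected(self, genome):
        with pytest.raises(ValueError, match="no autosomal"):
            pst.ploidy_wgd(profile([("chrX", 0, 1000, 2, 1, 1)]), genome)

    def test_doubling_doubles_ploidy_and_forces_wgd(self, genome):
        rng = np.random.default_rng(0)
        p = random_profile(genome, rng)
        ploidy, _, _ = pst.ploidy_wgd(p, genome)
        doubled = SegmentProfile(p.sample_id, [
            Segment(s.chrom, s.start_bp, s.end_bp, 2 * s.total_cn,
                    2 * s.major_cn, 2 * s.minor_cn) for s in p.segments])
        ploidy2, wgd2, _ = pst.ploidy_wgd(doubled, genome)
        assert ploidy2 == pytest.approx(2 * ploidy)
        # every doubled segment has major >= 2 except zero-total ones
        cov = sum(s.length for s in doubled.segments if s.major_cn >= 2)
        if cov > 0.5 * genome.autosomal_length():
            assert wgd2


class TestCin:
    def test_rule_application(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 0, 10 * MB, 2, 1, 1), (c, 10 * MB, 20 * MB, 5, 3, 2),
                     (c, 20 * MB, 30 * MB, 1, 1, 0)])
        n_gain, n_loss, n_loh, cin = pst.cin_score(p, genome)
        assert (n_gain, n_loss, n_loh, cin) == (1, 1, 1, 3)

    def test_diploid_zero(self, genome):
        assert pst.cin_score(diploid_genome_profile(genome), genome)[3] == 0

    def test_split_segments_merge_first(self, genome):
        c = genome.autosomes[0]
        whole = profile([(c, 0, 30 * MB, 4, 2, 2)])
        split = profile([(c, 0, 17 * MB, 4, 2, 2), (c, 17 * MB, 30 * MB, 4, 2, 2)])
        assert pst.cin_score(whole, genome) == pst.cin_score(split, genome)

    def test_exclusive_mode_counts_once(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 0, 10 * MB, 1, 1, 0)])  # loss AND LOH
        assert pst.cin_score(p, genome)[3] == 2
        assert pst.cin_score(p, genome, exclusive=True)[3] == 1


class TestHrdLoh:
    def test_interior_20mb_counts(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 30 * MB, 50 * MB, 2, 2, 0)])
        assert pst.hrd_loh_count(p, genome) == 1

    def test_whole_chromosome_excluded(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 0, genome.length(c), 1, 1, 0)])
        assert pst.hrd_loh_count(p, genome) == 0

    def test_below_threshold_excluded(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 30 * MB, 42 * MB, 2, 2, 0)])  # 12 Mb
        assert pst.hrd_loh_count(p, genome) == 0

    def test_run_spans_different_loh_states(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 30 * MB, 40 * MB, 2, 2, 0), (c, 40 * MB, 50 * MB, 1, 1, 0)])
        assert pst.hrd_loh_count(p, genome) == 1  # one maximal 20 Mb run


class TestLst:
    def test_adjacent_large_segments(self, genome):
        c = genome.autosomes[0]
        ce = genome.centromere(c)[1]
        p = profile([(c, ce, ce + 20 * MB, 2, 1, 1),
                     (c, ce + 20 * MB, ce + 50 * MB, 3, 2, 1)])
        assert pst.lst_count(p, genome) == 1

    def test_small_interposed_segment_smoothed(self, genome):
        c = genome.autosomes[0]
        ce = genome.centromere(c)[1]
        p = profile([(c, ce, ce + 20 * MB, 2, 1, 1),
                     (c, ce + 20 * MB, ce + 22 * MB, 6, 3, 3),
                     (c, ce + 22 * MB, ce + 52 * MB, 3, 2, 1)])
        assert pst.lst_count(p, genome) == 1  # 2 Mb piece removed, gap 2 <= 3 Mb

    def test_five_mb_interposed_blocks(self, genome):
        c = genome.autosomes[0]
        ce = genome.centromere(c)[1]
        p = profile([(c, ce, ce + 20 * MB, 2, 1, 1),
                     (c, ce + 20 * MB, ce + 25 * MB, 6, 3, 3),
                     (c, ce + 25 * MB, ce + 55 * MB, 3, 2, 1)])
        assert pst.lst_count(p, genome) == 0  # 5 Mb flank < 10 Mb on both junctions

    def test_copy_neutral_loh_is_a_transition(self, genome):
        c = genome.autosomes[0]
        ce = genome.centromere(c)[1]
        p = profile([(c, ce, ce + 20 * MB, 2, 1, 1),
                     (c, ce + 20 * MB, ce + 50 * MB, 2, 2, 0)])
        assert pst.lst_count(p, genome) == 1


class TestTai:
    def test_telomeric_imbalance(self, genome):
        c = genome.autosomes[0]  # chr1: centromere well beyond 30 Mb
        p = profile([(c, 0, 30 * MB, 3, 2, 1)])
        assert pst.tai_count(p, genome) == 1

    def test_centromere_crossing_excluded(self, genome):
        c = genome.autosomes[0]
        end = genome.centromere(c)[1] + 10 * MB
        p = profile([(c, 0, end, 3, 2, 1)])
        assert pst.tai_count(p, genome) == 0

    def test_balanced_telomeric_excluded(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 0, 30 * MB, 4, 2, 2)])
        assert pst.tai_count(p, genome) == 0

    def test_whole_chromosome_excluded(self, genome):
        c = genome.autosomes[0]
        p = profile([(c, 0, genome.length(c), 3, 2, 1)])
        assert pst.tai_count(p, genome) == 0

    def test_q_telomere_counts(self, genome):
        c = genome.autosomes[0]
        ln = genome.length(c)
        p = profile([(c, ln - 30 * MB, ln, 2, 2, 0)])
        assert pst.tai_count(p, genome) == 1


class TestHrdScore:
    def test_diploid_all_zero(self, genome):
        s = pst.hrd_score(diploid_genome_profile(genome), genome)
        assert (s.hrd, s.cin, s.wgd) == (0, 0, False)

    def test_hrd_is_component_sum_and_matches_generator(self, genome):
        targets = pst.InstabilityTargets(n_hrd_loh=3, n_lst=4, n_tai=2,
                                         n_gain=8, n_loss=3)
        prof, expected = pst.simulate_segments(targets, genome, seed=42)
        s = pst.hrd_score(prof, genome)
        assert (s.hrd_loh, s.lst, s.tai, s.hrd) == (3, 4, 2, 9)
        assert s.hrd == s.hrd_loh + s.lst + s.tai
        assert s.n_gain == expected["n_gain"] and s.n_loss == expected["n_loss"]

    def test_agrees_with_naive_oracle_on_random_profiles(self, genome):
        rng = np.random.default_rng(123)
        for i in range(200):
            p = random_profile(genome, rng, f"r{i}")
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s = pst.hrd_score(p, genome)
            expected = naive_scores(p, genome)
            got = {k: getattr(s, k) for k in expected}
            got["ploidy"] = pytest.approx(expected["ploidy"])
            assert got == expected, f"disagreement on profile {i}"

    def test_adding_one_loh_segment_increments_hrd_loh(self, genome):
        targets = pst.InstabilityTargets(n_hrd_loh=2, n_lst=2, n_tai=1,
                                         n_gain=5, n_loss=1)
        prof, _ = pst.simulate_segments(targets, genome, seed=7)
        base = pst.hrd_score(prof, genome)
        # pick an all-filler chromosome with a long q arm and carve a LOH scar in
        untouched = [c for c in genome.autosomes
                     if all(s.state == (1, 1) for s in prof.by_chrom().get(c, []))
                     and genome.length(c) - genome.centromere(c)[1] > 45 * MB][-1]
        ce = genome.centromere(untouched)[1]
        new_segs = []
        for s in prof.segments:
            if s.chrom == untouched and s.start_bp <= ce and s.end_bp >= ce + 40 * MB:
                new_segs += [
                    Segment(s.chrom, s.start_bp, ce + 5 * MB, s.total_cn, s.major_cn, s.minor_cn),
                    Segment(s.chrom, ce + 9 * MB, ce + 29 * MB, 2, 2, 0),
                    Segment(s.chrom, ce + 33 * MB, s.end_bp, s.total_cn, s.major_cn, s.minor_cn),
                ]
            else:
                new_segs.append(s)
        aug = pst.hrd_score(SegmentProfile("aug", new_segs), genome)
        assert aug.hrd_loh == base.hrd_loh + 1
        assert aug.lst == base.lst and aug.tai == base.tai


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=15, deadline=None)
def test_scores_invariant_to_order_and_subdivision(seed):
    """Shuffling segment input order and splitting constant-state segments
    leaves every instability score unchanged."""
    genome = pst.default_genome()
    rng = np.random.default_rng(seed)
    import warnings
    p = random_profile(genome, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = pst.hrd_score(p, genome)
        # shuffle
        order = rng.permutation(len(p.segments))
        shuffled = SegmentProfile(p.sample_id, [p.segments[i] for i in order])
        assert pst.hrd_score(shuffled, genome) == base
        # subdivide every segment longer than 2 units into two pieces
        split = []
        for s in p.segments:
            mid = (s.start_bp + s.end_bp) // 2
            if mid > s.start_bp and mid < s.end_bp:
                split += [Segment(s.chrom, s.start_bp, mid, s.total_cn, s.major_cn, s.minor_cn),
                          Segment(s.chrom, mid, s.end_bp, s.total_cn, s.major_cn, s.minor_cn)]
            else:
                split.append(s)
        assert pst.hrd_score(SegmentProfile(p.sample_id, split), genome) == base
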