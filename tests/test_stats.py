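"""Diversity, ROH calling, D-statistic and f4-ratio."""

import numpy as np
import pytest

from ghostabc.simulate import GenotypeMatrix
from ghostabc.stats import (
    call_roh,
    d_statistic,
    f4_ratio,
    pairwise_diff_per_kbp,
)
from ghostabc.synthetic import toy_genotype_matrix

QUARTET = ("W", "X", "Y", "O")


def quartet_matrix(dosage_rows, positions, fragment_length=3_000_000):
    return toy_genotype_matrix(
        np.asarray(dosage_rows, dtype=np.int8),
        QUARTET,
        positions=np.asarray(positions, dtype=np.int64),
        fragment_lengths=(fragment_length,),
    )


class TestPairwiseDiversity:
    def test_identical_homozygous_genomes_are_zero(self):
        dos = np.array([[2, 2], [0, 0], [2, 2]], dtype=np.int8)
        geno = toy_genotype_matrix(dos, ("a", "b"), fragment_lengths=(100_000,))
        assert pairwise_diff_per_kbp(geno, "a", "b", 0).diff_per_kbp == 0.0

    def test_self_comparison_counts_heterozygotes(self):
        dos = np.ones((100, 1), dtype=np.int8)
        geno = toy_genotype_matrix(
            dos, ("a",), positions=np.arange(100) * 1000, fragment_lengths=(100_000,)
        )
        res = pairwise_diff_per_kbp(geno, "a", "a")
        assert res.diff_per_kbp == pytest.approx(1.0)
        assert res.n_callable_kbp == pytest.approx(100.0)

    def test_matches_hand_walked_allele_sampling(self):
        """Replays the documented RNG stream on a 10-site toy."""
        rng = np.random.default_rng(1234)
        dos = rng.integers(0, 3, size=(10, 2)).astype(np.int8)
        geno = toy_genotype_matrix(dos, ("a", "b"), fragment_lengths=(10_000,))
        res = pairwise_diff_per_kbp(geno, "a", "b", rng_seed=99)
        # oracle: same documented stream, site-by-site walk
        draws = np.random.default_rng(99).integers(0, 2, size=(10, 2))
        ndiff = 0
        for s in range(10):
            alleles = []
            for k in range(2):
                if dos[s, k] == 1:
                    alleles.append(draws[s, k])
                else:
                    alleles.append(dos[s, k] // 2)
            ndiff += alleles[0] != alleles[1]
        assert res.diff_per_kbp == pytest.approx(ndiff / 10.0)

    def test_empty_callable_genome_errors(self):
        geno = toy_genotype_matrix(
            np.zeros((0, 2), dtype=np.int8), ("a", "b"), fragment_lengths=(1,)
        )
        geno.callable_mask = {0: np.empty((0, 2), dtype=np.int64)}
        with pytest.raises(ValueError):
            pairwise_diff_per_kbp(geno, "a", "b")

    def test_diversity_grows_with_split_time(self):
        """Cross-population diversity increases with divergence time."""
        from ghostabc.simulate import desk_fragments
        from ghostabc.synthetic import make_admixed_panel

        values = []
        for t_split in (500.0, 3_000.0):
            geno, _ = make_admixed_panel(
                0.0,
                fragments=desk_fragments(100, 10_000),
                rng_seed=31,
                t_afr_split_gen=t_split,
            )
            values.append(pairwise_diff_per_kbp(geno, "Yor", "X", 5).diff_per_kbp)
        assert values[1] > values[0]


class TestCallRoh:
    def test_fully_callable_zero_het_is_one_top_tier_segment(self):
        segs = call_roh({"c": np.array([], dtype=np.int64)},
                        {"c": np.array([[0, 2_000_000]])})
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end) == (0, 2_000_000)
        assert seg.tier == 1.5
        assert seg.callable_fraction == 1.0

    def test_low_callable_fraction_rejected(self):
        # 1 Mbp zero-het span of which only 60% is callable
        mask = {"c": np.array([[i * 100_000, i * 100_000 + 60_000] for i in range(10)])}
        segs = call_roh({"c": np.array([], dtype=np.int64)}, mask)
        assert segs == []

    def test_callable_fraction_at_boundary_is_kept(self):
        # 67% callable exactly: 670 kbp callable inside a 1 Mbp span
        mask = {"c": np.array([[0, 335_000], [665_000, 1_000_000]])}
        segs = call_roh({"c": np.array([], dtype=np.int64)}, mask)
        assert len(segs) == 1
        assert segs[0].callable_fraction == pytest.approx(0.67)
        assert segs[0].tier == 0.5

    def test_exact_ten_percent_window_is_not_low_het(self):
        """A window at exactly 10% of expected heterozygosity splits the run."""
        mask = {"c": np.array([[0, 3_000_000]])}
        # 10-kbp windows: expected 10 hets; threshold < 1; one het at 1.505 Mb
        with_het = call_roh(
            {"c": np.array([1_505_000])}, mask, window_kbp=10.0
        )
        without = call_roh({"c": np.array([], dtype=np.int64)}, mask, window_kbp=10.0)
        assert len(without) == 1
        assert len(with_het) == 2
        # each half spans at most exactly 1.5 Mbp, which is not *more than*
        # 1.5 Mbp, so both land in the 1.0 Mbp tier
        assert {round(s.tier, 1) for s in with_het} == {1.0}

    def test_tier_assignment_uses_largest_satisfied(self):
        mask = {"c": np.array([[0, 1_200_000]])}
        segs = call_roh({"c": np.array([], dtype=np.int64)}, mask)
        assert segs[0].tier == 1.0

    def test_span_not_exceeding_smallest_tier_dropped(self):
        mask = {"c": np.array([[0, 400_000]])}
        assert call_roh({"c": np.array([], dtype=np.int64)}, mask) == []

    def test_mask_representation_invariance(self):
        """Splitting mask intervals at interior points changes nothing."""
        het = {"c": np.array([700_123, 1_900_456])}
        whole = {"c": np.array([[0, 2_500_000]])}
        split = {"c": np.array([[0, 300_000], [300_000, 1_111_111],
                                [1_111_111, 2_500_000]])}
        assert call_roh(het, whole) == call_roh(het, split)

    def test_unsorted_het_positions_error(self):
        with pytest.raises(ValueError, match="sorted"):
            call_roh({"c": np.array([10, 5])}, {"c": np.array([[0, 1_000_000]])})

    def test_background_het_breaks_runs(self):
        # 1 het per kbp everywhere: every 1-kbp window has >= 0.1 expected
        pos = np.arange(0, 2_000_000, 1000) + 500
        segs = call_roh({"c": pos}, {"c": np.array([[0, 2_000_000]])})
        assert segs == []


# 12-site toy: dosages for (W, X, Y, O), homozygous so sampling is forced.
TOY_SITES = [
    # block 1 (positions < 1 Mbp): 2 ABBA, 1 BABA, 1 uninformative
    ([0, 2, 2, 0], 0),
    ([0, 2, 2, 0], 100),
    ([2, 0, 2, 0], 200),
    ([2, 2, 2, 0], 300),
    # block 2: ABBA, BABA, ABBA-via-outgroup-recoding, uninformative
    ([0, 2, 2, 0], 1_000_000),
    ([2, 0, 2, 0], 1_000_100),
    ([2, 0, 0, 2], 1_000_200),
    ([0, 0, 2, 0], 1_000_300),
    # block 3: 3 ABBA, 1 BABA
    ([0, 2, 2, 0], 2_000_000),
    ([0, 2, 2, 0], 2_000_100),
    ([0, 2, 2, 0], 2_000_200),
    ([2, 0, 2, 0], 2_000_300),
]


def jackknife_by_hand(abba_blocks, baba_blocks):
    """Delete-one-block weighted jackknife, written out longhand."""
    A, B = sum(abba_blocks), sum(baba_blocks)
    d_hat = (A - B) / (A + B)
    m = [a + b for a, b in zip(abba_blocks, baba_blocks)]
    n = sum(m)
    g = len(m)
    d_minus = [
        ((A - a) - (B - b)) / ((A - a) + (B - b))
        for a, b in zip(abba_blocks, baba_blocks)
    ]
    h = [n / mj for mj in m]
    theta_j = g * d_hat - sum((1 - mj / n) * dm for mj, dm in zip(m, d_minus))
    tau = [hj * d_hat - (hj - 1) * dm for hj, dm in zip(h, d_minus)]
    var = sum((t - theta_j) ** 2 / (hj - 1) for t, hj in zip(tau, h)) / g
    return d_hat, var**0.5


class TestDStatistic:
    def test_twelve_site_toy_matches_hand_tally(self):
        rows, positions = zip(*TOY_SITES)
        geno = quartet_matrix(rows, positions)
        res = d_statistic(geno, *QUARTET, block_size=1_000_000, rng_seed=0)
        assert (res.abba, res.baba) == (7, 3)
        d_hand, se_hand = jackknife_by_hand([2, 2, 3], [1, 1, 1])
        assert res.d == pytest.approx(d_hand)
        assert res.se == pytest.approx(se_hand)
        assert res.z == pytest.approx(res.d / res.se)
        assert res.n_blocks == 3

    def test_equal_abba_baba_gives_zero(self):
        rows = [[0, 2, 2, 0], [2, 0, 2, 0]] * 3
        pos = [0, 100, 1_000_000, 1_000_100, 2_000_000, 2_000_100]
        res = d_statistic(quartet_matrix(rows, pos), *QUARTET, block_size=1_000_000)
        assert res.d == 0.0

    def test_all_abba_is_one(self):
        rows = [[0, 2, 2, 0]] * 6
        pos = [0, 100, 1_000_000, 1_000_100, 2_000_000, 2_000_100]
        res = d_statistic(quartet_matrix(rows, pos), *QUARTET, block_size=1_000_000)
        assert res.d == 1.0

    def test_antisymmetric_in_first_two_taxa(self):
        rng = np.random.default_rng(21)
        rows = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        pos = np.sort(rng.choice(3_000_000, size=60, replace=False))
        geno = quartet_matrix(rows, pos)
        swapped = quartet_matrix(rows[:, [1, 0, 2, 3]], pos)
        a = d_statistic(geno, *QUARTET, block_size=1_000_000, rng_seed=3)
        b = d_statistic(swapped, *QUARTET, block_size=1_000_000, rng_seed=3)
        assert a.d == pytest.approx(-b.d)
        assert abs(a.d) <= 1.0
        assert np.sign(a.z) == np.sign(a.d)

    def test_no_informative_sites_errors(self):
        rows = [[2, 2, 2, 0], [0, 0, 0, 0]]
        with pytest.raises(ValueError, match="informative"):
            d_statistic(quartet_matrix(rows, [0, 100]), *QUARTET)

    def test_null_panel_is_not_significant(self, admixed_panel_null):
        # block size chosen so the 8 Mbp fixture yields ~30 jackknife blocks
        geno, _ = admixed_panel_null
        res = d_statistic(geno, "Yor", "X", "Fr", "O",
                          block_size=250_000, rng_seed=17)
        assert res.n_blocks >= 20
        assert abs(res.z) < 3

    def test_admixed_panel_is_significant_and_positive(self, admixed_panel_03):
        geno, _ = admixed_panel_03
        res = d_statistic(geno, "Yor", "X", "Fr", "O",
                          block_size=250_000, rng_seed=17)
        assert res.z > 3
        assert res.d > 0


class TestF4Ratio:
    NUM = ("Sar", "Han", "X", "Yor")
    DEN = ("Sar", "Han", "Fr", "Yor")

    def test_x_equals_reference_gives_unity(self, admixed_panel_03):
        geno, _ = admixed_panel_03
        res = f4_ratio(geno, self.DEN, self.DEN, block_size=250_000, rng_seed=4)
        assert res.alpha == pytest.approx(1.0)

    def test_duplicated_population_gives_zero(self, admixed_panel_03):
        geno, _ = admixed_panel_03
        res = f4_ratio(geno, ("Sar", "Han", "Yor", "Yor"), self.DEN,
                       block_size=250_000, rng_seed=4)
        assert res.alpha == 0.0

    def test_planted_admixture_fraction_recovered(self, admixed_panel_03):
        """Replicated recovery: the mean estimate brackets the planted 30%."""
        from ghostabc.simulate import desk_fragments
        from ghostabc.synthetic import make_admixed_panel

        geno, manifest = admixed_panel_03
        estimates = [
            f4_ratio(geno, self.NUM, self.DEN, block_size=250_000, rng_seed=4).alpha
        ]
        for seed in (1, 2, 3):
            g, _ = make_admixed_panel(
                0.3, fragments=desk_fragments(300, 20_000), rng_seed=seed
            )
            estimates.append(
                f4_ratio(g, self.NUM, self.DEN, block_size=250_000, rng_seed=4).alpha
            )
        assert 0.2 < np.mean(estimates) < 0.4

    def test_null_panel_alpha_near_zero(self, admixed_panel_null):
        geno, _ = admixed_panel_null
        res = f4_ratio(geno, self.NUM, self.DEN, block_size=250_000, rng_seed=4)
        assert res.alpha == pytest.approx(0.0, abs=max(3 * res.se, 0.08))
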