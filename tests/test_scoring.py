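import itertools

import numpy as np
import pytest

from urocnv import (ChromSizes, InvalidInputError, compare_groups,
                    cluster_paired_profiles, teff_index, tile_genome,
                    uga_score)
from urocnv.scoring import AbnormalityScore
from urocnv.segment import Segment, SegmentedProfile
from conftest import make_profile


def _seg(mean, n_bins=10, chrom="chr1", filtered="none", order=0):
    start = order * 1_000_000
    return Segment(chrom, start, start + n_bins * 60_000, 0, n_bins - 1,
                   n_bins, mean, abs(mean) * np.sqrt(n_bins), filtered)


def _segmented(segments):
    bins = tile_genome(ChromSizes((("chr1", 600_000),)), 60_000)
    prof = make_profile(bins, np.zeros(10), sample_id="fixture")
    return SegmentedProfile(prof, segments, {})


class TestUgaScore:
    def test_sort_and_sum_oracle_twelve_segments(self):
        means = [round(0.1 * i, 10) for i in range(1, 13)]
        segs = [_seg(m, order=i) for i, m in enumerate(means)]
        score = uga_score(_segmented(segs), k=10)
        # independent oracle: sort descending, sum first ten
        expected = sum(sorted((abs(m) for m in means), reverse=True)[:10])
        assert score.score == pytest.approx(expected, abs=1e-9)
        assert score.score == pytest.approx(7.5, abs=1e-9)
        assert score.k == 10

    def test_all_zero_means(self):
        score = uga_score(_segmented([_seg(0.0, order=i) for i in range(5)]))
        assert score.score == 0.0

    def test_fewer_than_ten_segments(self):
        segs = [_seg(m, order=i) for i, m in enumerate([0.5, -0.2, 0.1])]
        score = uga_score(_segmented(segs))
        assert score.score == pytest.approx(0.8)
        assert score.k == 3

    def test_filtered_segments_excluded(self):
        segs = [_seg(5.0, filtered="centromere"), _seg(3.0, n_bins=4,
                                                       filtered="too_small"),
                _seg(0.4, order=2)]
        score = uga_score(_segmented(segs))
        assert score.score == pytest.approx(0.4)

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(0)
        means = list(rng.normal(0, 0.5, 15))
        segs = [_seg(m, order=i) for i, m in enumerate(means)]
        base = uga_score(_segmented(segs)).score
        for perm_seed in range(3):
            shuffled = list(segs)
            np.random.default_rng(perm_seed).shuffle(shuffled)
            assert uga_score(_segmented(shuffled)).score == \
                pytest.approx(base, abs=1e-12)
        # raise one contributing |mean|: score never decreases
        top = max(range(len(means)), key=lambda i: abs(means[i]))
        segs[top] = _seg(means[top] * 2, order=top)
        assert uga_score(_segmented(segs)).score >= base

    def test_rank_by_sqrt_n_alternative(self):
        segs = [_seg(0.3, n_bins=100), _seg(0.4, n_bins=5, order=1)]
        by_mean = uga_score(_segmented(segs), k=1)
        by_stat = uga_score(_segmented(segs), k=1,
                            rank_by="abs_mean_sqrt_n")
        assert by_mean.score == pytest.approx(0.4)
        assert by_stat.score == pytest.approx(0.3)  # 0.3*10 > 0.4*sqrt(5)

    def test_invalid_k(self):
        with pytest.raises(InvalidInputError):
            uga_score(_segmented([_seg(0.5)]), k=0)


def _score(value, sample="p1"):
    return AbnormalityScore(sample, value, 1, [])


class TestTeffIndex:
    def test_equal_scores_zero(self):
        assert teff_index(_score(2.0), _score(2.0)).value == 0.0

    def test_halving_gives_plus_100(self):
        assert teff_index(_score(2.0), _score(1.0)).value == \
            pytest.approx(100.0)

    def test_doubling_gives_minus_100(self):
        assert teff_index(_score(1.0), _score(2.0)).value == \
            pytest.approx(-100.0)

    def test_antisymmetry(self):
        pre, post = _score(3.7), _score(1.2)
        assert teff_index(pre, post).value == \
            pytest.approx(-teff_index(post, pre).value)

    def test_zero_score_undefined(self):
        with pytest.raises(InvalidInputError, match="undefined"):
            teff_index(_score(0.0), _score(1.0))


def exact_ranksum_p(a, b):
    """Oracle: enumerate all label assignments, two-sided rank-sum."""
    pooled = np.array(list(a) + list(b))
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:len(a)].sum()
    n = len(pooled)
    total = 0
    extreme = 0
    center = len(a) * (n + 1) / 2
    for comb in itertools.combinations(range(n), len(a)):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - center) >= abs(obs - center) - 1e-12:
            extreme += 1
    return extreme / total


class TestCompareGroups:
    def test_separated_groups_match_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        scores = [_score(v, f"p{i}") for i, v in enumerate(a + b)]
        labels = ["low_volume"] * 3 + ["high_volume"] * 3
        _, p, medians = compare_groups(scores, labels)
        assert p == pytest.approx(exact_ranksum_p(a, b))
        assert p == pytest.approx(2 / 20)
        assert medians == {"high_volume": 20.0, "low_volume": 2.0}

    def test_shifted_groups_usually_significant(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 1, 20)
            b = rng.normal(2, 1, 20)  # shift = 2 sd
            scores = [_score(v, f"p{i}") for i, v in enumerate(
                np.concatenate([a, b]))]
            labels = ["low_volume"] * 20 + ["high_volume"] * 20
            _, p, _ = compare_groups(scores, labels)
            hits += p < 0.05
        assert hits >= 160

    def test_empty_group_rejected(self):
        scores = [_score(v) for v in (1, 2, 3)]
        with pytest.raises(InvalidInputError):
            compare_groups(scores, ["a", "a", "a"])


class TestClusterPairedProfiles:
    def _profiles(self, vectors, ids):
        bins = tile_genome(
            ChromSizes((("chr1", len(vectors[0]) * 60_000),)), 60_000)
        return [make_profile(bins, v, sample_id=i)
                for v, i in zip(vectors, ids)]

    def test_identical_profiles_distance_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.5, 200)
        w = rng.normal(0, 0.5, 200)
        profs = self._profiles([v, v, w, rng.normal(0, 0.5, 200)],
                               ["1001U1", "1001U2", "1002U1", "1002U2"])
        Z, condensed, report = cluster_paired_profiles(profs)
        assert condensed[0] == pytest.approx(0.0, abs=1e-12)  # pair (0,1)
        assert report["pair_status"]["1001"] is True

    def test_negated_profile_distance_two(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.5, 200)
        profs = self._profiles(
            [v, -v, rng.normal(0, 0.5, 200), rng.normal(0, 0.5, 200)],
            ["aU1", "aU2", "bU1", "bU2"])
        _, condensed, _ = cluster_paired_profiles(profs)
        assert condensed[0] == pytest.approx(2.0, abs=1e-9)

    def test_simulated_pairs_are_mutual_nearest_neighbors(self):
        """Pairs share a CN truth (tumor fraction varying +/-20%); unrelated
        patients have independent truths."""
        from urocnv import (ratio_profile, scale_to_global_mean,
                            simulate_counts)
        from urocnv.simulate import neutral_truth, place_segment, toy_genome
        import dataclasses

        bins = toy_genome(n_bins=600, n_chroms=6, seed=5)
        landscapes = {  # distinct CN truth per patient
            0: [("chr1", 0.1, 0.6, 3), ("chr4", 0.3, 0.9, 1)],
            1: [("chr2", 0.2, 0.8, 1), ("chr5", 0.1, 0.5, 4)],
            2: [("chr3", 0.3, 0.9, 3), ("chr6", 0.2, 0.7, 1)],
        }
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            profs = []
            for patient in range(3):
                truth = neutral_truth(bins, f=0.3, depth=150,
                                      seed=seed * 10 + patient)
                for chrom, lo, hi, cn in landscapes[patient]:
                    place_segment(truth, chrom, lo, hi, cn)
                for tp in (1, 2):
                    f = 0.3 * (1 + rng.uniform(-0.2, 0.2))
                    t = dataclasses.replace(truth, tumor_fraction=f)
                    cf = scale_to_global_mean(simulate_counts(
                        t, f"p{patient}U{tp}",
                        np.random.default_rng(seed * 100 + patient * 10 + tp)))
                    gd = scale_to_global_mean(simulate_counts(
                        dataclasses.replace(truth, cn=np.full(bins.n_bins, 2)),
                        f"p{patient}G",
                        np.random.default_rng(seed * 100 + patient * 10 + tp + 5)))
                    profs.append(ratio_profile(cf, gd, sample_id=f"p{patient}U{tp}"))
            _, _, report = cluster_paired_profiles(profs)
            hits += report["pairs_mutual_nn"]
            total += report["pairs_total"]
        assert hits / total >= 0.9

    def test_too_few_profiles_rejected(self):
        profs = self._profiles([np.zeros(60)] * 3, ["a1", "a2", "b1"])
        with pytest.raises(InvalidInputError):
            cluster_paired_profiles(profs[:3])
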